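"""Round/distorted classification and transition-cycle statistics.

The corrugation of a closed ring's top surface is summarized per frame by
the SDCH — the standard deviation of cross-sectional heights sampled
along the ring outline shrunk radially toward the center (default shrink
0.65, within the 0.6-0.7 range appropriate for these rings).  Rings with
SDCH below 0.3 nm are round; at or above, distorted.  Occasional spike
frames (tip-induced height artifacts) are replaced by the previous
frame's value before thresholding.  A transition cycle is one complete
round -> distorted -> round excursion; the transition frequency is the
number of completed cycles divided by the total observation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgproc import HeightMap
from .ringshape import Outline

__all__ = [
    "SDCH_THRESHOLD_NM",
    "TransitionReport",
    "sdch",
    "despike",
    "classify_states",
    "count_cycles",
]

#: SDCH threshold (nm) separating round (<) from distorted (>=) closed rings
SDCH_THRESHOLD_NM = 0.3


def sdch(
    hmap: HeightMap,
    outline: Outline,
    shrink: float = 0.65,
    n_samples: int = 64,
) -> float:
    """Standard deviation of heights along the radially shrunk outline (nm).

    The ring center is the centroid of the smoothed outline; every outline
    point is moved toward it by the shrink factor, the shrunk path is
    resampled at ``n_samples`` equal-arc-length positions, and heights are
    read by bilinear interpolation.  Returns the population standard
    deviation of the sampled heights.
    """
    if not (0.5 <= shrink <= 0.9):
        raise ValueError("shrink must be in [0.5, 0.9]")
    if n_samples < 8:
        raise ValueError("need >= 8 samples")
    center = outline.centroid()
    shrunk = center + shrink * (outline.points - center)

    # resample at equal arc length along the closed shrunk path
    ring = np.vstack([shrunk, shrunk[:1]])
    seg = np.hypot(*np.diff(ring, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    ts = np.linspace(0.0, total, n_samples, endpoint=False)
    xs = np.interp(ts, t, ring[:, 0])
    ys = np.interp(ts, t, ring[:, 1])

    px = hmap.pixel_nm
    ny, nx = hmap.shape
    rows = ys / px
    cols = xs / px
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() > ny - 1 or cols.max() > nx - 1):
        raise ValueError("shrunk outline leaves the frame")
    heights = ndimage.map_coordinates(hmap.heights, [rows, cols], order=1)
    return float(np.std(heights, ddof=0))


def _as_series_frame(series) -> pd.DataFrame:
    if isinstance(series, pd.DataFrame):
        df = series.copy()
    else:
        df = pd.DataFrame({"sdch": np.asarray(series, dtype=float)})
    if "sdch" not in df.columns:
        raise ValueError("series must have an 'sdch' column")
    if "valid" not in df.columns:
        df["valid"] = np.isfinite(df["sdch"])
    return df.reset_index(drop=True)


def despike(
    series,
    k_mad: float = 6.0,
    jump_nm: float = 0.4,
) -> pd.DataFrame:
    """Replace spike frames by the previous frame's SDCH value.

    A frame is a spike when its SDCH exceeds the series median by more
    than ``k_mad`` median absolute deviations AND exceeds the
    (already-despiked) previous frame by more than ``jump_nm``.  The first
    frame has no predecessor and is never replaced.  Adds a boolean
    ``spike`` column.
    """
    df = _as_series_frame(series)
    if len(df) < 2:
        raise ValueError("need >= 2 frames")
    x = df["sdch"].to_numpy(dtype=float).copy()
    valid = df["valid"].to_numpy(dtype=bool)
    med = float(np.median(x[valid])) if valid.any() else float(np.median(x))
    mad = float(np.median(np.abs(x[valid] - med))) if valid.any() else 0.0
    gate = med + k_mad * mad
    spikes = np.zeros(len(x), dtype=bool)
    for i in range(1, len(x)):
        if not valid[i]:
            continue
        prev = x[i - 1] if valid[i - 1] else med
        if x[i] > gate and x[i] - prev > jump_nm:
            spikes[i] = True
            x[i] = prev
    df["sdch"] = x
    df["spike"] = spikes
    return df


def classify_states(series, threshold_nm: float = SDCH_THRESHOLD_NM) -> pd.DataFrame:
    """Label each frame round (SDCH < threshold) or distorted (>=).

    Frames flagged invalid (failed shape extraction, open rings) receive
    the state ``invalid`` and are excluded from dwell statistics.
    """
    df = _as_series_frame(series)
    x = df["sdch"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool)
    state = np.where(x < threshold_nm, "round", "distorted")
    state = np.where(valid, state, "invalid")
    df["state"] = state
    return df


@dataclass
class TransitionReport:
    """Completed round/distorted transition cycles over an observation."""

    n_cycles: int
    total_time: float  # s
    frequency: float  # 1/s
    dwell_times: dict[str, list[float]] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"transition cycles: {self.n_cycles}",
            f"total observation time: {self.total_time:.3f} s",
            f"cycle frequency: {self.frequency:.6g} 1/s",
        ]
        for state, dwells in self.dwell_times.items():
            if dwells:
                lines.append(
                    f"  {state}: {len(dwells)} complete dwells, "
                    f"mean {np.mean(dwells):.3f} s"
                )
            else:
                lines.append(f"  {state}: no complete dwells")
        return "\n".join(lines)


def count_cycles(series, frame_interval: float) -> TransitionReport:
    """Count completed transition cycles and report the cycle frequency.

    A cycle is registered at each distorted -> round transition that was
    preceded (anywhere earlier) by a round -> distorted transition, i.e.
    one full excursion; the frequency divides the cycle count by the total
    observation period ``n_frames * frame_interval``.  Dwell-time lists
    cover complete (uncensored) visits of the valid frames; invalid frames
    are skipped in the state walk.
    """
    df = _as_series_frame(series)
    if "state" not in df.columns:
        raise ValueError("series must be classified first (classify_states)")
    if not (frame_interval > 0):
        raise ValueError("frame_interval must be > 0")
    states = df["state"].to_numpy()
    ok = states != "invalid"
    if not ok.any():
        raise ValueError("all frames invalid: nothing to count")
    n_frames = len(states)
    total_time = n_frames * frame_interval

    walk = states[ok]
    n_cycles = 0
    armed = False  # a round->distorted transition has occurred
    for prev, cur in zip(walk[:-1], walk[1:]):
        if prev == "round" and cur == "distorted":
            armed = True
        elif prev == "distorted" and cur == "round" and armed:
            n_cycles += 1
    # dwell times: complete runs only (first and last runs are censored)
    dwells: dict[str, list[float]] = {"round": [], "distorted": []}
    run_state = walk[0]
    run_len = 1
    runs = []
    for s in walk[1:]:
        if s == run_state:
            run_len += 1
        else:
            runs.append((run_state, run_len))
            run_state, run_len = s, 1
    runs.append((run_state, run_len))
    for state, length in runs[1:-1]:
        dwells[state].append(length * frame_interval)

    return TransitionReport(
        n_cycles=n_cycles,
        total_time=total_time,
        frequency=n_cycles / total_time,
        dwell_times=dwells,
    )
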