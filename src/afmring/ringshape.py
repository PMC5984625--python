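"""Open/closed ring classification by elliptic Fourier circularity.

Pipeline per frame: binarize at an automatically chosen (Otsu) threshold,
take the largest 8-connected particle, trace its boundary (Moore neighbor
tracing), smooth the outline by truncating its elliptic Fourier series at
the 8th harmonic, and compute the circularity 4*pi*S / L**2 of the
smoothed profile (1 for a circle).  Rings with circularity at or above
the threshold (default 0.68) are closed; below it, open.  For closed
rings a ridge-path contour length is measured by locating the radial
height maximum on 360 rays from the ring center and smoothing the ridge
by the same elliptic Fourier truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString
from skimage.filters import threshold_otsu
from skimage.measure import label

from .imgproc import HeightMap

__all__ = [
    "Outline",
    "EFDescriptor",
    "ShapeMetrics",
    "FrameFlagged",
    "binarize_outline",
    "efd_fit",
    "efd_reconstruct",
    "smooth_outline",
    "circularity",
    "contour_length",
    "classify_and_tally",
    "CIRCULARITY_THRESHOLD",
]

#: circularity threshold separating closed (>=) from open (<) rings
CIRCULARITY_THRESHOLD = 0.68


class FrameFlagged(ValueError):
    """A frame excluded from statistics (empty, border-touching, degenerate)."""


@dataclass
class Outline:
    """Ordered boundary points (x, y) in nm of a closed contour.

    The first point is not repeated at the end; the closing segment is
    implicit.  Consecutive duplicates are rejected.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
            raise ValueError("outline needs an (N>=3, 2) point array")
        if p.shape[0] > 1 and np.allclose(p[0], p[-1]):
            p = p[:-1]
        seg = np.diff(p, axis=0)
        if np.any(np.all(seg == 0, axis=1)):
            raise ValueError("outline has consecutive duplicate points")
        self.points = p

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def perimeter(self) -> float:
        p = self.points
        seg = np.diff(np.vstack([p, p[:1]]), axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))

    def area(self) -> float:
        """Shoelace area (absolute value), nm^2."""
        p = self.points
        x, y = p[:, 0], p[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def centroid(self) -> np.ndarray:
        """Area centroid of the closed polygon (falls back to vertex mean)."""
        p = self.points
        x, y = p[:, 0], p[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return p.mean(axis=0)
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    def is_simple(self) -> bool:
        ring = np.vstack([self.points, self.points[:1]])
        return bool(LineString(ring).is_simple)


@dataclass
class EFDescriptor:
    """Elliptic Fourier coefficients of a closed contour.

    ``coeffs[n-1] = (a_n, b_n, c_n, d_n)`` for harmonic n; ``dc`` is the
    contour centroid term (A0, C0).
    """

    order: int
    coeffs: np.ndarray
    dc: tuple[float, float]

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if self.order < 1 or c.shape != (self.order, 4):
            raise ValueError("coeffs must have shape (order, 4) with order >= 1")
        self.coeffs = c


# ---------------------------------------------------------------------------
# binarization and boundary tracing
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold of a height histogram."""
    return float(threshold_otsu(np.asarray(values, dtype=float)))


# Moore neighborhood in clockwise order starting from West (row, col offsets)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the True region (Moore neighbor tracing).

    Returns boundary pixel (row, col) coordinates in order.  The walk
    starts at the topmost-leftmost foreground pixel entered from the West
    and stops when the (pixel, backtrack) state repeats, which closes the
    boundary cycle exactly once even on shapes with one-pixel necks.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    ny, nx = mask.shape

    def fg(p):
        r, c = p
        return 0 <= r < ny and 0 <= c < nx and mask[r, c]

    boundary = [start]
    backtrack = (start[0], start[1] - 1)  # entered scanning from the West
    current = start
    seen = {(current, backtrack)}
    for _ in range(8 * mask.size):
        dr, dc = backtrack[0] - current[0], backtrack[1] - current[1]
        start_idx = _MOORE.index((dr, dc))
        nxt = None
        prev = backtrack
        for j in range(1, 9):
            off = _MOORE[(start_idx + j) % 8]
            cand = (current[0] + off[0], current[1] + off[1])
            if fg(cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel
            break
        state = (nxt, prev)
        if state in seen:
            break
        seen.add(state)
        boundary.append(nxt)
        backtrack = prev
        current = nxt
    # drop closing duplicate if present
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary = boundary[:-1]
    return np.array(boundary, dtype=float)


def binarize_outline(hmap: HeightMap) -> Outline:
    """Binarize a frame and trace the outline of the dominant particle.

    The threshold maximizes the between-class variance of the height
    histogram (Otsu); the largest 8-connected foreground component is
    taken and its outer boundary traced by Moore neighbor tracing, then
    converted to nm.  Frames with empty foreground, a component touching
    the frame border, or a boundary too short to smooth are flagged
    (``FrameFlagged``) and should be excluded from statistics.
    """
    h = hmap.heights
    if np.ptp(h) == 0:
        raise FrameFlagged("flat frame: no foreground")
    thr = otsu_threshold(h)
    mask = h > thr
    if not mask.any():
        raise FrameFlagged("empty foreground after thresholding")
    lab = label(mask, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    comp = lab == largest
    rows, cols = np.nonzero(comp)
    ny, nx = comp.shape
    if rows.min() == 0 or cols.min() == 0 or rows.max() == ny - 1 or cols.max() == nx - 1:
        raise FrameFlagged("particle touches the frame border")
    b = _moore_trace(comp)
    if b.shape[0] < 8:
        raise FrameFlagged("boundary too short for harmonic smoothing")
    pts = np.column_stack([b[:, 1], b[:, 0]]) * hmap.pixel_nm  # (x, y) nm
    # Moore tracing can revisit pixels on one-pixel-wide necks; drop
    # consecutive duplicates defensively before building the outline.
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    return Outline(pts[keep])


# ---------------------------------------------------------------------------
# elliptic Fourier descriptors (Kuhl-Giardina)
# ---------------------------------------------------------------------------

def efd_fit(outline: Outline, order: int = 8) -> EFDescriptor:
    """Elliptic Fourier coefficients of a closed polygonal contour.

    The contour is parameterized by arc length t in [0, T]; harmonic n
    contributes a_n cos + b_n sin to x(t) and c_n cos + d_n sin to y(t).
    Truncating at low order smooths pixel-level jaggedness while keeping
    the global shape.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not outline.closed:
        raise ValueError("elliptic Fourier fit requires a closed contour")
    p = np.vstack([outline.points, outline.points[:1]])
    d = np.diff(p, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * math.pi * t / T

    n = np.arange(1, order + 1)[:, None]  # (order, 1)
    const = T / (2.0 * (n**2) * math.pi**2)
    d_cos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    d_sin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = (const * (dx_dt * d_cos)).sum(axis=1)[:, None]
    b = (const * (dx_dt * d_sin)).sum(axis=1)[:, None]
    c = (const * (dy_dt * d_cos)).sum(axis=1)[:, None]
    dd = (const * (dy_dt * d_sin)).sum(axis=1)[:, None]

    # DC term: average position over the arc-length parameterization
    xi = np.cumsum(d[:, 0]) - dx_dt * t[1:]
    delta = np.cumsum(d[:, 1]) - dy_dt * t[1:]
    a0 = (np.sum(dx_dt / 2.0 * np.diff(t**2)) + np.sum(xi * dt)) / T + p[0, 0]
    c0 = (np.sum(dy_dt / 2.0 * np.diff(t**2)) + np.sum(delta * dt)) / T + p[0, 1]

    return EFDescriptor(order, np.hstack([a, b, c, dd]), (float(a0), float(c0)))


def efd_reconstruct(desc: EFDescriptor, n_points: int = 256) -> Outline:
    """Sample the truncated Fourier series at equal parameter steps."""
    if n_points < 3:
        raise ValueError("need >= 3 reconstruction points")
    tt = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    n = np.arange(1, desc.order + 1)[:, None]
    cos_nt = np.cos(n * tt)
    sin_nt = np.sin(n * tt)
    a, b, c, d = desc.coeffs.T
    x = desc.dc[0] + a @ cos_nt + b @ sin_nt
    y = desc.dc[1] + c @ cos_nt + d @ sin_nt
    return Outline(np.column_stack([x, y]))


def smooth_outline(outline: Outline, order: int = 8, n_points: int = 256) -> Outline:
    """Order-``order`` elliptic Fourier smoothing of a traced outline."""
    return efd_reconstruct(efd_fit(outline, order), n_points)


# ---------------------------------------------------------------------------
# shape metrics
# ---------------------------------------------------------------------------

@dataclass
class ShapeMetrics:
    """Per-particle shape statistics of the smoothed outline."""

    perimeter_L: float
    area_S: float
    circularity: float
    contour_length: float | None = None
    ring_class: str | None = None
    valid: bool = True


def circularity(outline: Outline) -> ShapeMetrics:
    """Circularity 4*pi*S / L**2 of the (already smoothed) profile.

    L is the polygon perimeter and S the shoelace area of the smoothed
    outline.  A self-intersecting profile is flagged invalid rather than
    scored.
    """
    L = outline.perimeter()
    S = outline.area()
    circ = 4.0 * math.pi * S / (L * L)
    valid = outline.is_simple()
    return ShapeMetrics(perimeter_L=L, area_S=S, circularity=circ, valid=valid)


def contour_length(
    hmap: HeightMap,
    outline: Outline,
    n_rays: int = 360,
    order: int = 8,
    n_points: int = 256,
) -> float:
    """Ridge-path contour length (nm) of a closed ring.

    For each of ``n_rays`` rays from the ring center (outline centroid),
    the radial height maximum inside the outline is located by bilinear
    interpolation on a fine radial grid; the ridge points are smoothed by
    the order-8 elliptic Fourier truncation and the perimeter of the
    reconstruction is returned.  Rays whose maximum sits at the center or
    carries negligible height indicate an open ring and make the
    operation refuse.
    """
    center = outline.centroid()
    rel = outline.points - center
    out_r = np.hypot(rel[:, 0], rel[:, 1])
    out_th = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * math.pi)
    order_idx = np.argsort(out_th)
    out_th_s = out_th[order_idx]
    out_r_s = out_r[order_idx]
    # wrap for periodic interpolation of the outline radius
    th_wrap = np.concatenate([[out_th_s[-1] - 2 * math.pi], out_th_s,
                              [out_th_s[0] + 2 * math.pi]])
    r_wrap = np.concatenate([[out_r_s[-1]], out_r_s, [out_r_s[0]]])

    h = hmap.heights
    px = hmap.pixel_nm
    hmax = float(h.max())
    step = px / 4.0
    angles = np.linspace(0.0, 2 * math.pi, n_rays, endpoint=False)
    ridge = np.empty((n_rays, 2))
    for i, th in enumerate(angles):
        r_out = np.interp(th, th_wrap, r_wrap)
        radii = np.arange(0.0, r_out + step, step)
        xs = center[0] + radii * math.cos(th)
        ys = center[1] + radii * math.sin(th)
        vals = ndimage.map_coordinates(h, [ys / px, xs / px], order=1, mode="nearest")
        j = int(np.argmax(vals))
        if j == 0 or vals[j] < 0.2 * hmax:
            raise FrameFlagged(
                "ray without an interior ridge maximum: contour length is "
                "defined only for closed rings"
            )
        ridge[i] = xs[j], ys[j]
    smooth = smooth_outline(Outline(ridge), order=order, n_points=n_points)
    return smooth.perimeter()


def classify_and_tally(
    metrics: list[ShapeMetrics],
    threshold: float = CIRCULARITY_THRESHOLD,
    bin_width: float = 0.02,
) -> dict:
    """Assign closed/open classes and tally percentages and the histogram.

    Circularity at or above the threshold classifies closed (ties go to
    closed); invalid metrics are excluded.  The histogram uses fixed-width
    bins (default 0.02) aligned to zero.  Empty input yields an empty
    report.
    """
    valid = [m for m in metrics if m.valid and np.isfinite(m.circularity)]
    for m in metrics:
        if m.valid and np.isfinite(m.circularity):
            m.ring_class = "closed" if m.circularity >= threshold else "open"
        else:
            m.ring_class = None
    n = len(valid)
    if n == 0:
        return {"n": 0, "pct_closed": float("nan"), "pct_open": float("nan"),
                "histogram": pd.DataFrame(columns=["bin_left", "bin_right", "count"])}
    circ = np.array([m.circularity for m in valid])
    n_closed = int(np.sum(circ >= threshold))
    lo = math.floor(circ.min() / bin_width) * bin_width
    hi = math.ceil(circ.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(circ, bins=edges)
    hist = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
    })
    return {
        "n": n,
        "pct_closed": 100.0 * n_closed / n,
        "pct_open": 100.0 * (n - n_closed) / n,
        "histogram": hist,
    }
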