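"""Height-map containers, stack I/O and per-frame preprocessing.

An HS-AFM topograph is a calibrated grid of surface heights (nm) with a
known pixel size (nm/px); a movie is an ordered stack of such frames at a
fixed frame interval.  Two filters are applied to every frame before any
shape metric is computed:

* first-order plane flattening, which removes the tilt of the sample
  relative to the scanning plane, and
* an isotropic real-space low-pass filter parameterized by a cutoff
  *wavelength* in nm, with half-amplitude transfer at spatial frequency
  1/cutoff.

Movies are stored as multi-page 32-bit float TIFF plus a YAML sidecar
carrying the calibration metadata; the round trip is lossless at float32
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage

__all__ = [
    "HeightMap",
    "Movie",
    "read_stack",
    "write_stack",
    "plane_flatten",
    "lowpass",
]


@dataclass
class HeightMap:
    """A single calibrated topograph: heights in nm on a regular grid.

    Coordinate convention: x runs along columns (rightward), y along rows
    (downward); the point (x, y) = (j * pixel_nm, i * pixel_nm) is the
    center of pixel (i, j).
    """

    heights: np.ndarray
    pixel_nm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if not (self.pixel_nm > 0):
            raise ValueError("pixel_nm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        ny, nx = self.heights.shape
        return nx * self.pixel_nm, ny * self.pixel_nm


@dataclass
class Movie:
    """An ordered stack of frames sharing shape, calibration and timing."""

    frames: list[HeightMap]
    frame_interval: float  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("movie must contain at least one frame")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        shape = self.frames[0].shape
        px = self.frames[0].pixel_nm
        for k, fr in enumerate(self.frames):
            if fr.shape != shape:
                raise ValueError(f"frame {k} shape {fr.shape} != {shape}")
            if fr.pixel_nm != px:
                raise ValueError(f"frame {k} pixel_nm {fr.pixel_nm} != {px}")

    @property
    def pixel_nm(self) -> float:
        return self.frames[0].pixel_nm

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        return np.stack([fr.heights for fr in self.frames])

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_stack(movie: Movie, path: str | Path) -> Path:
    """Write a movie as float32 multi-page TIFF plus a YAML sidecar.

    Returns the sidecar path.  Heights are cast to float32; metadata
    (pixel_nm, frame_interval plus anything in ``movie.meta``) goes to the
    sidecar so the raster file stays a plain image stack.
    """
    path = Path(path)
    data = movie.stack().astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = dict(movie.meta)
    meta["pixel_nm"] = float(movie.pixel_nm)
    meta["frame_interval"] = float(movie.frame_interval)
    side = _sidecar_path(path)
    side.write_text(yaml.safe_dump(meta, sort_keys=True))
    return side


def read_stack(path: str | Path) -> Movie:
    """Read a movie written by :func:`write_stack`.

    Raises ``ValueError`` naming the missing sidecar field, and rejects
    stacks whose pages do not share one frame shape.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise ValueError(f"missing sidecar metadata file {side}")
    meta = yaml.safe_load(side.read_text()) or {}
    for key in ("pixel_nm", "frame_interval"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    pixel_nm = float(meta.pop("pixel_nm"))
    frame_interval = float(meta.pop("frame_interval"))
    with tifffile.TiffFile(path) as tf:
        shapes = {page.shape for page in tf.pages}
        if len(shapes) != 1:
            raise ValueError(f"stack has mismatched frame shapes: {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:
        data = data[None]
    frames = [HeightMap(fr.astype(float), pixel_nm) for fr in data]
    return Movie(frames, frame_interval, meta=meta)


def plane_flatten(hmap: HeightMap, mask: np.ndarray | None = None) -> HeightMap:
    """Fit and subtract a least-squares plane a + b*x + c*y.

    The plane is fitted over background pixels (``mask`` True) when a mask
    is given, else over all pixels, and subtracted everywhere, so the
    background mean becomes ~0 and tilt is removed.  A mask with fewer than
    3 pixels, or with all its pixels collinear, is degenerate and rejected.
    """
    h = hmap.heights
    ny, nx = h.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x = xx * hmap.pixel_nm
    y = yy * hmap.pixel_nm
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != h.shape:
            raise ValueError("mask shape must match heights")
        if mask.sum() < 3:
            raise ValueError("degenerate mask: need >= 3 background pixels")
        xs, ys, zs = x[mask], y[mask], h[mask]
    else:
        xs, ys, zs = x.ravel(), y.ravel(), h.ravel()
    A = np.column_stack([np.ones_like(xs), xs, ys])
    coef, _, rank, _ = np.linalg.lstsq(A, zs, rcond=None)
    if rank < 3:
        raise ValueError("degenerate mask: background pixels are collinear")
    plane = coef[0] + coef[1] * x + coef[2] * y
    out = HeightMap(h - plane, hmap.pixel_nm, meta=dict(hmap.meta))
    out.meta["plane_coeffs"] = [float(c) for c in coef]
    return out


def lowpass_sigma_nm(cutoff_nm: float) -> float:
    """Gaussian real-space sigma giving transfer amplitude 0.5 at f = 1/cutoff.

    The transfer function of a Gaussian kernel of real-space width sigma is
    H(f) = exp(-2 pi^2 sigma^2 f^2); solving H(1/cutoff) = 1/2 gives
    sigma = cutoff * sqrt(ln 2 / 2) / pi.
    """
    return cutoff_nm * math.sqrt(math.log(2.0) / 2.0) / math.pi


def lowpass(hmap: HeightMap, cutoff_nm: float) -> HeightMap:
    """Isotropic Gaussian low-pass with half-amplitude at wavelength ``cutoff_nm``.

    The cutoff is a length scale: features of wavelength equal to the
    cutoff are attenuated to half amplitude, longer wavelengths pass, and
    the mean (DC) level is preserved.  Boundary handling is reflective.
    Cutoffs at or below twice the pixel size are under-sampled and rejected.
    """
    if not (cutoff_nm > 2.0 * hmap.pixel_nm):
        raise ValueError(
            f"cutoff {cutoff_nm} nm must exceed the Nyquist length "
            f"2*pixel_nm = {2 * hmap.pixel_nm} nm"
        )
    sigma_px = lowpass_sigma_nm(cutoff_nm) / hmap.pixel_nm
    smoothed = ndimage.gaussian_filter(hmap.heights, sigma_px, mode="reflect")
    out = HeightMap(smoothed, hmap.pixel_nm, meta=dict(hmap.meta))
    out.meta["lowpass_cutoff_nm"] = float(cutoff_nm)
    return out
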