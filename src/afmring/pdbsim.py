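"""AFM topograph simulation from atomic coordinates.

The molecular surface is the upper envelope of the atoms' van der Waals
spheres resting on the support plane z = 0; the image is the grey-scale
dilation of that surface by a sphere-capped cone probe (tip radius R,
half cone angle theta), i.e. the locus of the lowest tip apex able to
touch the surface at each lateral position.  The simulated image is then
low-pass filtered (default cutoff 3 nm) like the experimental frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgproc import HeightMap, lowpass

__all__ = [
    "VDW_RADII_NM",
    "AtomSet",
    "TipModel",
    "load_atoms",
    "sample_surface",
    "tip_profile",
    "simulate_afm",
]

#: van der Waals radii in nm per element; unknown elements fall back to 0.17
VDW_RADII_NM = {
    "C": 0.17,
    "N": 0.155,
    "O": 0.152,
    "S": 0.18,
    "H": 0.12,
    "P": 0.18,
}
DEFAULT_VDW_NM = 0.17


@dataclass
class AtomSet:
    """Spheres (center + radius) in nm, resting on the z = 0 support plane."""

    coords: np.ndarray  # (N, 3) nm
    radii: np.ndarray  # (N,) nm
    elements: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or r.shape != (c.shape[0],):
            raise ValueError("coords must be (N, 3) with matching radii")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        if np.any(r <= 0):
            raise ValueError("radii must be > 0")
        self.coords = c
        self.radii = r
        self.elements = np.asarray(self.elements)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def rest_on_plane(self) -> "AtomSet":
        """Translate so the lowest sphere touches z = 0, centered laterally."""
        c = self.coords.copy()
        c[:, 2] -= float(np.min(c[:, 2] - self.radii))
        c[:, :2] -= c[:, :2].mean(axis=0)
        return AtomSet(c, self.radii, self.elements, dict(self.meta))


@dataclass(frozen=True)
class TipModel:
    """Sphere-capped cone probe: apex radius R_tip, half cone angle (deg)."""

    R_tip: float = 0.5
    half_angle_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.R_tip < 0:
            raise ValueError("R_tip must be >= 0")
        if not (0 < self.half_angle_deg < 90):
            raise ValueError("half_angle_deg must be in (0, 90)")


def rotation_matrix(euler_deg: tuple[float, float, float]) -> np.ndarray:
    """Rotation from extrinsic x, y, z Euler angles in degrees."""
    ax, ay, az = (math.radians(a) for a in euler_deg)
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def load_atoms(
    pdb_path,
    exclude_residues: tuple[int, int] | list[tuple[int, int]] | None = None,
    chains: list[str] | None = None,
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> AtomSet:
    """Load atoms from a PDB file and place the molecule on the support plane.

    Heteroatoms and waters are excluded; ``exclude_residues`` removes
    residue-id ranges (inclusive), emulating domain truncation;
    ``chains`` restricts to the named chains.  Coordinates are converted
    to nm, rotated by the configured view, and translated so the lowest
    van der Waals sphere touches z = 0.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(pdb_path))
    atoms = pdb.get_structure(model=1)
    keep = ~atoms.hetero
    if chains is not None:
        keep &= np.isin(atoms.chain_id, chains)
    if exclude_residues is not None:
        ranges = exclude_residues
        if ranges and np.isscalar(ranges[0]):
            ranges = [tuple(ranges)]
        for lo, hi in ranges:
            keep &= ~((atoms.res_id >= lo) & (atoms.res_id <= hi))
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise ValueError("empty selection: no atoms remain")
    elements = np.char.capitalize(np.char.strip(atoms.element.astype(str)))
    radii = np.array([VDW_RADII_NM.get(e, DEFAULT_VDW_NM) for e in elements])
    coords = atoms.coord / 10.0  # A -> nm
    coords = coords @ rotation_matrix(rotation_deg).T
    aset = AtomSet(coords, radii, elements,
                   meta={"source": str(pdb_path), "rotation_deg": list(rotation_deg)})
    return aset.rest_on_plane()


def _grid(pixel_nm: float, size_px: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(size_px, dtype=float)
    c = (size_px - 1) / 2.0
    x = (idx - c) * pixel_nm
    return x[None, :], x[:, None]  # x along columns, y along rows


def sample_surface(atoms: AtomSet, pixel_nm: float = 0.1, size_px: int = 128) -> HeightMap:
    """Upper envelope of the van der Waals spheres on a zero background.

    s(x, y) = max over atoms of z_i + sqrt(r_i^2 - d^2) for lateral
    distance d <= r_i.  The molecule (plus sphere radii) must fit inside
    the frame.
    """
    x, y = _grid(pixel_nm, size_px)
    half = (size_px - 1) / 2.0 * pixel_nm
    lat = np.abs(atoms.coords[:, :2]) + atoms.radii[:, None]
    if np.any(lat > half):
        raise ValueError("molecule does not fit the frame")
    s = np.zeros((size_px, size_px))
    for (cx, cy, cz), r in zip(atoms.coords, atoms.radii):
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        inside = d2 <= r * r
        if not inside.any():
            continue
        cap = np.zeros_like(s)
        cap[inside] = cz + np.sqrt(r * r - d2[inside])
        np.maximum(s, cap, out=s)
    return HeightMap(s, pixel_nm, meta={"n_atoms": atoms.n_atoms})


def tip_profile(r, R_tip: float, half_angle_deg: float):
    """Height of the probe surface above its apex at lateral distance r.

    Spherical cap t = R - sqrt(R^2 - r^2) out to the tangent circle
    r* = R cos(theta), then the cone t = (r - R cos theta)/tan(theta)
    + R (1 - sin theta); the sphere and cone join smoothly at r*.
    """
    r = np.asarray(r, dtype=float)
    theta = math.radians(half_angle_deg)
    R = R_tip
    r_star = R * math.cos(theta)
    t = np.empty_like(r)
    sphere = r <= r_star
    t[sphere] = R - np.sqrt(np.maximum(R * R - r[sphere] ** 2, 0.0))
    t[~sphere] = (r[~sphere] - r_star) / math.tan(theta) + R * (1.0 - math.sin(theta))
    return t


def simulate_afm(
    atoms: AtomSet,
    tip: TipModel = TipModel(),
    pixel_nm: float = 0.1,
    size_px: int = 128,
    lowpass_cutoff_nm: float | None = 3.0,
) -> HeightMap:
    """Simulate an AFM topograph: surface sampling, tip dilation, low-pass.

    The image I(x) = max over x' of [s(x') - t(|x' - x|)] is the classic
    grey-scale dilation of the surface by the (inverted) tip shape;
    broadening never lowers heights and the apex height is preserved.
    ``R_tip = 0`` means an idealized infinitely sharp probe (no dilation).
    ``lowpass_cutoff_nm = None`` disables the final filter.
    """
    surf = sample_surface(atoms, pixel_nm, size_px)
    s = surf.heights
    if tip.R_tip > 0:
        theta = math.radians(tip.half_angle_deg)
        h_max = float(s.max())
        # lateral reach where the tip profile height equals the tallest feature
        r_reach = tip.R_tip * math.cos(theta) + math.tan(theta) * max(
            h_max - tip.R_tip * (1.0 - math.sin(theta)), 0.0
        )
        half_px = int(math.ceil(r_reach / pixel_nm))
        if 2 * half_px + 1 > size_px:
            raise ValueError("tip support radius exceeds the frame")
        off = np.arange(-half_px, half_px + 1, dtype=float) * pixel_nm
        rr = np.hypot(off[None, :], off[:, None])
        structure = -tip_profile(rr, tip.R_tip, tip.half_angle_deg)
        s = ndimage.grey_dilation(s, structure=structure, mode="nearest")
    out = HeightMap(s, pixel_nm, meta={
        "tip_radius_nm": tip.R_tip,
        "half_angle_deg": tip.half_angle_deg,
        "lowpass_cutoff_nm": lowpass_cutoff_nm,
    })
    if lowpass_cutoff_nm is not None:
        meta = out.meta
        out = lowpass(out, lowpass_cutoff_nm)
        out.meta.update(meta)
    return out
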