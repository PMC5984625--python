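import numpy as np
import pytest

from afmring import synthgen
from afmring.imgproc import HeightMap


@pytest.fixture(scope="session")
def round_model():
    return synthgen.make_ring_model("round")


@pytest.fixture(scope="session")
def spiral_model():
    return synthgen.make_ring_model("spiral")


@pytest.fixture(scope="session")
def round_frame(round_model):
    """Noiseless rendered wild-type round hexamer at default sampling."""
    return synthgen.render_heightmap(round_model, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def spiral_frame(spiral_model):
    return synthgen.render_heightmap(spiral_model, noise_sd=0.0, seed=0)


def make_disk(radius_nm=5.0, height=5.0, pixel_nm=0.25, size_px=96):
    """Ideal flat-topped disk on a zero background."""
    idx = np.arange(size_px, dtype=float)
    c = (size_px - 1) / 2.0
    x = (idx[None, :] - c) * pixel_nm
    y = (idx[:, None] - c) * pixel_nm
    h = np.where(np.hypot(x, y) <= radius_nm, height, 0.0)
    return HeightMap(h, pixel_nm)


def make_annulus(r_mid_nm=5.6, sigma_nm=1.8, height=8.0, pixel_nm=0.5,
                 size_px=128, azimuthal=None):
    """Gaussian-cross-section ring, optionally height-modulated in angle."""
    idx = np.arange(size_px, dtype=float)
    c = (size_px - 1) / 2.0
    x = (idx[None, :] - c) * pixel_nm
    y = (idx[:, None] - c) * pixel_nm
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    crest = height if azimuthal is None else height + azimuthal(theta)
    h = crest * np.exp(-((r - r_mid_nm) ** 2) / (2 * sigma_nm**2))
    return HeightMap(h, pixel_nm)
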