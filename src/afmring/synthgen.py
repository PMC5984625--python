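"""Synthetic HS-AFM data generator for ring-oligomer analysis.

Emulates the observables of a high-speed AFM study of an AAA+ disaggregase
(ClpB-like) hexamer: height-map movies of single ring oligomers in four
forms — round closed ring, spiral, twisted-half-spiral, and open
("worm-like") chain — plus equilibrium/kinetic titration curves.  The
generator's defaults define the study conditions (ridge circumference
35.2 nm, 10 fps, 0.5 nm/px, binding and kinetic constants); downstream
modules are tested against the generator's ground truth.

Rendering model
---------------
Each protomer occupies an arc of the ridge circle and is rendered as a
Gaussian cap in the distance to that arc (caps max-composed, since an AFM
topograph reports an envelope, not additive density).  Abutting
equal-height arcs therefore produce a smooth closed crest — the round
form — while descending crest heights produce the spiral staircase and
angular gaps produce seams and the open form.  A small per-protomer bump
adds the shallow height peaks seen on real rings without pushing the
round form over the distorted-state threshold.

All stochastic operations require an explicit integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from functools import lru_cache

import numpy as np
import pandas as pd

from . import fitkin
from .imgproc import HeightMap, Movie

__all__ = [
    "FORMS",
    "OligomerModel",
    "DynamicsModel",
    "TitrationSpec",
    "TITRATION_DEFAULTS",
    "make_ring_model",
    "render_heightmap",
    "simulate_states",
    "simulate_movie",
    "iter_movie_frames",
    "simulate_titration",
    "frame_seed",
]

FORMS = ("round", "spiral", "twisted_half_spiral", "open")

#: default ridge radius: circumference 35.2 nm (wild-type round hexamer)
DEFAULT_RIDGE_RADIUS = 35.2 / (2.0 * math.pi)


@dataclass(frozen=True)
class OligomerModel:
    """Geometry of one ring oligomer.

    ridge_radius is the distance from ring center to the protomer crest
    (nm); protomer_height the tallest crest height (nm); protomer_sigma
    the lateral Gaussian width of the crest cross-section (nm);
    height_drop the total descent of a spiral run (nm); seam_gap_deg the
    angular gap at each seam; open_gap_deg the missing arc of the open
    form; protomer_bump a shallow extra peak at each protomer center (nm).
    """

    form: str
    n_protomers: int = 6
    ridge_radius: float = DEFAULT_RIDGE_RADIUS
    protomer_height: float = 8.0
    protomer_sigma: float = 1.8
    height_drop: float = 0.0
    seam_gap_deg: float = 0.0
    open_gap_deg: float = 0.0
    protomer_bump: float = 0.15
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")
        if not (3 <= self.n_protomers <= 8):
            raise ValueError("n_protomers must be in [3, 8]")
        for name in ("ridge_radius", "protomer_height", "protomer_sigma"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("height_drop", "seam_gap_deg", "open_gap_deg", "protomer_bump"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.form == "round" and (self.height_drop != 0 or self.seam_gap_deg != 0):
            raise ValueError("round form has zero height_drop and no seams")

    @property
    def n_seams(self) -> int:
        return {"round": 0, "spiral": 1, "twisted_half_spiral": 2, "open": 0}[self.form]

    def footprint_radius(self) -> float:
        """Radius (nm) beyond which the rendered height is negligible."""
        return self.ridge_radius + 4.0 * self.protomer_sigma

    def arcs(self) -> list[tuple[float, float, float, float]]:
        """Protomer arcs as (phi0, phi1, crest0, crest1) in radians / nm.

        Crest heights interpolate linearly along each descending run; the
        round and open forms have constant crest height.
        """
        g = math.radians(self.seam_gap_deg)
        phase = math.radians(self.phase_deg)
        n = self.n_protomers
        h = self.protomer_height
        out: list[tuple[float, float, float, float]] = []

        def run(a0: float, a1: float, k: int, h_top: float, drop: float) -> None:
            """k protomer arcs spanning [a0, a1] with crest h_top -> h_top-drop."""
            for i in range(k):
                f0, f1 = i / k, (i + 1) / k
                out.append((
                    a0 + f0 * (a1 - a0),
                    a0 + f1 * (a1 - a0),
                    h_top - drop * f0,
                    h_top - drop * f1,
                ))

        if self.form == "round":
            run(phase, phase + 2 * math.pi, n, h, 0.0)
        elif self.form == "spiral":
            run(phase + g / 2, phase + 2 * math.pi - g / 2, n, h, self.height_drop)
        elif self.form == "twisted_half_spiral":
            k1 = n // 2
            k2 = n - k1
            run(phase + g / 2, phase + math.pi - g / 2, k1, h, self.height_drop)
            run(phase + math.pi + g / 2, phase + 2 * math.pi - g / 2, k2, h,
                self.height_drop)
        else:  # open
            gap = math.radians(self.open_gap_deg)
            run(phase + gap / 2, phase + 2 * math.pi - gap / 2, n, h, 0.0)
        return out


_FORM_DEFAULTS = {
    "round": {},
    "spiral": {"height_drop": 1.5, "seam_gap_deg": 10.0},
    "twisted_half_spiral": {"height_drop": 1.5, "seam_gap_deg": 10.0},
    "open": {"open_gap_deg": 120.0},
}


def make_ring_model(form: str, **overrides) -> OligomerModel:
    """Build a fully parameterized oligomer model for one of the four forms.

    Wild-type defaults: hexamer, ridge circumference 35.2 nm, crest height
    8.0 nm, lateral width 1.8 nm; spiral forms descend 1.5 nm per run with
    10 degree seams; the open form is missing a 120 degree arc.  Overrides
    must name declared model fields and be physical.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
    known = {f.name for f in fields(OligomerModel)} - {"form"}
    bad = set(overrides) - known
    if bad:
        raise ValueError(f"unknown override(s) {sorted(bad)}; known fields {sorted(known)}")
    params = dict(_FORM_DEFAULTS[form])
    params.update(overrides)
    return OligomerModel(form=form, **params)


def _height_field(model: OligomerModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Noise-free height (nm) at points (x, y) relative to the ring center."""
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    R = model.ridge_radius
    two_sigma2 = 2.0 * model.protomer_sigma**2
    h = np.zeros_like(r)
    for phi0, phi1, c0, c1 in model.arcs():
        span = phi1 - phi0
        rel = np.mod(theta - phi0, 2.0 * math.pi)
        # nearest parameter along the arc (angular clamp, wrap-aware)
        rel = np.where(rel > span + (2 * math.pi - span) / 2, rel - 2 * math.pi, rel)
        s = np.clip(rel, 0.0, span)
        u = s / span if span > 0 else s
        phi_n = phi0 + s
        d2 = r * r + R * R - 2.0 * r * R * np.cos(theta - phi_n)
        crest = c0 + (c1 - c0) * u + model.protomer_bump * np.sin(math.pi * u) ** 2
        np.maximum(h, crest * np.exp(-d2 / two_sigma2), out=h)
    return h


def render_heightmap(
    model: OligomerModel,
    pixel_nm: float = 0.5,
    size_px: int = 128,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> HeightMap:
    """Render one oligomer centered in a square frame, plus i.i.d. pixel noise.

    Heights are the max-composed protomer caps on a zero background; the
    ring must fit inside the frame with margin.  ``seed`` is mandatory
    (deterministic rendering is part of the generator contract), even at
    noise_sd = 0.
    """
    if seed is None:
        raise ValueError("seed is required for stochastic rendering")
    if not (pixel_nm > 0):
        raise ValueError("pixel_nm must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    half = (size_px - 1) / 2.0 * pixel_nm
    if model.footprint_radius() > half:
        raise ValueError(
            f"model footprint {model.footprint_radius():.1f} nm exceeds the "
            f"frame half-size {half:.1f} nm"
        )
    h = _base_frame(model, float(pixel_nm), int(size_px)).copy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        h += rng.normal(0.0, noise_sd, size=h.shape)
    return HeightMap(h, pixel_nm, meta={"form": model.form, "seed": int(seed)})


@lru_cache(maxsize=32)
def _base_frame(model: OligomerModel, pixel_nm: float, size_px: int) -> np.ndarray:
    """Cached noise-free frame of one model (movies reuse few state models)."""
    idx = np.arange(size_px, dtype=float)
    c = (size_px - 1) / 2.0
    x = (idx[None, :] - c) * pixel_nm
    y = (idx[:, None] - c) * pixel_nm
    h = _height_field(model, x, y)
    h.setflags(write=False)
    return h


# ---------------------------------------------------------------------------
# Markov-chain movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicsModel:
    """Continuous-time Markov dynamics over named oligomer states.

    ``rate_matrix[i, j]`` is the transition rate (1/s) from state i to
    state j; diagonal entries are ignored (the generator diagonal is
    minus the row sum).  Absorbing states (all-zero rows) are allowed —
    they model static rings.
    """

    states: tuple[str, ...]
    rate_matrix: np.ndarray
    frame_rate: float = 10.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        q = np.asarray(self.rate_matrix, dtype=float)
        n = len(self.states)
        if q.shape != (n, n):
            raise ValueError("rate_matrix must be square, one row per state")
        off = q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not (self.frame_rate > 0 and self.duration > 0):
            raise ValueError("frame_rate and duration must be > 0")
        object.__setattr__(self, "rate_matrix", q)

    def generator(self) -> np.ndarray:
        """Embedded generator: off-diagonal rates, rows summing to zero."""
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def simulate_states(dyn: DynamicsModel, start_state: str | None = None) -> pd.DataFrame:
    """Sample the chain with exponential dwells and discretize at the frame rate.

    Returns a DataFrame (frame, time_s, state) with the state prevailing at
    each frame time k / frame_rate.  The start state defaults to the first
    listed state.
    """
    rng = np.random.default_rng(dyn.seed)
    q = dyn.generator()
    n_frames = int(round(dyn.duration * dyn.frame_rate))
    dt = 1.0 / dyn.frame_rate
    idx = {s: i for i, s in enumerate(dyn.states)}
    state = idx[start_state] if start_state is not None else 0

    frame_states = np.empty(n_frames, dtype=object)
    t = 0.0
    k = 0
    while k < n_frames:
        lam = -q[state, state]
        if lam <= 0:
            frame_states[k:] = dyn.states[state]
            break
        dwell = rng.exponential(1.0 / lam)
        t_end = t + dwell
        while k < n_frames and k * dt < t_end:
            frame_states[k] = dyn.states[state]
            k += 1
        probs = q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = rng.choice(len(dyn.states), p=probs)
        t = t_end
    return pd.DataFrame({
        "frame": np.arange(n_frames),
        "time_s": np.arange(n_frames) * dt,
        "state": frame_states,
    })


def frame_seed(base_seed: int, frame: int) -> int:
    """Deterministic per-frame noise seed (re-render reproducibility)."""
    return (int(base_seed) * 1000003 + frame + 1) % (2**31)


def iter_movie_frames(
    dyn: DynamicsModel,
    models: dict[str, OligomerModel],
    truth: pd.DataFrame,
    pixel_nm: float = 0.5,
    size_px: int = 128,
    noise_sd: float = 0.1,
):
    """Yield rendered frames for a simulated state table, one at a time.

    Streaming companion of :func:`simulate_movie` for long records that
    should not be held in memory; frame k uses noise seed
    ``frame_seed(dyn.seed, k)``.
    """
    missing = set(dyn.states) - set(models)
    if missing:
        raise ValueError(f"no oligomer model for state(s) {sorted(missing)}")
    for k, s in enumerate(truth["state"]):
        yield render_heightmap(models[s], pixel_nm, size_px, noise_sd,
                               seed=frame_seed(dyn.seed, k))


def simulate_movie(
    dyn: DynamicsModel,
    models: dict[str, OligomerModel],
    pixel_nm: float = 0.5,
    size_px: int = 128,
    noise_sd: float = 0.1,
    start_state: str | None = None,
) -> tuple[Movie, pd.DataFrame]:
    """Render a state-switching movie and return it with the ground truth.

    Every state must map to an oligomer model.  Frame k is rendered from
    the model of the state active at time k / frame_rate with noise seed
    ``frame_seed(dyn.seed, k)``, so re-rendering the returned state table
    reproduces the movie exactly.
    """
    truth = simulate_states(dyn, start_state=start_state)
    frames = list(iter_movie_frames(dyn, models, truth, pixel_nm, size_px, noise_sd))
    movie = Movie(frames, 1.0 / dyn.frame_rate,
                  meta={"seed": int(dyn.seed), "states": list(dyn.states)})
    return movie, truth


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

#: wild-type parameter defaults per titration model (units noted per key)
TITRATION_DEFAULTS: dict[str, dict[str, float]] = {
    # fraction of closed rings vs [ATP] (uM): K_d uM, F_max fraction
    "binding_1to1": {"K_d": 9.9, "F_max": 0.60},
    # ATPase rate vs [ATP] (mM): V_max 1/s per hexamer, K_m mM, n_H
    "hill": {"V_max": 1.0, "K_m": 0.16, "n_H": 2.6},
    # transition-cycle frequency vs [ATP] (mM): f_max 1/s, K_m mM
    "michaelis_menten": {"V_max": 0.6, "K_m": 0.35},
    # direct mant-nucleotide titration (uM): site conc P_tot = 6 uM monomer
    "mant_direct": {"K_d": 4.0, "dF_max": 1.0, "P_tot": 6.0},
    # replacement titration vs [ATP] (uM)
    "mant_competition": {"K_A": 9.2, "K_M": 4.0, "M_tot": 12.5, "dF_max": 1.0},
}

_CONC_UNITS = {
    "binding_1to1": "uM",
    "hill": "mM",
    "michaelis_menten": "mM",
    "mant_direct": "uM",
    "mant_competition": "uM",
}


@dataclass(frozen=True)
class TitrationSpec:
    """A titration experiment: model name, true parameters, design and noise."""

    model: str
    concentrations: np.ndarray
    true_params: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in TITRATION_DEFAULTS:
            raise ValueError(
                f"unknown titration model {self.model!r}; "
                f"valid: {sorted(TITRATION_DEFAULTS)}"
            )
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "concentrations", c)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        params = dict(TITRATION_DEFAULTS[self.model])
        bad = set(self.true_params) - set(params)
        if bad:
            raise ValueError(f"unknown parameter(s) {sorted(bad)} for {self.model}")
        params.update(self.true_params)
        if any(v <= 0 for v in params.values()):
            raise ValueError("all true_params must be positive")
        object.__setattr__(self, "true_params", params)
        if self.seed is None:
            raise ValueError("seed is required (set noise_sd=0 for noiseless data)")


def titration_response(model: str, c: np.ndarray, p: dict[str, float]) -> np.ndarray:
    """Noise-free response of a named titration model at concentrations c."""
    if model == "binding_1to1":
        return fitkin.binding_1to1(c, p["K_d"], p["F_max"])
    if model == "hill":
        return fitkin.hill(c, p["V_max"], p["K_m"], p["n_H"])
    if model == "michaelis_menten":
        return fitkin.michaelis_menten(c, p["V_max"], p["K_m"])
    if model == "mant_direct":
        return fitkin.mant_direct(c, p["K_d"], p["dF_max"], p["P_tot"])
    if model == "mant_competition":
        return p["dF_max"] * fitkin.competition_bound_fraction(
            c, p["K_A"], p["K_M"], p["M_tot"]
        )
    raise ValueError(f"unknown titration model {model!r}")


def simulate_titration(spec: TitrationSpec) -> fitkin.TitrationCurve:
    """Evaluate the model closed form and add Gaussian response noise."""
    resp = titration_response(spec.model, spec.concentrations, spec.true_params)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        resp = resp + rng.normal(0.0, spec.noise_sd, size=resp.shape)
    return fitkin.TitrationCurve(
        spec.concentrations, resp,
        conc_unit=_CONC_UNITS[spec.model],
    )
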