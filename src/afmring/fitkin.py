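"""Equilibrium- and steady-state model fits and rate conversions.

Models
------
* 1:1 binding hyperbola          F(c) = F_max * c / (K_d + c)
* Hill                           v(c) = V_max * c^n / (K_m^n + c^n)
* Michaelis-Menten               Hill with n = 1
* single Gaussian on a histogram
* mant-nucleotide direct titration with free-ligand depletion
  (the quadratic mass-balance root for bound ligand B)
* competitive replacement of a bound fluorescent nucleotide by ATP,
  bound fraction (M/K_M) / (1 + M/K_M + A/K_A)
* NADH-coupled ATPase slope -> turnover per hexamer
* maximum sliding-window slope of a fluorescence trace (disaggregation
  rate)

All fits are unweighted nonlinear least squares with positivity bounds and
deterministic half-max initialization, so rerunning a fit on the same data
reproduces the same estimates.  Standard errors come from the covariance of
the estimates at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationCurve",
    "FitResult",
    "binding_1to1",
    "hill",
    "michaelis_menten",
    "mant_direct",
    "competition_bound_fraction",
    "competition_bound_fraction_depletion",
    "fit_binding_1to1",
    "fit_hill",
    "fit_gaussian_hist",
    "fit_mant_direct",
    "fit_competition",
    "nadh_slope_to_rate",
    "max_window_slope",
    "EPSILON_NADH_340",
]

#: NADH molar extinction coefficient at 340 nm, M^-1 cm^-1.
EPSILON_NADH_340 = 6220.0


@dataclass
class TitrationCurve:
    """Concentration-response pairs with unit tags.

    Concentrations must be non-negative; points are stored sorted by
    concentration (fits are invariant to input order).
    """

    concentration: np.ndarray
    response: np.ndarray
    conc_unit: str = "uM"
    response_unit: str = ""
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentration and response must be equal-length 1D")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        order = np.argsort(c, kind="stable")
        self.concentration = c[order]
        self.response = r[order]
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != c.shape:
                raise ValueError("weights must match data length")
            self.weights = w[order]


@dataclass
class FitResult:
    """Named parameter estimates with standard errors and diagnostics."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    message: str = ""
    extra: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def report(self) -> str:
        lines = [f"model: {self.model}", f"converged: {self.converged}"]
        for k, v in self.params.items():
            se = self.stderr.get(k, float("nan"))
            lines.append(f"  {k} = {v:.6g} +/- {se:.3g}")
        lines.append(f"  RSS = {self.rss:.6g}")
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model closed forms
# ---------------------------------------------------------------------------

def binding_1to1(c, K_d, F_max):
    c = np.asarray(c, dtype=float)
    return F_max * c / (K_d + c)


def hill(c, V_max, K_m, n):
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    nz = c > 0
    cn = np.power(c[nz], n)
    out[nz] = V_max * cn / (np.power(K_m, n) + cn)
    return out


def michaelis_menten(c, V_max, K_m):
    return hill(c, V_max, K_m, 1.0)


def mant_direct(L, K_d, dF_max, P_tot):
    """Fluorescence increase on direct titration with ligand depletion.

    B is the bound-ligand concentration from the exact 1:1 mass balance,
    B = ((P + L + K_d) - sqrt((P + L + K_d)^2 - 4 P L)) / 2,
    and the signal is dF_max * B / P_tot (fractional site occupancy scaled
    by the saturating fluorescence change).  P_tot is the binding-site
    (monomer) concentration, same unit as L and K_d.
    """
    L = np.asarray(L, dtype=float)
    s = P_tot + L + K_d
    B = (s - np.sqrt(s * s - 4.0 * P_tot * L)) / 2.0
    return dF_max * B / P_tot


def competition_bound_fraction(A, K_A, K_M, M_tot):
    """Bound fraction of the fluorescent nucleotide under ATP competition.

    Depletion-free competitive equilibrium: with free concentrations
    approximated by totals, the fraction of sites holding the fluorescent
    nucleotide M is (M/K_M) / (1 + M/K_M + A/K_A); it decreases
    monotonically with the competitor concentration A.
    """
    A = np.asarray(A, dtype=float)
    m = M_tot / K_M
    return m / (1.0 + m + A / K_A)


def competition_bound_fraction_depletion(A, K_A, K_M, M_tot, P_tot):
    """Depletion-aware competitive equilibrium, solved numerically.

    Solves the coupled mass balances P + M <-> PM (K_M), P + A <-> PA
    (K_A) for free protein per competitor concentration and returns the
    bound-M fraction of total sites.  Used as the oracle for the
    depletion-free closed form.
    """
    A = np.atleast_1d(np.asarray(A, dtype=float))
    out = np.empty_like(A)
    for i, a_tot in enumerate(A):
        def balance(p_free):
            m_free = M_tot / (1.0 + p_free / K_M)
            a_free = a_tot / (1.0 + p_free / K_A)
            return p_free * (1.0 + m_free / K_M + a_free / K_A) - P_tot
        p = optimize.brentq(balance, 0.0, P_tot, xtol=1e-12 * max(P_tot, 1.0))
        m_free = M_tot / (1.0 + p / K_M)
        out[i] = (p * m_free / K_M) / P_tot
    return out


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def _half_max_conc(curve: TitrationCurve) -> float:
    """Concentration of the data point nearest half of the maximum response."""
    r = curve.response
    target = 0.5 * np.max(r)
    idx = int(np.argmin(np.abs(r - target)))
    c = curve.concentration[idx]
    if c <= 0:
        pos = curve.concentration[curve.concentration > 0]
        c = float(np.median(pos)) if pos.size else 1.0
    return float(c)


def _curve_fit(model_name, func, curve, p0, names, bounds):
    try:
        popt, pcov = optimize.curve_fit(
            func,
            curve.concentration,
            curve.response,
            p0=p0,
            bounds=bounds,
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # non-convergence diagnostics
        return FitResult(
            model=model_name,
            params={k: float("nan") for k in names},
            stderr={k: float("nan") for k in names},
            rss=float("nan"),
            converged=False,
            message=str(exc),
        )
    resid = curve.response - func(curve.concentration, *popt)
    rss = float(np.sum(resid**2))
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    params = dict(zip(names, map(float, popt)))
    stderr = dict(zip(names, map(float, perr)))
    ok = all(np.isfinite(v) and v > 0 for v in params.values())
    return FitResult(model_name, params, stderr, rss, converged=ok)


def fit_binding_1to1(curve: TitrationCurve) -> FitResult:
    """Fit the 1:1 binding hyperbola F_max * c / (K_d + c).

    Both parameters are free; K_d is initialized at the concentration of
    the data point nearest half-maximal response.  Needs >= 3 distinct
    concentrations.
    """
    if np.unique(curve.concentration).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    p0 = [_half_max_conc(curve), float(np.max(curve.response))]
    return _curve_fit(
        "binding_1to1", binding_1to1, curve, p0, ["K_d", "F_max"], (0, np.inf)
    )


def fit_hill(curve: TitrationCurve, fix_n: float | None = None) -> FitResult:
    """Fit the Hill equation; ``fix_n=1`` gives the Michaelis-Menten fit."""
    need = 3 if fix_n is not None else 4
    if np.unique(curve.concentration).size < need:
        raise ValueError(f"need >= {need} distinct concentrations")
    vmax0 = float(np.max(curve.response))
    km0 = _half_max_conc(curve)
    if fix_n is not None:
        def func(c, V_max, K_m):
            return hill(c, V_max, K_m, fix_n)
        res = _curve_fit("hill(fixed n)", func, curve, [vmax0, km0],
                         ["V_max", "K_m"], (0, np.inf))
        res.params["n"] = float(fix_n)
        res.stderr["n"] = 0.0
        return res
    return _curve_fit("hill", hill, curve, [vmax0, km0, 1.0],
                      ["V_max", "K_m", "n"], (0, np.inf))


def fit_gaussian_hist(values, bin_width: float) -> FitResult:
    """Least-squares single Gaussian fitted to binned counts.

    Bins of the given width span the data range; reports center mu, width
    sigma and amplitude.  Needs >= 30 values with nonzero spread.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError("need >= 30 values")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all values equal")
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    p0 = [float(counts.max()), float(values.mean()), float(values.std(ddof=0))]
    span = float(values.max() - values.min())
    bounds = ([0.0, values.min(), bin_width / 10.0],
              [np.inf, values.max(), 2.0 * span])
    try:
        popt, pcov = optimize.curve_fit(gauss, centers, counts, p0=p0,
                                        bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        return FitResult("gaussian", {}, {}, float("nan"), False, str(exc))
    popt[2] = abs(popt[2])
    resid = counts - gauss(centers, *popt)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    names = ["amplitude", "mu", "sigma"]
    return FitResult(
        "gaussian",
        dict(zip(names, map(float, popt))),
        dict(zip(names, map(float, np.abs(perr)))),
        float(np.sum(resid**2)),
        converged=bool(np.isfinite(popt).all()),
    )


def fit_mant_direct(curve: TitrationCurve, P_tot: float) -> FitResult:
    """Fit the depletion-aware direct titration; P_tot (site conc.) is known."""
    if not (P_tot > 0):
        raise ValueError("P_tot must be > 0")

    def func(L, K_d, dF_max):
        return mant_direct(L, K_d, dF_max, P_tot)

    p0 = [_half_max_conc(curve), float(np.max(curve.response))]
    res = _curve_fit("mant_direct", func, curve, p0, ["K_d", "dF_max"], (0, np.inf))
    res.extra["P_tot"] = float(P_tot)
    return res


def fit_competition(
    curve: TitrationCurve,
    P_tot: float,
    M_tot: float,
    K_M: float,
    depletion: bool = False,
) -> FitResult:
    """Fit the competitive replacement titration; free parameters K_A, amplitude.

    ``curve`` holds bound-nucleotide fluorescence vs competitor (ATP)
    concentration; K_M comes from a prior direct fit.  The default model
    is the depletion-free closed form; ``depletion=True`` switches to the
    numerical equilibrium solve (slower, used as the cross-check).
    """
    if not (P_tot > 0 and M_tot > 0 and K_M > 0):
        raise ValueError("P_tot, M_tot and K_M must be > 0")

    if depletion:
        def func(A, K_A, amp):
            return amp * competition_bound_fraction_depletion(A, K_A, K_M, M_tot, P_tot)
    else:
        def func(A, K_A, amp):
            return amp * competition_bound_fraction(A, K_A, K_M, M_tot)

    f0 = competition_bound_fraction(0.0, 1.0, K_M, M_tot)
    amp0 = float(np.max(curve.response)) / f0 if f0 > 0 else 1.0
    p0 = [_half_max_conc(curve), amp0]
    res = _curve_fit("competition", func, curve, p0, ["K_A", "amplitude"], (0, np.inf))
    res.extra.update(P_tot=float(P_tot), M_tot=float(M_tot), K_M=float(K_M),
                     depletion=depletion)
    return res


def nadh_slope_to_rate(
    slope_A340_per_s: float,
    enzyme_conc_uM: float = 0.25,
    path_cm: float = 1.0,
    epsilon: float = EPSILON_NADH_340,
) -> float:
    """Convert an NADH absorbance slope (A340/s) to ATP turnover per hexamer (1/s).

    In the coupled assay one NADH is oxidized per ATP hydrolyzed, so the
    turnover is |slope| / (epsilon * path) / [enzyme].  The slope must be
    <= 0 (absorbance falls during hydrolysis); the enzyme concentration is
    on the hexamer basis in uM (assay default 0.25 uM hexamer).
    """
    if slope_A340_per_s > 0:
        raise ValueError("hydrolysis slope must be <= 0 (A340 decreases)")
    if not (enzyme_conc_uM > 0):
        raise ValueError("enzyme concentration must be > 0")
    rate_M_per_s = -slope_A340_per_s / (epsilon * path_cm)
    return rate_M_per_s / (enzyme_conc_uM * 1e-6)


def max_window_slope(
    time_s,
    signal,
    window_s: float = 60.0,
    horizon_s: float = 300.0,
) -> tuple[float, float]:
    """Maximum least-squares slope over all windows inside the horizon.

    Every window of length ``window_s`` starting at a sample time and lying
    entirely within [0, horizon_s] is fitted by least squares; the maximum
    slope and its window start time are returned.  The default (60 s
    windows in the first 300 s) is the standard readout of an aggregate
    disaggregation trace.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and signal must be equal-length 1D")
    if t.size < 2 or t[-1] - t[0] < window_s:
        raise ValueError("trace shorter than one window")
    best = -np.inf
    best_start = t[0]
    for i, t0 in enumerate(t):
        if t0 + window_s > min(horizon_s, t[-1]) + 1e-9:
            break
        sel = (t >= t0 - 1e-9) & (t <= t0 + window_s + 1e-9)
        if sel.sum() < 2:
            continue
        slope = np.polyfit(t[sel], y[sel], 1)[0]
        if slope > best:
            best, best_start = float(slope), float(t0)
    if not np.isfinite(best):
        raise ValueError("no complete window inside the horizon")
    return best, best_start
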