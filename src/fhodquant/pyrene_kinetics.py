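"""Bulk pyrene-assay quantification.

Nucleation strength is measured as the slope of an assembly curve at
t_1/8, the time at which the reaction has reached one eighth of
completion, and the "specific activity" of a formin construct is the
slope of those slopes against formin concentration.  Barbed-end affinity
is measured from seeded-elongation assays by fitting normalized initial
rates to the tight-binding (quadratic) occupancy model

    r = a + b * (S - sqrt(S^2 - 4 [BE][F])),   S = [BE] + [F] + K_d,

where [BE] is the barbed-end concentration, [F] the formin (dimer)
concentration, and a, b are offset and scaling constants (the bracket
equals 2 [BE] theta, so b absorbs the 1/(2 [BE]) factor relating it to
the bound-versus-free rate difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .types import PolymerizationTrace

__all__ = [
    "NucleationActivity",
    "BindingFitResult",
    "estimate_baseline_plateau",
    "time_to_fraction",
    "slope_at_time",
    "nucleation_strength",
    "seeded_elongation_rate",
    "quadratic_occupancy",
    "quadratic_binding_model",
    "fit_quadratic_binding",
]


class ThresholdNotReachedError(ValueError):
    """Raised when a trace never crosses the requested completion fraction."""


class ConvergenceError(RuntimeError):
    """Raised when the binding fit fails from every starting point."""


@dataclass(frozen=True)
class NucleationActivity:
    """Specific nucleation activity of one construct from a dose series."""

    specific_activity: float  # a.u./s per nM formin
    intercept: float  # a.u./s
    r_squared: float
    n: int


@dataclass(frozen=True)
class BindingFitResult:
    """Tight-binding fit of normalized seeded-elongation rates."""

    k_app_nm: float
    a: float
    b: float
    k_app_se: float
    a_se: float
    b_se: float
    n_points: int
    sse: float

    @property
    def identifiable(self) -> bool:
        """False when the dose response is too flat to pin down K_app."""
        return np.isfinite(self.k_app_se) and self.k_app_se < 10 * max(self.k_app_nm, 1e-12)


def estimate_baseline_plateau(
    trace: PolymerizationTrace,
    baseline_frac: float = 0.02,
    plateau_frac: float = 0.05,
) -> tuple[float, float]:
    """Baseline (mean of first ``baseline_frac``) and plateau (mean of last
    ``plateau_frac``) of a trace."""
    n = trace.n
    nb = max(1, int(round(baseline_frac * n)))
    np_ = max(1, int(round(plateau_frac * n)))
    return float(np.mean(trace.value[:nb])), float(np.mean(trace.value[-np_:]))


def time_to_fraction(
    trace: PolymerizationTrace,
    fraction: float = 1 / 8,
    *,
    baseline_frac: float = 0.02,
    plateau_frac: float = 0.05,
    smooth_window: int = 1,
) -> float:
    """First time the trace crosses ``fraction`` of completion.

    Completion is measured between the baseline (mean of the first 2% of
    samples) and the plateau (mean of the last 5%); the crossing is
    linearly interpolated between samples.  ``smooth_window`` > 1 applies
    a centered moving average before thresholding (useful on noisy data).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    baseline, plateau = estimate_baseline_plateau(trace, baseline_frac, plateau_frac)
    if plateau <= baseline:
        raise ThresholdNotReachedError("trace has no rise between baseline and plateau")
    y = trace.value
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    threshold = baseline + fraction * (plateau - baseline)
    above = np.nonzero(y >= threshold)[0]
    if above.size == 0:
        raise ThresholdNotReachedError(
            f"trace never reaches {fraction:.3g} of completion (threshold {threshold:.3g})"
        )
    i = int(above[0])
    if i == 0:
        return float(trace.time_s[0])
    t0, t1 = trace.time_s[i - 1], trace.time_s[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def slope_at_time(trace: PolymerizationTrace, t: float, window_s: float) -> float:
    """Least-squares slope of value versus time over a window centered on ``t``."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    lo, hi = t - window_s / 2, t + window_s / 2
    if lo < trace.time_s[0] or hi > trace.time_s[-1]:
        raise ValueError(
            f"window [{lo:.3g}, {hi:.3g}] s extends outside trace "
            f"[{trace.time_s[0]:.3g}, {trace.time_s[-1]:.3g}] s"
        )
    mask = (trace.time_s >= lo) & (trace.time_s <= hi)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    res = stats.linregress(trace.time_s[mask], trace.value[mask])
    return float(res.slope)


def nucleation_strength(measurements: list[tuple[float, float]]) -> NucleationActivity:
    """Fit slope-at-t_1/8 versus formin concentration by OLS.

    ``measurements`` are (formin_conc_nm, slope_at_t18) pairs; the fitted
    slope is the construct's specific nucleation activity in a.u./s per nM.
    """
    concs = np.array([m[0] for m in measurements], dtype=float)
    slopes = np.array([m[1] for m in measurements], dtype=float)
    if np.unique(concs).size < 3:
        raise ValueError("need at least 3 distinct formin concentrations")
    res = stats.linregress(concs, slopes)
    r2 = float(res.rvalue**2) if np.std(slopes) > 0 else 1.0
    return NucleationActivity(
        specific_activity=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n=concs.size,
    )


def seeded_elongation_rate(
    trace: PolymerizationTrace,
    reference: PolymerizationTrace | None = None,
    window_s: float = 90.0,
) -> tuple[float, float | None]:
    """Elongation rate by linear regression over the first ``window_s`` seconds.

    Returns (rate, normalized_rate); the normalized rate divides by the
    rate of the actin-alone ``reference`` trace and is None without one.
    """
    span = trace.time_s[-1] - trace.time_s[0]
    if span < window_s:
        raise ValueError(f"trace spans {span:.3g} s < required {window_s:.3g} s")
    mask = trace.time_s <= trace.time_s[0] + window_s
    rate = float(stats.linregress(trace.time_s[mask], trace.value[mask]).slope)
    if reference is None:
        return rate, None
    ref_rate, _ = seeded_elongation_rate(reference, None, window_s)
    if ref_rate <= 0:
        raise ValueError("reference (actin-alone) rate must be > 0")
    return rate, rate / ref_rate


def quadratic_occupancy(formin_nm: float, barbed_ends_nm: float, k_d_nm: float) -> float:
    """Fractional occupancy of barbed ends under tight-binding kinetics.

    theta = (S - sqrt(S^2 - 4 [BE][F])) / (2 [BE]), S = [BE] + [F] + K_d.
    Valid without the free-ligand approximation, i.e. when K_d is
    comparable to or below the receptor concentration.
    """
    if formin_nm < 0 or barbed_ends_nm <= 0 or k_d_nm < 0:
        raise ValueError("concentrations must be >= 0 and barbed_ends_nm > 0")
    s = barbed_ends_nm + formin_nm + k_d_nm
    disc = s * s - 4.0 * barbed_ends_nm * formin_nm
    bracket = s - np.sqrt(max(disc, 0.0))
    return float(bracket / (2.0 * barbed_ends_nm))


def quadratic_binding_model(
    formin_nm: np.ndarray | float,
    barbed_ends_nm: float,
    k_d_nm: float,
    a: float,
    b: float,
) -> np.ndarray | float:
    """Normalized elongation rate r = a + b (S - sqrt(S^2 - 4 [BE][F]))."""
    f = np.asarray(formin_nm, dtype=float)
    if np.any(f < 0) or barbed_ends_nm < 0 or k_d_nm < 0:
        raise ValueError("concentrations must be >= 0")
    s = barbed_ends_nm + f + k_d_nm
    disc = np.maximum(s * s - 4.0 * barbed_ends_nm * f, 0.0)
    r = a + b * (s - np.sqrt(disc))
    return float(r) if np.isscalar(formin_nm) else r


def fit_quadratic_binding(
    points: list[tuple[float, float]],
    barbed_ends_nm: float,
    *,
    k_d_starts_nm: np.ndarray | None = None,
) -> BindingFitResult:
    """Nonlinear least squares for (K_d, a, b) with K_d >= 0.

    Multistarts over log-spaced K_d initial guesses (default 1e-3 to 1e2
    nM, 6 starts) and keeps the best converged solution.  Standard errors
    come from the Jacobian at the optimum; on flat (no dose response)
    data the fit returns b ~ 0 with a very wide K_d standard error rather
    than failing.
    """
    concs = np.array([p[0] for p in points], dtype=float)
    rates = np.array([p[1] for p in points], dtype=float)
    if np.unique(concs).size < 4:
        raise ValueError("need at least 4 distinct formin concentrations")
    if barbed_ends_nm <= 0:
        raise ValueError("barbed_ends_nm must be > 0")
    if k_d_starts_nm is None:
        k_d_starts_nm = np.logspace(-3, 2, 6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        k_d, a, b = theta
        return quadratic_binding_model(concs, barbed_ends_nm, k_d, a, b) - rates

    a0 = float(rates[np.argmin(concs)])
    best = None
    for k0 in k_d_starts_nm:
        # crude linear init for b from the span of the bracket term
        bracket = quadratic_binding_model(concs, barbed_ends_nm, k0, 0.0, 1.0)
        span = np.ptp(bracket)
        b0 = (rates[np.argmax(concs)] - a0) / span if span > 0 else 0.0
        try:
            sol = optimize.least_squares(
                residuals,
                x0=[k0, a0, b0],
                bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(2 * sol.cost)
        if best is None or sse < best[1]:
            best = (sol, sse)
    if best is None:
        raise ConvergenceError(
            f"quadratic binding fit failed from all {len(k_d_starts_nm)} starts "
            f"(n={concs.size}, [BE]={barbed_ends_nm} nM)"
        )
    sol, sse = best
    dof = max(concs.size - 3, 1)
    sigma2 = sse / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.inf)
    return BindingFitResult(
        k_app_nm=float(sol.x[0]),
        a=float(sol.x[1]),
        b=float(sol.x[2]),
        k_app_se=float(ses[0]),
        a_se=float(ses[1]),
        b_se=float(ses[2]),
        n_points=int(concs.size),
        sse=sse,
    )
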