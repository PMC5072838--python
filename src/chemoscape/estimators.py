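"""Phenotype estimators for the raw assay tables.

Turns timed cell counts, capillary pre/post counts, and per-cell swimming
speeds into the phenotypes the landscape consumes: intrinsic growth rates
(log-linear and logistic fits), chemotactic abilities (delta log-ratio
enrichment), motility summaries (motile fraction and motile mean), and
speed-vs-chemotaxis regressions.

Units: time in hours, speeds in micrometres per second, all logs natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from chemoscape.competition import logistic_closed_form

__all__ = [
    "TimedCounts",
    "CapillaryAssayCounts",
    "SpeedSample",
    "MotilitySummary",
    "GrowthRateFit",
    "LogisticFit",
    "LinearFit",
    "growth_rate_log_linear",
    "fit_logistic_growth",
    "chemotaxis_from_capillary",
    "motility_summary",
    "speed_vs_chemotaxis_fit",
]


class EstimationError(ValueError):
    """Raised when an estimate is undefined for the given data."""


@dataclass(frozen=True)
class TimedCounts:
    """Cell counts in a fixed sampled volume at a series of times (hours)."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise EstimationError("times and counts must be matching 1-d arrays")
        if np.any(c < 0):
            raise EstimationError("counts must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class CapillaryAssayCounts:
    """Counts of two marked competitors before and after capillary incubation."""

    pre_mutant: float
    pre_ancestor: float
    post_mutant: float
    post_ancestor: float


@dataclass(frozen=True)
class SpeedSample:
    """Per-cell swimming speeds (um/s) at one time point of the growth cycle."""

    speeds: np.ndarray
    time_in_cycle: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.speeds, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise EstimationError("speeds must be a non-empty 1-d array")
        if np.any(s < 0):
            raise EstimationError("speeds must be non-negative")
        object.__setattr__(self, "speeds", s)


@dataclass(frozen=True)
class MotilitySummary:
    """Decomposition of a speed sample into motile fraction and means.

    ``motile_mean`` is None when no cell exceeds the threshold.  Satisfies
    ``mean_speed = f * motile_mean + (1 - f) * nonmotile_mean``.
    """

    mean_speed: float
    motile_fraction: float
    motile_mean: float | None
    nonmotile_mean: float | None
    threshold: float
    n_cells: int


@dataclass(frozen=True)
class GrowthRateFit:
    """Slope of ln(counts) against time with its standard error."""

    rate: float
    rate_se: float
    intercept: float
    n: int


@dataclass(frozen=True)
class LogisticFit:
    """Logistic growth parameters with convergence diagnostics."""

    r: float
    K: float
    N0: float
    converged: bool
    ill_conditioned: bool
    rss: float


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    through_origin: bool


def growth_rate_log_linear(samples: TimedCounts) -> GrowthRateFit:
    """Growth rate as the OLS slope of log-transformed counts against time.

    Exact on noiseless exponentials; the standard error comes from the
    residual variance and is zero for an exact fit.
    """
    t, c = samples.times, samples.counts
    if np.unique(t).size < 2:
        raise EstimationError("need counts at >= 2 distinct times")
    if np.any(c <= 0):
        raise EstimationError("zero count encountered; cannot take logs")
    y = np.log(c)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = t.size
    if n > 2:
        sigma2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((t - t.mean()) ** 2))
        se = math.sqrt(sigma2 / sxx)
    else:
        se = 0.0
    return GrowthRateFit(rate=float(beta[1]), rate_se=se, intercept=float(beta[0]), n=n)


def fit_logistic_growth(
    samples: TimedCounts,
    p0: tuple[float, float, float] | None = None,
) -> LogisticFit:
    """Nonlinear least-squares fit of the logistic growth curve.

    Fits ``N(t) = K*N0*e^{rt} / (K + N0*(e^{rt}-1))`` for (r, K, N0).  The fit
    is flagged ill-conditioned when the data do not constrain the carrying
    capacity — no point reaches half the fitted K, or the K standard error
    exceeds the estimate.
    """
    t, c = samples.times, samples.counts
    if t.size < 4:
        raise EstimationError("logistic fit needs >= 4 time points")
    if np.any(c <= 0):
        raise EstimationError("counts must be positive for a logistic fit")

    if p0 is None:
        n0_guess = float(c[np.argmin(t)])
        k_guess = float(2.0 * c.max())
        span = float(t.max() - t.min())
        ratio = max(float(c.max()) / n0_guess, 1.01)
        r_guess = math.log(ratio) / max(span, 1e-9)
        p0 = (r_guess, k_guess, n0_guess)

    def model(tt, r, K, N0):
        return logistic_closed_form(tt, r, K, N0)

    try:
        popt, pcov = curve_fit(
            model,
            t,
            c,
            p0=p0,
            bounds=([1e-9, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise EstimationError(f"logistic fit did not converge from p0={p0}: {exc}") from exc

    r_hat, k_hat, n0_hat = (float(v) for v in popt)
    resid = c - model(t, *popt)
    rss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    ill = bool(c.max() < 0.5 * k_hat or not np.isfinite(k_se) or k_se > abs(k_hat))
    return LogisticFit(
        r=r_hat, K=k_hat, N0=n0_hat, converged=True, ill_conditioned=ill, rss=rss
    )


def chemotaxis_from_capillary(
    assay: CapillaryAssayCounts, pseudo_count: float = 0.0
) -> float:
    """Chemotactic ability as the change in log count ratio across incubation.

    ``ln(post_mutant/post_ancestor) - ln(pre_mutant/pre_ancestor)``: the
    log-enrichment of the mutant relative to the ancestor among cells that
    entered the capillary.  Dilution-invariant; antisymmetric under swapping
    the strain labels.  Zero counts are an error unless an explicit
    ``pseudo_count`` is supplied.
    """
    counts = [assay.pre_mutant, assay.pre_ancestor, assay.post_mutant, assay.post_ancestor]
    if pseudo_count < 0:
        raise EstimationError("pseudo_count must be non-negative")
    counts = [c + pseudo_count for c in counts]
    if min(counts) <= 0:
        raise EstimationError(
            "zero count makes the log-ratio undefined; pass pseudo_count=0.5 to regularise"
        )
    pm, pa, qm, qa = counts
    return math.log(qm / qa) - math.log(pm / pa)


def motility_summary(sample: SpeedSample, threshold: float = 5.0) -> MotilitySummary:
    """Split a speed sample into motile and non-motile components.

    A cell counts as motile when its speed exceeds ``threshold`` (um/s).  The
    default 5 um/s separates Brownian jiggle from flagellar swimming.
    """
    if threshold <= 0:
        raise EstimationError("threshold must be positive")
    s = sample.speeds
    motile = s > threshold
    frac = float(motile.mean())
    mean_speed = float(s.mean())
    motile_mean = float(s[motile].mean()) if motile.any() else None
    nonmotile_mean = float(s[~motile].mean()) if (~motile).any() else None
    return MotilitySummary(
        mean_speed=mean_speed,
        motile_fraction=frac,
        motile_mean=motile_mean,
        nonmotile_mean=nonmotile_mean,
        threshold=threshold,
        n_cells=int(s.size),
    )


def speed_vs_chemotaxis_fit(
    chemotaxis, speeds, through_origin: bool = False
) -> LinearFit:
    """Linear regression of population mean speed on chemotactic ability.

    With ``through_origin`` the intercept is fixed at zero and R-squared uses
    the uncentred total sum of squares (conventions differ; this one keeps
    R-squared in [0, 1] for the no-intercept model).
    """
    c = np.asarray(chemotaxis, dtype=float)
    v = np.asarray(speeds, dtype=float)
    if c.shape != v.shape or c.ndim != 1:
        raise EstimationError("chemotaxis and speed arrays must match")
    min_n = 1 if through_origin else 2
    if c.size < min_n:
        raise EstimationError(f"need >= {min_n} points")
    if through_origin:
        denom = float(c @ c)
        if denom == 0:
            raise EstimationError("degenerate predictor (all zero)")
        slope = float(c @ v) / denom
        intercept = 0.0
        resid = v - slope * c
        ss_tot = float(v @ v)
    else:
        if np.ptp(c) == 0:
            raise EstimationError("degenerate predictor (zero variance)")
        X = np.column_stack([np.ones_like(c), c])
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        intercept, slope = float(beta[0]), float(beta[1])
        resid = v - X @ beta
        ss_tot = float(np.sum((v - v.mean()) ** 2))
    ss_res = float(resid @ resid)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearFit(
        slope=slope,
        intercept=intercept,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n=int(c.size),
        through_origin=through_origin,
    )
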