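"""Fitness surface, selective gradients, Pareto front and constrained optimum.

The adaptive landscape is per-cycle relative fitness plotted over the two
phenotype differences between an evolving mutant and its ancestor: the
chemotactic-ability difference ``c`` and the intrinsic growth-rate difference
``r``.  The surface is additively separable — growth selection depends only on
``r`` and capillary selection only on ``c`` — so a grid of ``n_c x n_r`` nodes
requires only ``n_r`` ODE integrations.

Selective gradients are the mean forward difference of the surface along each
axis divided by the step, which on a plane equals the exact slope.  The Pareto
front is an ordinary least-squares line of ``c`` on ``r`` through the isolate
phenotypes that sit on the trade-off boundary; the constrained optimum
maximises cycle fitness along that line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from chemoscape.competition import (
    CONVENTIONS,
    CompetitionError,
    CompetitionParams,
    chemotaxis_selection_coefficient,
    cycle_fitness,
    growth_selection_coefficient,
    integrate_competition,
)

__all__ = [
    "LandscapeGrid",
    "FitnessSurface",
    "Gradients",
    "PhenotypePoint",
    "ParetoFront",
    "OptimumPoint",
    "SensitivitySurface",
    "METHODS_GRID",
    "fitness_surface",
    "selective_gradients",
    "fit_pareto_front",
    "optimum_on_front",
    "rk_sensitivity",
]


@dataclass(frozen=True)
class LandscapeGrid:
    """Inclusive rectangular grid over (chemotaxis diff, growth-rate diff)."""

    c_min: float = -1.0
    c_max: float = 8.0
    c_step: float = 0.2
    r_min: float = -0.2
    r_max: float = 0.3
    r_step: float = 0.025

    def __post_init__(self) -> None:
        if self.c_step <= 0 or self.r_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.c_max <= self.c_min or self.r_max <= self.r_min:
            raise ValueError("grid max must exceed min on both axes")
        if self.c_step > self.c_max - self.c_min or self.r_step > self.r_max - self.r_min:
            raise ValueError("grid step exceeds axis range")
        if len(self.c_values) < 2 or len(self.r_values) < 2:
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def c_values(self) -> np.ndarray:
        n = int(round((self.c_max - self.c_min) / self.c_step))
        return self.c_min + self.c_step * np.arange(n + 1)

    @property
    def r_values(self) -> np.ndarray:
        n = int(round((self.r_max - self.r_min) / self.r_step))
        return self.r_min + self.r_step * np.arange(n + 1)


#: The grid spanning the phenotype space traversed by the evolving
#: populations: c from -1 to 8 step 0.2, r from -0.2 to 0.3 step 0.025.
METHODS_GRID = LandscapeGrid()


@dataclass(frozen=True)
class FitnessSurface:
    """Per-cycle relative fitness on a grid; ``w[i, j]`` at (c_i, r_j)."""

    grid: LandscapeGrid
    w: np.ndarray
    baseline: CompetitionParams
    convention: str
    normalization_hours: float

    def __post_init__(self) -> None:
        expected = (len(self.grid.c_values), len(self.grid.r_values))
        if self.w.shape != expected:
            raise ValueError(f"surface shape {self.w.shape} != grid shape {expected}")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("surface contains non-finite values")


@dataclass(frozen=True)
class Gradients:
    """Mean selective gradients along the chemotaxis and growth axes."""

    dw_dc: float
    dw_dr: float


@dataclass(frozen=True)
class PhenotypePoint:
    """One isolate's phenotype relative to the ancestor."""

    r_diff: float
    c_diff: float
    r_err: float = 0.0
    c_err: float = 0.0
    week: int = 0


@dataclass(frozen=True)
class ParetoFront:
    """OLS line ``c = intercept + slope * r`` through trade-off isolates."""

    intercept: float
    slope: float
    r_squared: float
    n_points: int

    def c_at(self, r) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(r, dtype=float)


@dataclass(frozen=True)
class OptimumPoint:
    """Fitness maximum constrained to the Pareto front line."""

    c_opt: float
    r_opt: float
    w_opt: float


@dataclass(frozen=True)
class SensitivitySurface:
    """End-of-growth competition outcome f over (r, k) with finite differences."""

    r_values: np.ndarray
    k_values: np.ndarray
    f: np.ndarray
    df_dr: np.ndarray
    df_dk: np.ndarray
    step: float


def _growth_selection_vs_baseline(
    r_diff: float, baseline: CompetitionParams, rtol: float, atol: float
) -> float:
    r_m = baseline.r_w + r_diff
    if r_m <= 0:
        raise CompetitionError(
            f"mutant growth rate {r_m:.4g} <= 0 at growth difference {r_diff:.4g}"
        )
    params = CompetitionParams(
        r_m=r_m,
        r_w=baseline.r_w,
        m0=baseline.m0,
        w0=baseline.w0,
        k=baseline.k,
        t_growth=baseline.t_growth,
    )
    return growth_selection_coefficient(integrate_competition(params, rtol=rtol, atol=atol))


def fitness_surface(
    grid: LandscapeGrid = METHODS_GRID,
    baseline: CompetitionParams | None = None,
    convention: str = "gradient",
    normalization_hours: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> FitnessSurface:
    """Tabulate per-cycle relative fitness over a phenotype-difference grid.

    Growth selection ``s_g`` is computed once per growth-difference column by
    integrating the two-strain competition (separability), so the default
    46 x 21 grid costs 21 integrations.

    Parameters
    ----------
    grid
        Phenotype-difference grid; defaults to the standard analysis grid.
    baseline
        Ancestor parameters; mutant rate at column j is ``r_w + r_j``.
        Defaults to a 1:1 inoculum at 1/2000 of capacity with r_w = 1.0 h^-1.
    convention
        Chemotaxis-selection convention, ``"gradient"`` (s_c = c) or
        ``"main_text"`` (s_c = 0.5 c).
    normalization_hours
        Cycle duration dividing (s_g + s_c); defaults per convention
        (11.5 h for ``gradient``, 12 h for ``main_text``).
    """
    if baseline is None:
        baseline = CompetitionParams()
    if convention not in CONVENTIONS:
        raise CompetitionError(
            f"unknown convention {convention!r}; expected one of {sorted(CONVENTIONS)}"
        )
    if normalization_hours is None:
        normalization_hours = CONVENTIONS[convention][1]

    c_vals = grid.c_values
    r_vals = grid.r_values
    s_g = np.array(
        [_growth_selection_vs_baseline(r, baseline, rtol, atol) for r in r_vals]
    )
    s_c = np.array([chemotaxis_selection_coefficient(c, convention) for c in c_vals])
    w = (s_c[:, None] + s_g[None, :]) / normalization_hours
    return FitnessSurface(
        grid=grid,
        w=w,
        baseline=baseline,
        convention=convention,
        normalization_hours=normalization_hours,
    )


def selective_gradients(surface: FitnessSurface) -> Gradients:
    """Average selective gradient of the surface along each phenotype axis.

    Each gradient is the mean of all forward differences between adjacent
    nodes along that axis, divided by the axis step.  On a linear surface this
    recovers the exact slope; on the smooth near-planar competition surface it
    summarises the overall strength of selection on each trait.
    """
    w = surface.w
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError("gradients need at least 2 nodes per axis")
    dw_dc = float(np.mean(np.diff(w, axis=0)) / surface.grid.c_step)
    dw_dr = float(np.mean(np.diff(w, axis=1)) / surface.grid.r_step)
    return Gradients(dw_dc=dw_dc, dw_dr=dw_dr)


def fit_pareto_front(points) -> ParetoFront:
    """OLS regression of chemotaxis difference on growth-rate difference.

    Parameters
    ----------
    points
        Sequence of :class:`PhenotypePoint`, or of ``(r_diff, c_diff)`` pairs.
    """
    rs, cs = [], []
    for p in points:
        if isinstance(p, PhenotypePoint):
            rs.append(p.r_diff)
            cs.append(p.c_diff)
        else:
            r, c = p
            rs.append(float(r))
            cs.append(float(c))
    r = np.asarray(rs, dtype=float)
    c = np.asarray(cs, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 points to fit a front")
    if np.ptp(r) == 0:
        raise ValueError("growth-difference values must not all be equal")

    X = np.column_stack([np.ones_like(r), r])
    beta, *_ = np.linalg.lstsq(X, c, rcond=None)
    resid = c - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ParetoFront(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=int(r.size),
    )


def optimum_on_front(
    front: ParetoFront,
    baseline: CompetitionParams | None = None,
    r_bounds: tuple[float, float] = (-0.2, 0.3),
    convention: str = "gradient",
    normalization_hours: float | None = None,
    n_coarse: int = 201,
    fitness_fn=None,
) -> OptimumPoint:
    """Maximise cycle fitness along the Pareto front line.

    A coarse scan over ``r`` in ``r_bounds`` locates the best candidate, which
    is then refined by a bounded one-dimensional search between its
    neighbours.  Ties within 1e-9 of the maximum resolve to the lowest growth
    difference.

    ``fitness_fn`` may replace the competition model with any callable
    ``f(r, c) -> w`` (used for analytic test surfaces).
    """
    if baseline is None:
        baseline = CompetitionParams()
    if normalization_hours is None:
        normalization_hours = CONVENTIONS[convention][1]
    lo, hi = r_bounds
    if not (math.isfinite(lo) and math.isfinite(hi)) or hi <= lo:
        raise ValueError("r_bounds must be a finite increasing pair")
    if fitness_fn is None:
        if baseline.r_w + lo <= 0:
            raise ValueError("lower r bound implies non-positive mutant growth rate")

        def fitness_fn(r: float, c: float) -> float:
            s_g = _growth_selection_vs_baseline(r, baseline, 1e-8, 1e-12)
            s_c = chemotaxis_selection_coefficient(c, convention)
            return cycle_fitness(s_g, s_c, normalization_hours)

    def w_on_line(r: float) -> float:
        return fitness_fn(r, front.intercept + front.slope * r)

    r_scan = np.linspace(lo, hi, n_coarse)
    w_scan = np.array([w_on_line(r) for r in r_scan])
    # tie rule: lowest r within 1e-9 of the max
    best = int(np.flatnonzero(w_scan >= w_scan.max() - 1e-9)[0])
    a = r_scan[max(best - 1, 0)]
    b = r_scan[min(best + 1, n_coarse - 1)]
    candidates = [(float(w_scan[best]), float(r_scan[best]))]
    if b > a:
        res = minimize_scalar(lambda r: -w_on_line(r), bounds=(a, b), method="bounded")
        candidates.append((float(-res.fun), float(res.x)))
    w_max = max(w for w, _ in candidates)
    # among candidates tied within 1e-9 of the max, the lowest r wins
    r_opt = min(r for w, r in candidates if w >= w_max - 1e-9)
    return OptimumPoint(
        c_opt=float(front.intercept + front.slope * r_opt),
        r_opt=r_opt,
        w_opt=float(w_on_line(r_opt)),
    )


def rk_sensitivity(
    r_values,
    k_values,
    w0: float = 1.0 / 2000.0,
    m0: float | None = None,
    t: float = 11.5,
    r_baseline: float = 1.0,
    step: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SensitivitySurface:
    """End-of-growth competition outcome over mutant (rate, capacity) values.

    For each node the mutant grows as ``dm/dt = r*m*(1 - (m+w)/k)`` against a
    fixed baseline competitor (``dw/dt = r_baseline*w*(1 - m - w)``, capacity
    1); the outcome ``f(r, k)`` is the change in the natural-log mutant to
    baseline ratio over ``t`` hours.  Derivatives are forward differences at
    the given step along each axis (arrays one node shorter on that axis).
    """
    r_values = np.asarray(r_values, dtype=float)
    k_values = np.asarray(k_values, dtype=float)
    if np.any(k_values <= 0):
        raise CompetitionError("capacity values must be positive")
    if np.any(r_values <= 0):
        raise CompetitionError("rate values must be positive")
    if t <= 0 or step <= 0:
        raise CompetitionError("t and step must be positive")
    if m0 is None:
        m0 = w0

    def f_at(r: float, k: float) -> float:
        def rhs(_t, y):
            m, w = y
            return [r * m * (1.0 - (m + w) / k), r_baseline * w * (1.0 - m - w)]

        sol = solve_ivp(rhs, (0.0, t), [m0, w0], rtol=rtol, atol=atol, method="RK45")
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        m_T, w_T = sol.y[:, -1]
        return math.log(m_T / w_T) - math.log(m0 / w0)

    n_r, n_k = len(r_values), len(k_values)
    f = np.array([[f_at(r, k) for k in k_values] for r in r_values])
    df_dr = np.array(
        [[(f_at(r + step, k) - f_at(r, k)) / step for k in k_values] for r in r_values[:-1]]
    ).reshape(max(n_r - 1, 0), n_k)
    df_dk = np.array(
        [[(f_at(r, k + step) - f_at(r, k)) / step for k in k_values[:-1]] for r in r_values]
    ).reshape(n_r, max(n_k - 1, 0))
    return SensitivitySurface(
        r_values=r_values, k_values=k_values, f=f, df_dr=df_dr, df_dk=df_dk, step=step
    )
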