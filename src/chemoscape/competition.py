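"""Two-strain Lotka-Volterra competition and per-cycle selection coefficients.

One selection cycle consists of batch growth to late exponential phase
followed by a brief capillary-chemotaxis competition.  Growth selection is
obtained by integrating the competition ODEs

    dm/dt = r_m * m * (1 - (m + w)/k)
    dw/dt = r_w * w * (1 - (m + w)/k)

where ``m`` and ``w`` are mutant and wildtype abundances normalised to the
carrying capacity ``k``.  Chemotaxis selection is a log-enrichment applied at
the end of growth.  Both are natural-log selection coefficients per cycle;
their sum divided by the cycle duration is the per-hour relative fitness.

Two bookkeeping conventions for the chemotaxis term are supported (see
:func:`chemotaxis_selection_coefficient`); ``"main_text"`` maps a chemotactic
ability difference ``c`` to ``s_c = 0.5*c`` with a 12-hour cycle, while
``"gradient"`` uses ``s_c = c`` with the 11.5-hour growth phase as divisor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "CompetitionParams",
    "CompetitionTrajectory",
    "SelectionSummary",
    "CONVENTIONS",
    "integrate_competition",
    "growth_selection_coefficient",
    "chemotaxis_selection_coefficient",
    "cycle_fitness",
    "selection_summary",
    "calibrate_ancestral_rate",
    "logistic_closed_form",
]

#: Supported chemotaxis-selection conventions mapped to
#: (s_c multiplier, default normalization hours).
CONVENTIONS = {
    "main_text": (0.5, 12.0),
    "gradient": (1.0, 11.5),
}


class CompetitionError(ValueError):
    """Invalid competition parameters or degenerate trajectory."""


@dataclass(frozen=True)
class CompetitionParams:
    """Parameters of one two-strain batch competition.

    Abundances are fractions of the carrying capacity ``k``; rates are per
    hour.  The default initial condition is a 1:1 mix inoculated at 1/2000 of
    carrying capacity in total (the serial-transfer dilution), which reaches
    ~98% of capacity after 11.5 h at the default ancestral rate of 1.0 h^-1.
    """

    r_m: float = 1.0
    r_w: float = 1.0
    m0: float = 1.0 / 4000.0
    w0: float = 1.0 / 4000.0
    k: float = 1.0
    t_growth: float = 11.5

    def __post_init__(self) -> None:
        for name in ("r_m", "r_w", "m0", "w0", "k", "t_growth"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise CompetitionError(f"{name} must be finite, got {v!r}")
        if self.m0 <= 0 or self.w0 <= 0:
            raise CompetitionError("initial abundances must be positive")
        if self.k <= 0:
            raise CompetitionError("carrying capacity k must be positive")
        if self.m0 + self.w0 >= self.k:
            raise CompetitionError("initial abundances must sum to less than k")
        if self.t_growth <= 0:
            raise CompetitionError("t_growth must be positive")


@dataclass(frozen=True)
class CompetitionTrajectory:
    """Time course of a two-strain competition."""

    times: np.ndarray
    m_t: np.ndarray
    w_t: np.ndarray
    params: CompetitionParams

    @property
    def total(self) -> np.ndarray:
        return self.m_t + self.w_t

    def terminal(self) -> tuple[float, float]:
        return float(self.m_t[-1]), float(self.w_t[-1])


@dataclass(frozen=True)
class SelectionSummary:
    """Per-cycle selection decomposition for one competitor pair."""

    s_g: float
    s_c: float
    c_m_minus_c_w: float
    fitness: float
    normalization_hours: float
    convention: str = "main_text"


def logistic_closed_form(t, r: float, k: float, n0: float):
    """Logistic growth ``N(t) = k*n0*e^{rt} / (k + n0*(e^{rt}-1))``.

    Exact solution for the total population when both strains share the same
    intrinsic rate; used as an integration oracle and in logistic curve fits.
    """
    ert = np.exp(r * np.asarray(t, dtype=float))
    return k * n0 * ert / (k + n0 * (ert - 1.0))


def integrate_competition(
    params: CompetitionParams,
    n_steps: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> CompetitionTrajectory:
    """Integrate the two-strain Lotka-Volterra competition over one growth phase.

    Uses an adaptive explicit Runge-Kutta scheme; ``n_steps`` controls only the
    reported time grid, not the internal step size.

    Parameters
    ----------
    params
        Validated competition parameters.
    n_steps
        Number of output intervals between 0 and ``t_growth``.
    rtol, atol
        Integrator tolerances.

    Returns
    -------
    CompetitionTrajectory
        Abundances of both strains on an inclusive time grid.
    """
    if params.r_m <= 0 or params.r_w <= 0:
        raise CompetitionError(
            f"growth rates must be positive (r_m={params.r_m}, r_w={params.r_w})"
        )
    if n_steps < 1:
        raise CompetitionError("n_steps must be >= 1")

    k = params.k

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        m, w = y
        sat = 1.0 - (m + w) / k
        return [params.r_m * m * sat, params.r_w * w * sat]

    t_eval = np.linspace(0.0, params.t_growth, n_steps + 1)
    sol = solve_ivp(
        rhs,
        (0.0, params.t_growth),
        [params.m0, params.w0],
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    m_t, w_t = sol.y
    if m_t[-1] <= 0 or w_t[-1] <= 0:
        raise RuntimeError("integration produced non-positive terminal abundance")
    return CompetitionTrajectory(times=sol.t, m_t=m_t, w_t=w_t, params=params)


def growth_selection_coefficient(traj: CompetitionTrajectory) -> float:
    """Growth-phase selection ``s_g = ln(m_T/w_T) - ln(m_0/w_0)``.

    The change in the natural-log abundance ratio of mutant to wildtype over
    the growth phase.  Zero when the strains share a growth rate; antisymmetric
    under exchanging the strains.
    """
    m_T, w_T = traj.terminal()
    m_0, w_0 = float(traj.m_t[0]), float(traj.w_t[0])
    if min(m_T, w_T, m_0, w_0) <= 0:
        raise CompetitionError("abundances must be positive to form log ratios")
    return math.log(m_T / w_T) - math.log(m_0 / w_0)


def chemotaxis_selection_coefficient(c_diff: float, convention: str = "main_text") -> float:
    """Capillary-phase selection from a chemotactic-ability difference.

    ``main_text`` applies ``s_c = 0.5 * c_diff``; ``gradient`` applies
    ``s_c = c_diff`` (the scaling under which the chemotaxis axis of the
    fitness surface is the full per-cycle selection).
    """
    if not math.isfinite(c_diff):
        raise CompetitionError(f"c_diff must be finite, got {c_diff!r}")
    try:
        mult, _ = CONVENTIONS[convention]
    except KeyError:
        raise CompetitionError(
            f"unknown convention {convention!r}; expected one of {sorted(CONVENTIONS)}"
        ) from None
    return mult * c_diff


def cycle_fitness(s_g: float, s_c: float, normalization_hours: float = 12.0) -> float:
    """Per-hour relative fitness ``w = (s_g + s_c) / T`` over one full cycle."""
    if not (math.isfinite(s_g) and math.isfinite(s_c)):
        raise CompetitionError("selection coefficients must be finite")
    if normalization_hours <= 0:
        raise CompetitionError("normalization_hours must be positive")
    return (s_g + s_c) / normalization_hours


def selection_summary(
    params: CompetitionParams,
    c_diff: float,
    convention: str = "main_text",
    normalization_hours: float | None = None,
) -> SelectionSummary:
    """Full per-cycle selection decomposition for one mutant/wildtype pair."""
    if normalization_hours is None:
        normalization_hours = CONVENTIONS[convention][1]
    traj = integrate_competition(params)
    s_g = growth_selection_coefficient(traj)
    s_c = chemotaxis_selection_coefficient(c_diff, convention)
    return SelectionSummary(
        s_g=s_g,
        s_c=s_c,
        c_m_minus_c_w=c_diff,
        fitness=cycle_fitness(s_g, s_c, normalization_hours),
        normalization_hours=normalization_hours,
        convention=convention,
    )


def calibrate_ancestral_rate(
    n0_total: float = 1.0 / 2000.0,
    target_fraction: float = 0.99,
    t_growth: float = 11.5,
    k: float = 1.0,
) -> float:
    """Ancestral growth rate at which a culture reaches a target saturation.

    Inverts the logistic closed form: returns the rate ``r`` such that a
    culture inoculated at ``n0_total`` reaches ``target_fraction * k`` after
    ``t_growth`` hours.  With the defaults this gives r close to 1.06 h^-1;
    an inoculum of 1/2000 growing at exactly 1.0 h^-1 reaches ~98% of
    capacity in 11.5 h.
    """
    if not 0 < n0_total < k:
        raise CompetitionError("n0_total must lie in (0, k)")
    if not n0_total / k < target_fraction < 1:
        raise CompetitionError("target_fraction must lie in (n0_total/k, 1)")

    def gap(r: float) -> float:
        return float(logistic_closed_form(t_growth, r, k, n0_total)) - target_fraction * k

    return brentq(gap, 1e-6, 10.0, xtol=1e-12)
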