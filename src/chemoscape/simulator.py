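"""Serial-transfer evolution simulator with a growth/motility trade-off.

Simulates the cyclical selection experiment: multi-strain Lotka-Volterra
batch growth, capillary selection for chemotaxis, a 2048-fold bottleneck, and
mutation.  A genotype allocates a fraction ``u`` of its resources to motility;
investment costs growth (``r_eff = r_base * (1 - gamma * u_growth)``) and buys
chemotactic ability (``c_eff = c_free + c_max * u_select``).  Non-plastic
genotypes hold one allocation for the whole cycle (``u_growth == u_select``),
which confines them to a straight trade-off front in phenotype-difference
space; a rare plasticity mutation unlocks the two allocations from each
other, letting a lineage grow with low motility investment yet swim at
selection time — the behavioural innovation that breaks through the front.

The ``c_free`` trait models chemotaxis gains that carry no measurable growth
cost (the experiment's first adaptive phase); it is capped, after which
further gains must be bought on the trade-off.

The mutation kernel (Gaussian trait steps reflected into [0, 1], a rare
plasticity unlock) is a modelling choice: the experiment identifies mutations
only post hoc, so mutational supply here is an effective parameterisation,
not a measured quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from chemoscape.competition import (
    CONVENTIONS,
    CompetitionParams,
    chemotaxis_selection_coefficient,
    cycle_fitness,
    growth_selection_coefficient,
    integrate_competition,
)
from chemoscape.landscape import OptimumPoint, ParetoFront, optimum_on_front

__all__ = [
    "Genotype",
    "TradeoffModel",
    "PopulationState",
    "CyclePlan",
    "MutationModel",
    "SimulationConfig",
    "CycleOutcome",
    "EvolutionRecord",
    "PhaseReport",
    "ExtinctionError",
    "effective_traits",
    "step_cycle",
    "run_experiment",
    "measure_selection",
    "doublings_per_cycle",
    "total_generations",
    "tradeoff_front",
    "detect_phases",
]


class ExtinctionError(RuntimeError):
    """The whole population was lost at a bottleneck."""


@dataclass(frozen=True)
class Genotype:
    """One lineage's heritable strategy.

    ``u_growth`` is the motility investment expressed during batch growth,
    ``u_select`` the investment expressed at capillary-selection time.  They
    must be equal unless ``plastic`` is set.  ``c_free`` is chemotactic
    ability acquired without growth cost.
    """

    u_growth: float = 0.0
    u_select: float = 0.0
    plastic: bool = False
    r_base: float = 1.0
    c_free: float = 0.0

    def __post_init__(self) -> None:
        for u in (self.u_growth, self.u_select):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"investments must lie in [0, 1], got {u}")
        if not self.plastic and self.u_growth != self.u_select:
            raise ValueError("non-plastic genotype must have u_growth == u_select")
        if self.r_base <= 0:
            raise ValueError("r_base must be positive")
        if self.c_free < 0:
            raise ValueError("c_free must be non-negative")


@dataclass(frozen=True)
class TradeoffModel:
    """Linear resource-partitioning trade-off between growth and motility.

    ``gamma`` is the relative growth cost of full motility investment and
    ``c_max`` the chemotactic ability bought by full investment, so the
    non-plastic sweep of ``u`` traces the line with slope
    ``-c_max / (gamma * r_base)`` in (growth diff, chemotaxis diff) space.
    The defaults (gamma 0.25, c_max 2.4, ancestral rate 1.0) give the
    empirical front slope of -9.6; ``c_free_max`` (2.7) is its intercept.
    """

    gamma: float = 0.25
    c_max: float = 2.4
    c_free_max: float = 2.7

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.c_max <= 0:
            raise ValueError("c_max must be positive")
        if self.c_free_max < 0:
            raise ValueError("c_free_max must be non-negative")


def effective_traits(g: Genotype, model: TradeoffModel) -> tuple[float, float]:
    """Realised (growth rate, chemotactic ability) of a genotype.

    ``r_eff = r_base * (1 - gamma * u_growth)``;
    ``c_eff = c_free + c_max * u_select``.
    """
    r_eff = g.r_base * (1.0 - model.gamma * g.u_growth)
    c_eff = g.c_free + model.c_max * g.u_select
    return r_eff, c_eff


def tradeoff_front(model: TradeoffModel, ancestor: Genotype) -> ParetoFront:
    """The trade-off line in phenotype-difference space, as a ParetoFront.

    Image of the non-plastic ``u`` sweep (at saturated ``c_free``) expressed
    as differences from the ancestor: a line with slope
    ``-c_max / (gamma * r_base)`` and intercept ``c_free_max`` (when the
    ancestor sits at u = 0, c_free = 0).
    """
    r_anc, c_anc = effective_traits(ancestor, model)
    slope = -model.c_max / (model.gamma * ancestor.r_base)
    # c_diff at r_diff = 0 for a genotype with c_free at cap
    intercept = (model.c_free_max - c_anc) + slope * (ancestor.r_base - r_anc)
    return ParetoFront(intercept=intercept, slope=slope, r_squared=1.0, n_points=2)


@dataclass(frozen=True)
class CyclePlan:
    """Timing and dilution of one selection cycle."""

    t_growth: float = 11.5
    capillary_hours: float = 0.5
    dilution_factor: float = 2048.0
    cycles_total: int = 150
    cycles_per_week: int = 14

    def __post_init__(self) -> None:
        if min(self.t_growth, self.capillary_hours) <= 0:
            raise ValueError("durations must be positive")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.cycles_total < 1 or self.cycles_per_week < 1:
            raise ValueError("cycle counts must be positive")


def doublings_per_cycle(dilution_factor: float = 2048.0) -> float:
    """Population doublings needed to regrow after one dilution: log2(D)."""
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    return math.log2(dilution_factor)


def total_generations(plan: CyclePlan) -> float:
    """Generations over the whole experiment: cycles x doublings per cycle."""
    return plan.cycles_total * doublings_per_cycle(plan.dilution_factor)


@dataclass(frozen=True)
class MutationModel:
    """Effective mutational supply for the simulator.

    ``rate_per_cycle`` is the expected number of mutation events per cycle in
    the whole population; ``step_sd`` the Gaussian step scale on the
    allocation traits (reflected into [0, 1]); ``free_step_sd`` the step on
    cost-free chemotaxis (clipped to its cap); ``p_plasticity`` the chance a
    mutation unlocks plasticity; ``r_step_sd`` an optional step on the base
    growth rate.
    """

    rate_per_cycle: float = 1.0
    step_sd: float = 0.5
    free_step_sd: float = 0.9
    p_plasticity: float = 0.1
    r_step_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_per_cycle < 0:
            raise ValueError("rate_per_cycle must be non-negative")
        if self.step_sd <= 0 or self.free_step_sd < 0 or self.r_step_sd < 0:
            raise ValueError("step scales must be non-negative (step_sd positive)")
        if not 0.0 <= self.p_plasticity <= 1.0:
            raise ValueError("p_plasticity must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationState:
    """Lineages with abundances as fractions of carrying capacity."""

    genotypes: tuple[Genotype, ...]
    abundances: np.ndarray
    cycle_index: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if len(self.genotypes) != a.size:
            raise ValueError("genotypes and abundances must align")
        if np.any(a < 0):
            raise ValueError("abundances must be non-negative")
        if a.sum() > 1.0 + 1e-9:
            raise ValueError("total abundance must not exceed carrying capacity")
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "abundances", a)

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.abundances.sum()
        if tot == 0:
            raise ExtinctionError("population is extinct")
        return self.abundances / tot

    def index_of(self, g: Genotype) -> int:
        try:
            return self.genotypes.index(g)
        except ValueError:
            raise KeyError(f"genotype not present: {g}") from None


@dataclass(frozen=True)
class CycleOutcome:
    """One cycle's intermediate states, for selection decomposition."""

    pre: PopulationState
    post_growth: PopulationState
    post_selection: PopulationState
    post_bottleneck: PopulationState
    events: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a reproducible experiment run needs except the seed."""

    plan: CyclePlan = field(default_factory=CyclePlan)
    tradeoff: TradeoffModel = field(default_factory=TradeoffModel)
    mutation: MutationModel = field(default_factory=MutationModel)
    ancestor: Genotype = field(default_factory=Genotype)
    census: float | None = 1e5
    convention: str = "gradient"
    isolates_per_week: int = 6
    noise_r: float = 0.01
    noise_c: float = 0.15

    def __post_init__(self) -> None:
        if self.census is not None and self.census < 10:
            raise ValueError("census must be >= 10 (or None for deterministic)")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.isolates_per_week < 1:
            raise ValueError("isolates_per_week must be positive")


def _grow(
    pop: PopulationState, plan: CyclePlan, tradeoff: TradeoffModel
) -> PopulationState:
    """Multi-strain Lotka-Volterra growth with shared saturation."""
    rates = np.array(
        [effective_traits(g, tradeoff)[0] for g in pop.genotypes]
    )

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return rates * y * (1.0 - y.sum())

    sol = solve_ivp(
        rhs,
        (0.0, plan.t_growth),
        pop.abundances,
        rtol=1e-8,
        atol=1e-14,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"growth integration failed: {sol.message}")
    grown = np.clip(sol.y[:, -1], 0.0, None)
    return PopulationState(pop.genotypes, grown, pop.cycle_index)


def _select(
    pop: PopulationState, tradeoff: TradeoffModel, convention: str
) -> PopulationState:
    """Capillary selection: reweight each lineage by exp(s_c(c_eff))."""
    c_eff = np.array([effective_traits(g, tradeoff)[1] for g in pop.genotypes])
    s_c = np.array(
        [chemotaxis_selection_coefficient(c, convention) for c in c_eff]
    )
    s_c = s_c - s_c.max()  # stabilise; only relative weights matter
    weighted = pop.abundances * np.exp(s_c)
    tot = weighted.sum()
    if tot <= 0:
        raise ExtinctionError("no cells entered the capillary")
    # keep the pre-selection total: the capillary changes composition, the
    # bottleneck changes scale
    weighted *= pop.abundances.sum() / tot
    return PopulationState(pop.genotypes, weighted, pop.cycle_index)


def _bottleneck(
    pop: PopulationState,
    plan: CyclePlan,
    census: float | None,
    rng: np.random.Generator | None,
) -> PopulationState:
    """Dilute into fresh medium; finite census resamples lineage frequencies."""
    new_total = pop.abundances.sum() / plan.dilution_factor
    freqs = pop.frequencies
    if census is None:
        keep = freqs > 1e-12
        genotypes = tuple(g for g, k in zip(pop.genotypes, keep) if k)
        freqs = freqs[keep] / freqs[keep].sum()
    else:
        if rng is None:
            raise ValueError("finite census requires an rng")
        counts = rng.multinomial(int(census), freqs)
        if counts.sum() == 0:
            raise ExtinctionError("all lineages lost at the bottleneck")
        keep = counts > 0
        genotypes = tuple(g for g, k in zip(pop.genotypes, keep) if k)
        freqs = counts[keep] / counts.sum()
    return PopulationState(genotypes, new_total * freqs, pop.cycle_index + 1)


def _mutate_genotype(
    g: Genotype, tradeoff: TradeoffModel, model: MutationModel, rng: np.random.Generator
) -> tuple[Genotype, str]:
    """Apply one mutation event to a genotype; returns (mutant, event label)."""

    def reflect01(x: float) -> float:
        # reflect a Gaussian step back into [0, 1]
        x = math.fmod(x, 2.0)
        if x < 0:
            x += 2.0
        return 2.0 - x if x > 1.0 else x

    plastic = g.plastic
    label = "trait"
    if not plastic and rng.random() < model.p_plasticity:
        plastic = True
        label = "plasticity_unlock"
    if rng.random() < 0.5 and g.c_free < tradeoff.c_free_max and model.free_step_sd > 0:
        c_free = min(
            max(g.c_free + rng.normal(0.0, model.free_step_sd), 0.0),
            tradeoff.c_free_max,
        )
        return replace(g, c_free=c_free, plastic=plastic), (
            label if label != "trait" else "c_free"
        )
    if plastic:
        if rng.random() < 0.5:
            u_growth = reflect01(g.u_growth + rng.normal(0.0, model.step_sd))
            u_select = g.u_select
        else:
            u_growth = g.u_growth
            u_select = reflect01(g.u_select + rng.normal(0.0, model.step_sd))
    else:
        u = reflect01(g.u_growth + rng.normal(0.0, model.step_sd))
        u_growth = u_select = u
    r_base = g.r_base
    if model.r_step_sd > 0:
        r_base = max(r_base + rng.normal(0.0, model.r_step_sd), 1e-3)
    return (
        Genotype(
            u_growth=u_growth,
            u_select=u_select,
            plastic=plastic,
            r_base=r_base,
            c_free=g.c_free,
        ),
        label,
    )


def _mutate(
    pop: PopulationState,
    tradeoff: TradeoffModel,
    model: MutationModel,
    census: float | None,
    rng: np.random.Generator,
) -> tuple[PopulationState, tuple[str, ...]]:
    n_events = rng.poisson(model.rate_per_cycle)
    if n_events == 0:
        return pop, ()
    genotypes = list(pop.genotypes)
    abund = pop.abundances.copy()
    events: list[str] = []
    mutant_frac = 1.0 / census if census is not None else 1e-4
    total = abund.sum()
    for _ in range(n_events):
        freqs = abund / abund.sum()
        parent = int(rng.choice(len(genotypes), p=freqs))
        take = min(mutant_frac * total, abund[parent])
        if take <= 0:
            continue
        mutant, label = _mutate_genotype(genotypes[parent], tradeoff, model, rng)
        abund[parent] -= take
        genotypes.append(mutant)
        abund = np.append(abund, take)
        events.append(f"mutation:{label}")
    keep = abund > 0
    return (
        PopulationState(
            tuple(g for g, k in zip(genotypes, keep) if k),
            abund[keep],
            pop.cycle_index,
        ),
        tuple(events),
    )


def step_cycle(
    pop: PopulationState,
    plan: CyclePlan,
    tradeoff: TradeoffModel,
    mutation: MutationModel | None = None,
    rng: np.random.Generator | int | None = None,
    census: float | None = 1e5,
    convention: str = "gradient",
) -> CycleOutcome:
    """Run one full selection cycle: growth, capillary, bottleneck, mutation.

    With ``census=None`` the bottleneck is deterministic (infinite census) and
    lineage frequencies are preserved exactly through dilution, making the
    per-cycle change in any log abundance ratio equal to ``s_g + s_c`` from
    the competition model.  Reproducible bit-for-bit given the same rng seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if rng is None and (census is not None or mutation is not None):
        raise ValueError("stochastic stages need an rng or integer seed")
    grown = _grow(pop, plan, tradeoff)
    selected = _select(grown, tradeoff, convention)
    bottled = _bottleneck(selected, plan, census, rng)
    events: tuple[str, ...] = ()
    if mutation is not None and mutation.rate_per_cycle > 0:
        bottled, events = _mutate(bottled, tradeoff, mutation, census, rng)
    return CycleOutcome(
        pre=pop,
        post_growth=grown,
        post_selection=selected,
        post_bottleneck=bottled,
        events=events,
    )


def measure_selection(
    pop_before: PopulationState,
    pop_after: PopulationState,
    focal: Genotype,
    reference: Genotype,
) -> float:
    """Per-cycle selection of ``focal`` against ``reference``.

    The change in natural-log abundance ratio across whatever happened between
    the two states; both genotypes must be present in both.
    """
    i0, j0 = pop_before.index_of(focal), pop_before.index_of(reference)
    i1, j1 = pop_after.index_of(focal), pop_after.index_of(reference)
    before = pop_before.abundances
    after = pop_after.abundances
    if min(before[i0], before[j0], after[i1], after[j1]) <= 0:
        raise ValueError("zero abundance; selection coefficient undefined")
    return math.log(after[i1] / after[j1]) - math.log(before[i0] / before[j0])


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvolutionRecord:
    """Output of a full serial-transfer run."""

    trajectory: pd.DataFrame
    weekly: pd.DataFrame
    isolates: pd.DataFrame
    events: tuple[str, ...]
    front: ParetoFront
    optimum: OptimumPoint
    config: SimulationConfig
    extinct: bool = False


def _mean_phenotype(
    pop: PopulationState, tradeoff: TradeoffModel, ancestor: Genotype
) -> tuple[float, float, float]:
    r_anc, c_anc = effective_traits(ancestor, tradeoff)
    freqs = pop.frequencies
    r_diff = c_diff = plastic = 0.0
    for g, f in zip(pop.genotypes, freqs):
        r_eff, c_eff = effective_traits(g, tradeoff)
        r_diff += f * (r_eff - r_anc)
        c_diff += f * (c_eff - c_anc)
        plastic += f * g.plastic
    return r_diff, c_diff, plastic


class _GrowthSelectionCache:
    """Memoised s_g(r_diff) against the run's ancestral baseline."""

    def __init__(self, r_anc: float, plan: CyclePlan) -> None:
        self.baseline = CompetitionParams(
            r_m=r_anc, r_w=r_anc, t_growth=plan.t_growth
        )
        self._cache: dict[float, float] = {}

    def __call__(self, r_diff: float) -> float:
        key = round(r_diff, 9)
        if key not in self._cache:
            params = replace(self.baseline, r_m=self.baseline.r_w + r_diff)
            self._cache[key] = growth_selection_coefficient(
                integrate_competition(params)
            )
        return self._cache[key]


def run_experiment(
    config: SimulationConfig | None = None, rng_seed: int = 0
) -> EvolutionRecord:
    """Run the full serial-transfer experiment.

    Records the per-cycle lineage table, weekly population summaries (mean
    phenotype differences from the ancestor, mean fitness, plastic fraction),
    weekly sampled isolates with measurement noise, and an event log noting
    plasticity fixation and any breakthrough beyond the trade-off front.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(rng_seed)
    plan, tradeoff, ancestor = config.plan, config.tradeoff, config.ancestor
    r_anc, _ = effective_traits(ancestor, tradeoff)
    front = tradeoff_front(tradeoff, ancestor)
    optimum = optimum_on_front(
        front,
        baseline=CompetitionParams(r_m=r_anc, r_w=r_anc, t_growth=plan.t_growth),
        r_bounds=(-tradeoff.gamma * ancestor.r_base + 1e-9, 0.0),
        convention=config.convention,
    )
    s_g_of = _GrowthSelectionCache(r_anc, plan)
    norm_hours = CONVENTIONS[config.convention][1]

    pop = PopulationState((ancestor,), np.array([1.0 / plan.dilution_factor]))
    traj_rows: list[dict] = []
    weekly_rows: list[dict] = []
    isolate_rows: list[dict] = []
    events: list[str] = []
    extinct = False
    plastic_fixed_at: int | None = None

    for cycle in range(plan.cycles_total):
        try:
            outcome = step_cycle(
                pop,
                plan,
                tradeoff,
                mutation=config.mutation,
                rng=rng,
                census=config.census,
                convention=config.convention,
            )
        except ExtinctionError as exc:
            events.append(f"cycle {cycle}: extinction ({exc})")
            extinct = True
            break
        pop = outcome.post_bottleneck
        for label in outcome.events:
            if label == "mutation:plasticity_unlock":
                events.append(f"cycle {cycle}: plasticity mutation arose")
        freqs = pop.frequencies
        for gid, (g, f) in enumerate(zip(pop.genotypes, freqs)):
            r_eff, c_eff = effective_traits(g, tradeoff)
            traj_rows.append(
                {
                    "cycle": pop.cycle_index,
                    "genotype": gid,
                    "abundance": pop.abundances[gid],
                    "frequency": f,
                    "r_eff": r_eff,
                    "c_eff": c_eff,
                    "u_growth": g.u_growth,
                    "u_select": g.u_select,
                    "plastic": g.plastic,
                }
            )
        r_diff, c_diff, plastic_frac = _mean_phenotype(pop, tradeoff, ancestor)
        if plastic_fixed_at is None and plastic_frac >= 0.5:
            plastic_fixed_at = pop.cycle_index
            events.append(f"cycle {pop.cycle_index}: plasticity reached majority")

        is_week_end = (cycle + 1) % plan.cycles_per_week == 0 or cycle == plan.cycles_total - 1
        if is_week_end:
            week = (cycle + 1 + plan.cycles_per_week - 1) // plan.cycles_per_week
            mean_fitness = 0.0
            for g, f in zip(pop.genotypes, freqs):
                r_eff, c_eff = effective_traits(g, tradeoff)
                s_g = s_g_of(r_eff - r_anc)
                s_c = chemotaxis_selection_coefficient(
                    c_eff - effective_traits(ancestor, tradeoff)[1], config.convention
                )
                mean_fitness += f * cycle_fitness(s_g, s_c, norm_hours)
            residual = c_diff - front.c_at(r_diff)
            weekly_rows.append(
                {
                    "week": week,
                    "cycle": pop.cycle_index,
                    "mean_r_diff": r_diff,
                    "mean_c_diff": c_diff,
                    "mean_fitness": mean_fitness,
                    "plastic_fraction": plastic_frac,
                    "front_residual": float(residual),
                }
            )
            if plastic_fixed_at is not None and residual > 0.5:
                events.append(
                    f"cycle {pop.cycle_index}: breakthrough beyond the front "
                    f"(residual {residual:.2f})"
                )
            picks = rng.choice(len(pop.genotypes), size=config.isolates_per_week, p=freqs)
            for iso, gi in enumerate(picks):
                g = pop.genotypes[int(gi)]
                r_eff, c_eff = effective_traits(g, tradeoff)
                isolate_rows.append(
                    {
                        "week": week,
                        "isolate": iso,
                        "r_diff": r_eff - r_anc + rng.normal(0.0, config.noise_r),
                        "c_diff": c_eff
                        - effective_traits(ancestor, tradeoff)[1]
                        + rng.normal(0.0, config.noise_c),
                        "plastic": g.plastic,
                    }
                )

    return EvolutionRecord(
        trajectory=pd.DataFrame(traj_rows),
        weekly=pd.DataFrame(weekly_rows),
        isolates=pd.DataFrame(isolate_rows),
        events=tuple(events),
        front=front,
        optimum=optimum,
        config=config,
        extinct=extinct,
    )


@dataclass(frozen=True)
class PhaseReport:
    """Detection of the three qualitative phases in a run's weekly summary."""

    phase1: bool
    phase2: bool
    phase3: bool
    phase1_weeks: tuple[int, ...]
    phase2_weeks: tuple[int, ...]
    phase3_weeks: tuple[int, ...]

    @property
    def all_detected(self) -> bool:
        return self.phase1 and self.phase2 and self.phase3


def detect_phases(
    record: EvolutionRecord,
    c_gain_min: float = 0.5,
    r_flat_tol: float = 0.12,
    r_band: float = 0.1,
    c_band: float = 1.0,
    residual_min: float = 0.5,
) -> PhaseReport:
    """Classify weekly summaries into the three adaptive phases.

    Phase 1: before plasticity reaches a majority, chemotaxis has risen by at
    least ``c_gain_min`` while the mean growth difference stays within
    ``r_flat_tol`` of zero.  Phase 2: the mean phenotype sits within
    (``r_band``, ``c_band``) of the constrained optimum on the front.
    Phase 3: after plasticity reaches a majority, the mean phenotype lies
    more than ``residual_min`` above the front line.
    """
    wk = record.weekly
    opt = record.optimum
    p1 = wk[
        (wk.mean_c_diff >= c_gain_min)
        & (wk.mean_r_diff.abs() <= r_flat_tol)
        & (wk.plastic_fraction < 0.5)
    ]
    p2 = wk[
        ((wk.mean_r_diff - opt.r_opt).abs() <= r_band)
        & ((wk.mean_c_diff - opt.c_opt).abs() <= c_band)
    ]
    p3 = wk[(wk.plastic_fraction >= 0.5) & (wk.front_residual >= residual_min)]
    return PhaseReport(
        phase1=len(p1) > 0,
        phase2=len(p2) > 0,
        phase3=len(p3) > 0,
        phase1_weeks=tuple(int(w) for w in p1.week),
        phase2_weeks=tuple(int(w) for w in p2.week),
        phase3_weeks=tuple(int(w) for w in p3.week),
    )
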