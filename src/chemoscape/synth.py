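"""Synthetic-data generators emulating the four assay types.

Every pipeline stage can be exercised without real measurements: timed
flow-cytometry-like counts (Poisson noise around exponential growth),
capillary pre/post counts for two marked competitors (multinomial enrichment),
per-cell swimming-speed samples (motile/non-motile mixtures with
time-of-cycle schedules), and weekly isolate phenotype panels shaped by a
linear Pareto front with three adaptive phases.

Each generator has a zero-noise mode (``rng=None``) on which the matching
estimator is exact, and is bit-reproducible given a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chemoscape.competition import chemotaxis_selection_coefficient
from chemoscape.estimators import CapillaryAssayCounts, SpeedSample, TimedCounts
from chemoscape.landscape import ParetoFront

__all__ = [
    "ArchetypeProfile",
    "PanelSpec",
    "ARCHETYPES",
    "make_growth_counts",
    "make_capillary_counts",
    "make_speed_sample",
    "make_isolate_panel",
    "make_speed_chemotaxis_pairs",
]

#: Time anchors (hours) for the piecewise-linear motility schedules.
SCHEDULE_TIMES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 11.5)


@dataclass(frozen=True)
class ArchetypeProfile:
    """Motility behaviour of one strain archetype over the growth cycle.

    Schedules are piecewise-linear over :data:`SCHEDULE_TIMES`.  The ancestor
    swims fastest mid-cycle and slows near capacity; mid-experiment clones
    swim faster than the ancestor nearly the whole time; late (plastic)
    clones suppress motility during rapid growth and boost it as the carrying
    capacity is approached.
    """

    name: str
    motile_fraction_by_time: tuple[float, ...]
    motile_speed_mean_by_time: tuple[float, ...]
    nonmotile_speed_mean: float = 1.0
    motile_speed_sd: float = 4.0
    nonmotile_speed_sd: float = 0.5

    def __post_init__(self) -> None:
        n = len(SCHEDULE_TIMES)
        if len(self.motile_fraction_by_time) != n or len(self.motile_speed_mean_by_time) != n:
            raise ValueError(f"schedules must have {n} anchors")
        if any(not 0.0 <= f <= 1.0 for f in self.motile_fraction_by_time):
            raise ValueError("motile fractions must lie in [0, 1]")
        if any(s < 0 for s in self.motile_speed_mean_by_time):
            raise ValueError("speeds must be non-negative")

    def fraction_at(self, t: float) -> float:
        return float(np.interp(t, SCHEDULE_TIMES, self.motile_fraction_by_time))

    def motile_speed_at(self, t: float) -> float:
        return float(np.interp(t, SCHEDULE_TIMES, self.motile_speed_mean_by_time))


ARCHETYPES: dict[str, ArchetypeProfile] = {
    "ancestor": ArchetypeProfile(
        name="ancestor",
        motile_fraction_by_time=(0.45, 0.55, 0.65, 0.65, 0.55, 0.45, 0.40),
        motile_speed_mean_by_time=(14.0, 18.0, 20.0, 20.0, 17.0, 14.0, 12.0),
    ),
    "phase2": ArchetypeProfile(
        name="phase2",
        motile_fraction_by_time=(0.55, 0.65, 0.70, 0.70, 0.68, 0.65, 0.62),
        motile_speed_mean_by_time=(18.0, 22.0, 25.0, 26.0, 25.0, 23.0, 22.0),
    ),
    "phase3": ArchetypeProfile(
        name="phase3",
        motile_fraction_by_time=(0.30, 0.30, 0.35, 0.50, 0.70, 0.85, 0.90),
        motile_speed_mean_by_time=(10.0, 10.0, 11.0, 14.0, 18.0, 22.0, 24.0),
    ),
}


def make_growth_counts(
    r_true: float,
    n0: float = 1000.0,
    times=(3.0, 4.0, 5.0),
    volume_factor: float = 1.0,
    rng: np.random.Generator | None = None,
) -> TimedCounts:
    """Timed counts with Poisson noise around exponential growth.

    Expected count at time t is ``n0 * exp(r_true * t) * volume_factor``.
    With ``rng=None`` the expectations are returned exactly, so the
    log-linear growth-rate estimator recovers ``r_true`` to machine
    precision.
    """
    if not math.isfinite(r_true):
        raise ValueError("r_true must be finite")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if volume_factor < 0:
        raise ValueError("volume_factor must be non-negative")
    t = np.asarray(times, dtype=float)
    expected = n0 * np.exp(r_true * t) * volume_factor
    counts = expected if rng is None else rng.poisson(expected).astype(float)
    return TimedCounts(times=t, counts=counts)


def make_capillary_counts(
    c_diff_true: float,
    depth: int = 5000,
    convention: str = "main_text",
    rng: np.random.Generator | None = None,
) -> CapillaryAssayCounts:
    """Capillary assay counts for a 1:1 mix of mutant and ancestor.

    Pre-incubation counts are ``depth`` per strain.  Post-incubation the
    mutant's odds of being counted are multiplied by ``exp(s_c)`` where
    ``s_c`` follows the requested convention, and ``2 * depth`` cells are
    drawn multinomially.  With ``rng=None`` the expected counts are returned,
    making the delta-log-ratio estimator exact.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    s_c = chemotaxis_selection_coefficient(c_diff_true, convention)
    p_mut = math.exp(s_c) / (1.0 + math.exp(s_c))
    total_post = 2 * depth
    if rng is None:
        post_m = total_post * p_mut
        post_a = total_post * (1.0 - p_mut)
    else:
        post_m = float(rng.binomial(total_post, p_mut))
        post_a = float(total_post - post_m)
    return CapillaryAssayCounts(
        pre_mutant=float(depth),
        pre_ancestor=float(depth),
        post_mutant=post_m,
        post_ancestor=post_a,
    )


def make_speed_sample(
    archetype: ArchetypeProfile | str,
    time_in_cycle: float,
    n_cells: int = 400,
    rng: np.random.Generator | None = None,
) -> SpeedSample:
    """Per-cell speeds from a motile/non-motile mixture at one cycle time.

    Motile cells draw truncated-normal speeds around the archetype's schedule
    value; non-motile cells jiggle near ``nonmotile_speed_mean``.  With
    ``rng=None`` the sample is degenerate: exactly the expected motile count
    at exactly the component means.
    """
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    frac = archetype.fraction_at(time_in_cycle)
    mu_m = archetype.motile_speed_at(time_in_cycle)
    mu_n = archetype.nonmotile_speed_mean
    if rng is None:
        n_motile = int(round(frac * n_cells))
        speeds = np.concatenate(
            [np.full(n_motile, mu_m), np.full(n_cells - n_motile, mu_n)]
        )
    else:
        motile = rng.random(n_cells) < frac
        speeds = np.where(
            motile,
            _truncated_normal(mu_m, archetype.motile_speed_sd, n_cells, rng),
            _truncated_normal(mu_n, archetype.nonmotile_speed_sd, n_cells, rng),
        )
    return SpeedSample(
        speeds=speeds, time_in_cycle=time_in_cycle, label=archetype.name
    )


def _truncated_normal(
    mu: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal draws resampled until non-negative (mu well above 0 in practice)."""
    if sd == 0:
        return np.full(n, mu)
    out = rng.normal(mu, sd, n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
        bad = out < 0
    return out


@dataclass(frozen=True)
class PanelSpec:
    """Layout of a weekly isolate phenotype panel.

    Weeks before ``phase_boundaries[0]`` show cost-free chemotaxis gains
    (c rises toward the front intercept, r stays near zero); weeks up to
    ``phase_boundaries[1]`` scatter along the front line moving toward
    ``r_terminal``; later weeks move beyond the front (growth recovers at
    high chemotaxis).  Per-trait measurement noise is i.i.d. Gaussian.
    """

    weeks: int = 11
    isolates_per_week: int = 6
    front: ParetoFront = field(
        default_factory=lambda: ParetoFront(
            intercept=2.7, slope=-9.6, r_squared=1.0, n_points=2
        )
    )
    phase_boundaries: tuple[int, int] = (2, 7)
    r_terminal: float = -0.15
    breakthrough_r: float = 0.05
    # growth rates come from count regressions and are an order of magnitude
    # tighter than chemotaxis assays; heavy predictor noise would also
    # attenuate the front regression (errors in variables)
    noise_sd_r: float = 0.005
    noise_sd_c: float = 0.3

    def __post_init__(self) -> None:
        if self.weeks < 1 or self.isolates_per_week < 1:
            raise ValueError("counts must be positive")
        b1, b2 = self.phase_boundaries
        if not 0 < b1 < b2 <= self.weeks + 1:
            raise ValueError("phase boundaries must be increasing and within weeks")
        if self.noise_sd_r < 0 or self.noise_sd_c < 0:
            raise ValueError("noise SDs must be non-negative")


def make_isolate_panel(
    spec: PanelSpec | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Weekly isolate phenotypes tracing the three-phase trajectory.

    Returns a table with columns (week, isolate, r_diff, c_diff, phase).
    With ``rng=None`` the points sit exactly on their phase's locus — in
    particular phase-2 rows sit exactly on the front line, so the front
    regression recovers the spec's line exactly.
    """
    if spec is None:
        spec = PanelSpec()
    b1, b2 = spec.phase_boundaries
    rows = []
    for week in range(1, spec.weeks + 1):
        for iso in range(spec.isolates_per_week):
            if week <= b1:
                phase = 1
                c = spec.front.intercept * week / b1
                r = 0.0
            elif week <= b2:
                phase = 2
                progress = (week - b1) / max(b2 - b1, 1)
                r = spec.r_terminal * progress
                c = float(spec.front.c_at(r))
            else:
                phase = 3
                progress = (week - b2) / max(spec.weeks - b2, 1)
                r = spec.r_terminal + (spec.breakthrough_r - spec.r_terminal) * progress
                c = float(spec.front.c_at(spec.r_terminal))
            if rng is not None:
                r += rng.normal(0.0, spec.noise_sd_r)
                c += rng.normal(0.0, spec.noise_sd_c)
            rows.append(
                {"week": week, "isolate": iso, "r_diff": r, "c_diff": c, "phase": phase}
            )
    return pd.DataFrame(rows)


def make_speed_chemotaxis_pairs(
    n: int = 30,
    slope: float = 4.06,
    intercept: float = 8.25,
    c_range: tuple[float, float] = (0.0, 4.0),
    target_r_squared: float = 0.82,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """(chemotaxis, mean speed) pairs around a linear speed-chemotaxis law.

    The noise SD is derived from the target R-squared via
    ``sd = |slope| * sd(c) * sqrt(1/R^2 - 1)``, so fits to generated data
    land near the configured R-squared up to sampling error.  ``rng=None``
    gives exact points on the line.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < target_r_squared <= 1:
        raise ValueError("target_r_squared must lie in (0, 1]")
    c = np.linspace(c_range[0], c_range[1], n)
    v = intercept + slope * c
    if rng is not None and target_r_squared < 1:
        sd = abs(slope) * float(np.std(c)) * math.sqrt(1.0 / target_r_squared - 1.0)
        v = v + rng.normal(0.0, sd, n)
    return pd.DataFrame({"chemotaxis": c, "speed": v})
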