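"""Serial-transfer simulator: traits, cycles, selection consistency, phases."""

import math

import numpy as np
import pytest

from chemoscape.competition import (
    CompetitionParams,
    chemotaxis_selection_coefficient,
    growth_selection_coefficient,
    integrate_competition,
    logistic_closed_form,
)
from chemoscape.simulator import (
    CyclePlan,
    Genotype,
    MutationModel,
    PopulationState,
    SimulationConfig,
    TradeoffModel,
    detect_phases,
    doublings_per_cycle,
    effective_traits,
    measure_selection,
    run_experiment,
    step_cycle,
    total_generations,
    tradeoff_front,
)


@pytest.fixture
def plan():
    return CyclePlan()


@pytest.fixture
def tradeoff():
    return TradeoffModel()


class TestEffectiveTraits:
    def test_no_investment(self, tradeoff):
        r, c = effective_traits(Genotype(r_base=1.2), tradeoff)
        assert (r, c) == (1.2, 0.0)

    def test_full_investment(self):
        model = TradeoffModel(gamma=0.3, c_max=5.0)
        g = Genotype(u_growth=1.0, u_select=1.0, r_base=2.0)
        r, c = effective_traits(g, model)
        assert r == pytest.approx(0.7 * 2.0)
        assert c == pytest.approx(5.0)

    def test_nonplastic_sweep_collinear(self, tradeoff):
        # eliminating u: the (r_eff, c_eff) points fall on one line with
        # slope -c_max / (gamma * r_base)
        pts = [
            effective_traits(Genotype(u_growth=u, u_select=u), tradeoff)
            for u in np.linspace(0, 1, 11)
        ]
        r, c = np.array(pts).T
        slopes = np.diff(c) / np.diff(r)
        expected = -tradeoff.c_max / (tradeoff.gamma * 1.0)
        np.testing.assert_allclose(slopes, expected, rtol=1e-9)

    def test_nonplastic_investment_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Genotype(u_growth=0.2, u_select=0.6, plastic=False)

    def test_front_matches_trait_map(self, tradeoff):
        front = tradeoff_front(tradeoff, Genotype())
        assert front.slope == pytest.approx(-9.6)
        assert front.intercept == pytest.approx(2.7)


class TestCycleArithmetic:
    def test_doublings_per_cycle(self):
        assert doublings_per_cycle(2048.0) == 11.0

    def test_total_generations(self, plan):
        assert total_generations(plan) == 1650.0


class TestStepCycle:
    def test_single_genotype_follows_logistic(self, plan, tradeoff):
        pop = PopulationState((Genotype(),), np.array([1.0 / 2048.0]))
        out = step_cycle(pop, plan, tradeoff, census=None)
        grown = out.post_growth.abundances[0]
        expected = logistic_closed_form(11.5, 1.0, 1.0, 1.0 / 2048.0)
        assert grown == pytest.approx(float(expected), abs=1e-8)
        # frequency trivially unchanged; dilution resets the scale
        assert out.post_bottleneck.abundances[0] == pytest.approx(grown / 2048.0)

    def test_deterministic_log_ratio_matches_competition_model(self, plan, tradeoff):
        # two genotypes, infinite census: the per-cycle change in log ratio
        # must equal s_g + s_c computed by the landscape module
        a = Genotype()  # ancestor-like
        b = Genotype(u_growth=0.5, u_select=0.5)
        pop = PopulationState((a, b), np.array([2.4e-4, 2.4e-4]))
        out = step_cycle(pop, plan, tradeoff, census=None, convention="gradient")
        observed = measure_selection(pop, out.post_bottleneck, b, a)

        r_a, c_a = effective_traits(a, tradeoff)
        r_b, c_b = effective_traits(b, tradeoff)
        params = CompetitionParams(r_m=r_b, r_w=r_a, m0=2.4e-4, w0=2.4e-4)
        s_g = growth_selection_coefficient(
            integrate_competition(params, rtol=1e-10, atol=1e-14)
        )
        s_c = chemotaxis_selection_coefficient(c_b - c_a, "gradient")
        assert observed == pytest.approx(s_g + s_c, abs=1e-6)

    def test_selection_decomposes_into_growth_and_capillary_parts(self, plan, tradeoff):
        a = Genotype()
        b = Genotype(u_growth=0.4, u_select=0.4)
        pop = PopulationState((a, b), np.array([2.4e-4, 2.4e-4]))
        out = step_cycle(pop, plan, tradeoff, census=None, convention="gradient")
        growth_part = measure_selection(pop, out.post_growth, b, a)
        capillary_part = measure_selection(out.post_growth, out.post_selection, b, a)
        total = measure_selection(pop, out.post_bottleneck, b, a)
        assert total == pytest.approx(growth_part + capillary_part, abs=1e-9)
        r_b, c_b = effective_traits(b, tradeoff)
        assert capillary_part == pytest.approx(c_b, abs=1e-9)

    def test_fitter_genotype_frequency_increases_every_cycle(self, plan, tradeoff):
        a = Genotype()
        b = Genotype(u_growth=0.3, u_select=0.3)  # chemotaxis gain outweighs cost
        pop = PopulationState((a, b), np.array([2.4e-4, 2.4e-4]))
        freqs = [0.5]
        for _ in range(5):
            out = step_cycle(pop, plan, tradeoff, census=None, convention="gradient")
            pop = out.post_bottleneck
            freqs.append(pop.frequencies[pop.index_of(b)])
        assert np.all(np.diff(freqs) > 0)

    def test_equal_traits_conserve_expected_frequency(self, plan, tradeoff, rng):
        # neutral lineages drift with zero expected change
        a = Genotype()
        b = Genotype()  # identical traits, separate lineage
        deltas = []
        for _ in range(60):
            pop = PopulationState((a, b), np.array([2.4e-4, 2.4e-4]))
            out = step_cycle(pop, plan, tradeoff, rng=rng, census=2000)
            f = out.post_bottleneck.frequencies
            deltas.append(f[0] - 0.5 if len(f) == 2 else (1.0 if f[0] else 0.0) - 0.5)
        se = np.std(deltas, ddof=1) / math.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 1e-3

    def test_stochastic_mean_matches_deterministic(self, plan, tradeoff):
        a = Genotype()
        b = Genotype(u_growth=0.2, u_select=0.2)
        pop = PopulationState((a, b), np.array([2.4e-4, 2.4e-4]))
        det = measure_selection(
            pop,
            step_cycle(pop, plan, tradeoff, census=None, convention="gradient").post_bottleneck,
            b,
            a,
        )
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(500):
            out = step_cycle(pop, plan, tradeoff, rng=rng, census=1e5, convention="gradient")
            post = out.post_bottleneck
            try:
                vals.append(measure_selection(pop, post, b, a))
            except KeyError:
                continue
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(det, abs=2 * se)

    def test_seeded_run_is_bit_reproducible(self, plan, tradeoff):
        pop = PopulationState(
            (Genotype(), Genotype(u_growth=0.1, u_select=0.1)),
            np.array([3e-4, 2e-4]),
        )
        mut = MutationModel()
        runs = []
        for _ in range(2):
            state = pop
            rng = np.random.default_rng(99)
            for _ in range(3):
                state = step_cycle(
                    state, plan, tradeoff, mutation=mut, rng=rng, census=1e4
                ).post_bottleneck
            runs.append(state)
        assert runs[0].genotypes == runs[1].genotypes
        np.testing.assert_array_equal(runs[0].abundances, runs[1].abundances)


@pytest.fixture(scope="module")
def record():
    """Default 150-cycle experiment, fixed seed."""
    return run_experiment(rng_seed=42)


class TestRunExperiment:
    def test_weekly_summaries_cover_the_run(self, record):
        assert record.weekly.week.iloc[-1] == 11
        assert len(record.isolates) == 11 * 6
        assert not record.extinct

    def test_three_phases_detected(self, record):
        phases = detect_phases(record)
        assert phases.phase1, "early cost-free chemotaxis gain missing"
        assert phases.phase2, "front-constrained approach to the optimum missing"
        assert phases.phase3, "post-plasticity breakthrough missing"
        # and in temporal order
        assert min(phases.phase1_weeks) < min(phases.phase2_weeks) < min(phases.phase3_weeks)

    def test_breakthrough_event_logged(self, record):
        assert any("breakthrough" in e for e in record.events)

    def test_isolates_scatter_around_population_mean(self, record):
        wk = record.weekly.set_index("week")
        iso = record.isolates.groupby("week").c_diff.mean()
        final = wk.mean_c_diff.iloc[-1]
        assert iso.iloc[-1] == pytest.approx(final, abs=0.5)

    def test_mutation_off_is_pure_cycle_composition(self, tradeoff):
        cfg = SimulationConfig(
            plan=CyclePlan(cycles_total=5),
            mutation=MutationModel(rate_per_cycle=0.0),
            census=None,
        )
        rec = run_experiment(cfg, rng_seed=1)
        # single ancestor genotype, no mutation: phenotype never moves
        assert rec.weekly.mean_c_diff.abs().max() == pytest.approx(0.0, abs=1e-12)
        assert len(rec.trajectory.genotype.unique()) == 1
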