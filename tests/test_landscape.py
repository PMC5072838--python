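"""Fitness surface, selective gradients, Pareto front, optimum, r/k surface."""

import numpy as np
import pytest

from chemoscape.competition import CompetitionError, CompetitionParams
from chemoscape.landscape import (
    METHODS_GRID,
    FitnessSurface,
    LandscapeGrid,
    ParetoFront,
    PhenotypePoint,
    fit_pareto_front,
    fitness_surface,
    optimum_on_front,
    rk_sensitivity,
    selective_gradients,
)
from tests.conftest import ols_normal_equations


@pytest.fixture(scope="module")
def standard_surface():
    """Fitness surface on the standard analysis grid (46 x 21 nodes)."""
    return fitness_surface(METHODS_GRID, convention="gradient")


class TestGrid:
    def test_standard_grid_node_counts(self):
        assert len(METHODS_GRID.c_values) == 46
        assert len(METHODS_GRID.r_values) == 21
        assert METHODS_GRID.c_values[0] == -1.0
        assert METHODS_GRID.c_values[-1] == pytest.approx(8.0)
        assert METHODS_GRID.r_values[-1] == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "kwargs",
        [{"c_step": -0.1}, {"c_max": -2.0}, {"r_step": 0.8}],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LandscapeGrid(**kwargs)


class TestFitnessSurface:
    def test_no_growth_difference_leaves_only_chemotaxis_selection(self):
        grid = LandscapeGrid(c_min=0, c_max=1, c_step=0.5, r_min=-0.1, r_max=0.1, r_step=0.1)
        surf = fitness_surface(grid, convention="gradient")
        # at the r=0 column fitness is exactly s_c / T
        j = list(grid.r_values).index(0.0)
        np.testing.assert_allclose(surf.w[:, j], grid.c_values / 11.5, atol=1e-9)

    def test_additive_separability_mixed_second_differences(self, standard_surface):
        w = standard_surface.w
        mixed = w[1:, 1:] - w[1:, :-1] - w[:-1, 1:] + w[:-1, :-1]
        assert np.max(np.abs(mixed)) < 1e-12

    def test_chemotaxis_gradient_same_for_every_growth_column(self, standard_surface):
        col_grads = np.diff(standard_surface.w, axis=0) / standard_surface.grid.c_step
        assert np.ptp(col_grads) < 1e-12

    def test_diminishing_returns_along_growth_axis(self, standard_surface):
        # curvature of the landscape: forward differences of w along r decline
        diffs = np.diff(standard_surface.w[0, :])
        assert np.all(np.diff(diffs) < 0)

    def test_mutant_rate_must_stay_positive(self):
        grid = LandscapeGrid(r_min=-1.5, r_max=0.0, r_step=0.5)
        with pytest.raises(CompetitionError, match="growth"):
            fitness_surface(grid, baseline=CompetitionParams(r_w=1.0))


class TestSelectiveGradients:
    def test_constant_surface_has_zero_gradients(self, standard_surface):
        flat = FitnessSurface(
            grid=standard_surface.grid,
            w=np.full_like(standard_surface.w, 0.3),
            baseline=standard_surface.baseline,
            convention="gradient",
            normalization_hours=11.5,
        )
        g = selective_gradients(flat)
        assert g.dw_dc == 0.0 and g.dw_dr == 0.0

    @pytest.mark.parametrize("alpha,beta", [(0.25, -1.5), (0.0, 2.0), (-0.7, 0.0)])
    def test_linear_surface_recovers_exact_slopes(self, alpha, beta, standard_surface):
        grid = standard_surface.grid
        c, r = np.meshgrid(grid.c_values, grid.r_values, indexing="ij")
        surf = FitnessSurface(
            grid=grid,
            w=alpha * c + beta * r,
            baseline=standard_surface.baseline,
            convention="gradient",
            normalization_hours=11.5,
        )
        g = selective_gradients(surf)
        assert g.dw_dc == pytest.approx(alpha, abs=1e-10)
        assert g.dw_dr == pytest.approx(beta, abs=1e-10)

    def test_model_surface_reproduces_known_gradient_pair(self, standard_surface):
        # overall selection is much steeper on growth than on chemotaxis
        g = selective_gradients(standard_surface)
        assert g.dw_dc == pytest.approx(0.087, abs=0.001)
        assert g.dw_dr == pytest.approx(0.603, rel=0.05)


class TestParetoFront:
    def test_exact_front_recovered(self):
        r = np.linspace(-0.2, 0.1, 12)
        points = [PhenotypePoint(r_diff=ri, c_diff=2.7 - 9.6 * ri) for ri in r]
        front = fit_pareto_front(points)
        assert front.intercept == pytest.approx(2.7, abs=1e-10)
        assert front.slope == pytest.approx(-9.6, abs=1e-10)
        assert front.r_squared == pytest.approx(1.0)
        assert front.n_points == 12

    def test_two_points_interpolate(self):
        front = fit_pareto_front([(0.0, 1.0), (0.1, 2.0)])
        assert front.slope == pytest.approx(10.0)
        assert front.r_squared == pytest.approx(1.0)

    def test_noisy_fit_matches_normal_equations_oracle(self, rng):
        r = rng.uniform(-0.2, 0.2, 40)
        c = 2.7 - 9.6 * r + rng.normal(0, 0.3, 40)
        front = fit_pareto_front(list(zip(r, c)))
        intercept, slope = ols_normal_equations(r, c)
        assert front.intercept == pytest.approx(intercept, abs=1e-10)
        assert front.slope == pytest.approx(slope, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pareto_front([(0.1, 1.0)])
        with pytest.raises(ValueError):
            fit_pareto_front([(0.1, 1.0), (0.1, 2.0)])


class TestOptimumOnFront:
    def test_quadratic_surface_analytic_optimum(self):
        # w = -(c-1)^2 - (r-2)^2 restricted to c = r peaks at c = r = 1.5
        front = ParetoFront(intercept=0.0, slope=1.0, r_squared=1.0, n_points=2)
        opt = optimum_on_front(
            front,
            r_bounds=(0.0, 3.0),
            fitness_fn=lambda r, c: -((c - 1) ** 2) - (r - 2) ** 2,
        )
        assert opt.r_opt == pytest.approx(1.5, abs=1e-4)
        assert opt.c_opt == pytest.approx(1.5, abs=1e-4)

    def test_degenerate_tie_returns_lowest_growth_difference(self):
        # front parallel to the isoclines of a linear surface: all-way tie
        front = ParetoFront(intercept=1.0, slope=-2.0, r_squared=1.0, n_points=2)
        opt = optimum_on_front(
            front,
            r_bounds=(-0.1, 0.3),
            fitness_fn=lambda r, c: c + 2.0 * r,  # constant along the front
        )
        assert opt.r_opt == pytest.approx(-0.1, abs=1e-6)

    def test_model_surface_agrees_with_dense_scan(self):
        front = ParetoFront(intercept=2.7, slope=-9.6, r_squared=0.93, n_points=14)
        baseline = CompetitionParams()
        opt = optimum_on_front(front, baseline, r_bounds=(-0.2, 0.3), convention="gradient")
        # brute-force scan along the line
        from chemoscape.competition import (
            chemotaxis_selection_coefficient,
            cycle_fitness,
            growth_selection_coefficient,
            integrate_competition,
        )

        r_scan = np.linspace(-0.2, 0.3, 401)
        best_w, best_r = -np.inf, None
        for r in r_scan:
            params = CompetitionParams(r_m=baseline.r_w + r)
            s_g = growth_selection_coefficient(integrate_competition(params))
            s_c = chemotaxis_selection_coefficient(front.c_at(r), "gradient")
            w = cycle_fitness(s_g, s_c, 11.5)
            if w > best_w:
                best_w, best_r = w, r
        step = r_scan[1] - r_scan[0]
        assert abs(opt.r_opt - best_r) <= step
        assert opt.w_opt == pytest.approx(best_w, abs=1e-4)


class TestRkSensitivity:
    def test_identical_mutant_scores_zero(self):
        surf = rk_sensitivity([1.0], [1.0], t=11.5, r_baseline=1.0)
        assert surf.f[0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_exponential_regime_rate_derivative_is_time(self):
        # far from capacity both strains grow exponentially: f = (r - r_w) t,
        # so df/dr = t
        surf = rk_sensitivity([1.0], [1.2, 1.21], t=0.2, r_baseline=1.0)
        assert surf.df_dr.shape == (0, 2)
        surf = rk_sensitivity([0.9, 1.0, 1.1], [1.0], t=0.2, r_baseline=1.0)
        np.testing.assert_allclose(surf.df_dr, 0.2, rtol=0.01)

    def test_rate_contribution_diminishes_at_high_rates(self):
        # sigmoid growth: the faster the mutant already is, the less a further
        # rate increase contributes to the end-of-growth outcome
        surf = rk_sensitivity(
            np.arange(0.8, 1.8, 0.2), np.array([1.0]), t=11.5
        )
        dr = surf.df_dr[:, 0]
        assert np.all(dr > 0)
        assert np.all(np.diff(dr) < 0)

    def test_invalid_capacity_rejected(self):
        with pytest.raises(CompetitionError):
            rk_sensitivity([1.0], [0.0])
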