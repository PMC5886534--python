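"""Strata-count profiling, elbow heuristics, baselines and efficiency."""

import numpy as np
import pytest

from optstrat import (
    StrataCountProfile,
    StratificationProblem,
    compare_boundaries,
    cum_sqrt_f_boundaries,
    efficiency,
    geometric_boundaries,
    solve,
    strata_count_profile,
    suggest_elbow,
    uniform,
    weibull3p,
)
from optstrat.distributions import draw
from optstrat.exceptions import DegenerateDataError, DomainError, ParameterError


class TestStrataCountProfile:
    def test_uniform_inverse_square_law(self):
        """V(L) = V(1) / L^2 for a uniform variable."""
        p = StratificationProblem.linear(
            0.0, 12.0, [uniform(0, 12)], [1.0], error_scale=None, grid_step=12 / 600
        )
        prof = strata_count_profile(p, L_max=6, n=100)
        # V(1) = d^2 / (12 n) = 0.12, then 0.03 at L=2, 0.0075 at L=4
        assert prof.variance[0] == pytest.approx(0.12, rel=1e-6)
        assert prof.variance[1] == pytest.approx(0.03, rel=0.02)
        assert prof.variance[3] == pytest.approx(0.0075, rel=0.02)
        for L, v in zip(prof.L, prof.variance):
            assert v == pytest.approx(prof.variance[0] / L**2, rel=0.02)

    def test_variance_is_objective_squared_over_n(self):
        p = StratificationProblem.linear(
            0.0, 3.0, [weibull3p(2, 1, 0)], [1.0], grid_step=3 / 150
        )
        prof = strata_count_profile(p, L_max=4, n=250)
        for o, v in zip(prof.objective, prof.variance):
            assert v == pytest.approx(o * o / 250, abs=1e-12)

    def test_objective_nonincreasing(self):
        p = StratificationProblem.linear(
            0.0, 3.0, [weibull3p(1.6, 0.9, 0)], [1.0], grid_step=3 / 150
        )
        prof = strata_count_profile(p, L_max=6, n=100)
        assert all(b <= a + 1e-12 for a, b in zip(prof.objective, prof.objective[1:]))

    def test_l_max_validation(self):
        p = StratificationProblem.linear(0.0, 1.0, [uniform(0, 1)], [1.0])
        with pytest.raises(ParameterError):
            strata_count_profile(p, L_max=1, n=100)


def inverse_square_profile(L_max, n=100):
    Ls = tuple(range(1, L_max + 1))
    var = tuple(1.0 / L**2 for L in Ls)
    return StrataCountProfile(
        L=Ls, objective=tuple(np.sqrt(np.array(var) * n)), variance=var, n=n
    )


class TestSuggestElbow:
    def test_inverse_square_default_threshold(self):
        # improvement 1 - (L/(L+1))^2 first drops below 10% at L = 19
        assert suggest_elbow(inverse_square_profile(25)) == 19

    def test_inverse_square_quarter_threshold(self):
        assert suggest_elbow(inverse_square_profile(25), threshold=0.25) == 7

    def test_constant_profile_returns_one(self):
        prof = StrataCountProfile(
            L=(1, 2, 3, 4), objective=(1.0,) * 4, variance=(0.5,) * 4, n=100
        )
        assert suggest_elbow(prof) == 1

    def test_geometric_decay_never_crosses(self):
        var = tuple(0.5**L for L in range(1, 9))
        prof = StrataCountProfile(
            L=tuple(range(1, 9)), objective=var, variance=var, n=100
        )
        with pytest.warns(UserWarning, match="returning L_max"):
            assert suggest_elbow(prof) == 8

    def test_curvature_method_finds_kink(self):
        # steep drop then flat: curvature is maximal at the kink
        var = (1.0, 0.1, 0.09, 0.085, 0.082)
        prof = StrataCountProfile(
            L=(1, 2, 3, 4, 5), objective=var, variance=var, n=100
        )
        assert suggest_elbow(prof, method="curvature") == 2

    def test_needs_three_rows(self):
        prof = StrataCountProfile(L=(1, 2), objective=(1, 0.5), variance=(1, 0.5), n=10)
        with pytest.raises(ParameterError):
            suggest_elbow(prof)


class TestCumSqrtF:
    def test_four_bin_toy(self):
        # frequencies (9,1,1,9) -> sqrt 3,1,1,3 -> cum 3,4,5,8; target 4
        sample = np.concatenate(
            [
                np.full(9, 0.5), np.full(1, 1.5), np.full(1, 2.5), np.full(9, 3.5),
            ]
        )
        (b,) = cum_sqrt_f_boundaries(sample, L=2, n_bins=4)
        edges = np.histogram(sample, bins=4)[1]
        assert b == pytest.approx(edges[2])

    def test_equal_frequencies_symmetric_cut(self):
        sample = np.repeat(np.arange(10) + 0.5, 7)
        (b,) = cum_sqrt_f_boundaries(sample, L=2, n_bins=10)
        assert b == pytest.approx(5.0)  # middle edge of [0.5, 9.5] in 10 bins

    def test_every_bin_its_own_stratum(self):
        sample = np.repeat([0.5, 1.5, 2.5, 3.5], 5)
        bounds = cum_sqrt_f_boundaries(sample, L=4, n_bins=4)
        edges = np.histogram(sample, bins=4)[1]
        np.testing.assert_allclose(bounds, edges[1:4])

    def test_boundaries_strictly_increasing(self, rng):
        sample = rng.gamma(2.0, 1.5, 2000)
        bounds = cum_sqrt_f_boundaries(sample, L=5, n_bins=30)
        assert all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:]))

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateDataError):
            cum_sqrt_f_boundaries(np.ones(100), L=2)


class TestGeometric:
    def test_powers_of_two(self):
        assert geometric_boundaries(1, 16, 4) == pytest.approx((2.0, 4.0, 8.0))

    def test_single_stratum_empty(self):
        assert geometric_boundaries(1, 16, 1) == ()

    def test_sqrt_rule(self):
        assert geometric_boundaries(1, 100, 2) == pytest.approx((10.0,))

    def test_nonpositive_lower_bound(self):
        with pytest.raises(DomainError):
            geometric_boundaries(0.0, 10, 3)
        with pytest.raises(DomainError):
            geometric_boundaries(5.0, 5.0, 3)


class TestEfficiency:
    def test_values(self):
        assert efficiency(0.1, 0.1) == 100.0
        assert efficiency(0.12, 0.10) == pytest.approx(120.0)

    def test_antisymmetry(self):
        assert efficiency(0.07, 0.05) * efficiency(0.05, 0.07) == pytest.approx(100.0**2)

    def test_domain(self):
        with pytest.raises(DomainError):
            efficiency(0.0, 0.1)


class TestBaselineDominance:
    """The DP optimum dominates both classical baselines under the same
    parametric objective on skewed synthetic populations."""

    @pytest.mark.parametrize("seed, shape", [(11, 1.5), (12, 2.0), (13, 2.0)])
    def test_dp_beats_baselines(self, seed, shape):
        rng = np.random.default_rng(seed)
        dist = weibull3p(shape, 1.0, 0.1)
        sample = draw(dist, 5000, rng)
        d = float(np.max(sample)) - 0.1
        problem = StratificationProblem.linear(
            0.1, d, [dist], [1.0], error_scale=None, grid_step=d / 300
        )
        for L in range(2, 7):
            dp = solve(problem.with_L(L))
            others = {
                "cum_sqrt_f": cum_sqrt_f_boundaries(sample, L, 30),
                "geometric": geometric_boundaries(0.1, 0.1 + d, L),
            }
            scored = compare_boundaries(problem, others, dp.total_objective)
            for name, block in scored.items():
                assert block["objective"] >= dp.total_objective - 1e-10, (name, L)
                assert block["efficiency_pct"] >= 100.0 - 1e-6
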