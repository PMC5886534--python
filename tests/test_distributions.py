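"""Closed-form truncated moments against hand values and the quadrature oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optstrat import (
    DistributionSpec,
    Family,
    fit_mle,
    gamma3p,
    pdf,
    quadrature_moment,
    std_normal_error,
    stratum_mean,
    stratum_variance,
    stratum_weight,
    truncated_moment,
    uniform,
    weibull3p,
)
from optstrat.distributions import draw, stratum_moments, upper_partial_moment
from optstrat.exceptions import (
    DegenerateDataError,
    DegenerateStratumError,
    DomainError,
    ParameterError,
)

INF = math.inf


class TestPointValues:
    """Hand-derivable densities and stratum quantities."""

    @pytest.mark.parametrize(
        "dist, x, expected",
        [
            (weibull3p(1, 1, 0), 0.0, 1.0),                 # exponential at 0
            (weibull3p(2, 1, 0), -1.0, 0.0),                # below support
            (gamma3p(2, 1, 0), 1.0, math.exp(-1)),          # x e^-x at 1
            (uniform(0, 2), 1.0, 0.5),
            (uniform(0, 2), 3.0, 0.0),
        ],
    )
    def test_pdf(self, dist, x, expected):
        assert pdf(dist, x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "dist, lower, width, expected",
        [
            (weibull3p(1, 1, 0), 0.0, INF, 1.0),
            (weibull3p(2, 1, 0), 0.3, 0.0, 0.0),
            (weibull3p(2, 1, 0), 0.5, 0.5, math.exp(-0.25) - math.exp(-1)),
            (gamma3p(1, 1, 0), 0.0, 1.0, 1 - math.exp(-1)),
            (uniform(0, 1), 0.25, 0.5, 0.5),
        ],
    )
    def test_weight(self, dist, lower, width, expected):
        assert stratum_weight(dist, lower, width) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "dist, lower, width, expected",
        [
            (weibull3p(2, 1, 0), 0.0, INF, math.sqrt(math.pi) / 2),
            (weibull3p(1, 1, 5), 5.0, INF, 6.0),     # location equivariance
            (gamma3p(2, 1, 0), 0.0, INF, 2.0),       # alpha * theta
            (uniform(0, 1), 0.0, 0.5, 0.25),
        ],
    )
    def test_mean(self, dist, lower, width, expected):
        assert stratum_mean(dist, lower, width) == pytest.approx(expected, rel=1e-10)

    def test_variance_exponential_full_support(self):
        # theta^2 (Gamma(3) - Gamma(2)^2) = 4 (2 - 1)
        assert stratum_variance(weibull3p(1, 2, 0), 0, INF) == pytest.approx(4.0, rel=1e-10)

    def test_variance_std_normal(self):
        sn = std_normal_error()
        assert stratum_variance(sn, -INF, INF) == pytest.approx(1.0, rel=1e-10)
        # symmetric truncation [-1, 1]: 1 - 2 phi(1) / (2 Phi(1) - 1)
        from scipy import stats

        expected = 1 - 2 * stats.norm.pdf(1) / (2 * stats.norm.cdf(1) - 1)
        assert stratum_variance(sn, -1, 2) == pytest.approx(expected, rel=1e-10)

    def test_fourth_moment_rayleigh(self):
        # theta^4 Gamma(1 + 4/2) = Gamma(3) = 2
        assert truncated_moment(weibull3p(2, 1, 0), 4, 0, INF) == pytest.approx(2.0, rel=1e-10)

    def test_zeroth_moment_is_one(self):
        assert truncated_moment(gamma3p(3, 2, 1), 0, 1.5, 4.0) == 1.0

    def test_first_moment_equals_mean(self):
        dist = weibull3p(1.7, 2.0, 0.5)
        assert truncated_moment(dist, 1, 1.0, 2.0) == pytest.approx(
            stratum_mean(dist, 1.0, 2.0), rel=1e-12
        )


WEIBULL_GRID = [
    weibull3p(r, th, g)
    for r in (0.8, 1.0, 2.0, 3.6)
    for th in (0.5, 1.0, 2.0)
    for g in (0.0, 5.0)
]
GAMMA_GRID = [
    gamma3p(a, th, g)
    for a in (0.8, 1.0, 2.0, 3.6)
    for th in (0.5, 1.0, 2.0)
    for g in (0.0, 5.0)
]


class TestQuadratureOracle:
    """Every closed form agrees with adaptive quadrature of the density."""

    @pytest.mark.parametrize("dist", WEIBULL_GRID + GAMMA_GRID)
    @pytest.mark.parametrize("order", range(5))
    def test_interior_stratum(self, dist, order):
        lower = dist.location + 0.2 * dist.scale
        width = 1.2 * dist.scale
        cf = truncated_moment(dist, order, lower, width)
        qd = quadrature_moment(dist, order, lower, width)
        assert cf == pytest.approx(qd, rel=1e-8, abs=1e-10)

    @pytest.mark.parametrize("dist", [weibull3p(2, 1.5, 3), gamma3p(2.5, 0.7, 1)])
    @pytest.mark.parametrize("order", range(5))
    def test_tail_stratum(self, dist, order):
        lower = dist.location + 2.5 * dist.scale
        cf = truncated_moment(dist, order, lower, INF)
        qd = quadrature_moment(dist, order, lower, INF)
        assert cf == pytest.approx(qd, rel=1e-8)

    @pytest.mark.parametrize("order", range(5))
    def test_std_normal(self, order):
        sn = std_normal_error()
        cf = truncated_moment(sn, order, -0.7, 2.0)
        qd = quadrature_moment(sn, order, -0.7, 2.0)
        assert cf == pytest.approx(qd, rel=1e-8, abs=1e-10)

    def test_uniform_sub_interval(self):
        assert quadrature_moment(uniform(0, 1), 1, 0.0, 0.5) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "dist", [weibull3p(1, 1, 0), weibull3p(2, 2, 1), gamma3p(2, 1, 0), uniform(0, 3)]
    )
    def test_density_normalizes(self, dist):
        lo, hi = dist.support
        assert stratum_weight(dist, lo, INF if hi == INF else hi - lo) == pytest.approx(
            1.0, abs=1e-10
        )


class TestPartitionLaws:
    """Weights add; means mix; law of total variance holds on any split."""

    @pytest.mark.parametrize(
        "dist, a, b",
        [
            (weibull3p(2, 1, 0), 0.2, 2.5),
            (gamma3p(1.6, 0.8, 0.5), 0.9, 3.0),
            (std_normal_error(), -1.5, 1.0),
        ],
    )
    @pytest.mark.parametrize("frac", [0.2, 0.5, 0.9])
    def test_split(self, dist, a, b, frac):
        mid = a + frac * (b - a)
        parent = stratum_moments(dist, a, b - a)
        left = stratum_moments(dist, a, mid - a)
        right = stratum_moments(dist, mid, b - mid)
        assert left.weight + right.weight == pytest.approx(parent.weight, abs=1e-12)
        mix_mean = (left.weight * left.mean + right.weight * right.mean) / parent.weight
        assert mix_mean == pytest.approx(parent.mean, abs=1e-8)
        pl, pr = left.weight / parent.weight, right.weight / parent.weight
        total_var = (
            pl * left.variance
            + pr * right.variance
            + pl * (left.mean - parent.mean) ** 2
            + pr * (right.mean - parent.mean) ** 2
        )
        assert total_var == pytest.approx(parent.variance, abs=1e-8)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        lo=st.floats(0.05, 2.0),
        w1=st.floats(0.05, 1.5),
        w2=st.floats(0.05, 1.5),
    )
    def test_weight_additivity_property(self, lo, w1, w2):
        dist = weibull3p(1.8, 1.2, 0.0)
        whole = stratum_weight(dist, lo, w1 + w2)
        parts = stratum_weight(dist, lo, w1) + stratum_weight(dist, lo + w1, w2)
        assert whole == pytest.approx(parts, abs=1e-12)


class TestLimitsAndEquivariance:
    def test_narrow_stratum_limits(self):
        dist = weibull3p(2, 1, 0)
        assert stratum_variance(dist, 0.8, 1e-6) == pytest.approx(0.0, abs=1e-10)
        assert stratum_mean(dist, 0.8, 1e-6) == pytest.approx(0.8, abs=1e-5)

    @pytest.mark.parametrize("make", [weibull3p, gamma3p])
    def test_location_shift(self, make):
        base = make(1.9, 1.3, 0.0)
        shifted = make(1.9, 1.3, 4.0)
        a, w = 0.5, 1.5
        assert stratum_weight(shifted, a + 4, w) == pytest.approx(
            stratum_weight(base, a, w), rel=1e-12
        )
        assert stratum_mean(shifted, a + 4, w) == pytest.approx(
            stratum_mean(base, a, w) + 4, rel=1e-10
        )
        assert stratum_variance(shifted, a + 4, w) == pytest.approx(
            stratum_variance(base, a, w), rel=1e-8
        )

    @pytest.mark.parametrize("make", [weibull3p, gamma3p])
    def test_scale_change(self, make):
        c = 3.0
        base = make(1.9, 1.3, 0.0)
        scaled = make(1.9, 1.3 * c, 0.0)
        a, w = 0.5, 1.5
        assert stratum_weight(scaled, a * c, w * c) == pytest.approx(
            stratum_weight(base, a, w), rel=1e-12
        )
        assert stratum_mean(scaled, a * c, w * c) == pytest.approx(
            c * stratum_mean(base, a, w), rel=1e-10
        )
        assert stratum_variance(scaled, a * c, w * c) == pytest.approx(
            c**2 * stratum_variance(base, a, w), rel=1e-8
        )


class TestValidation:
    def test_bad_parameters(self):
        with pytest.raises(ParameterError):
            weibull3p(-1, 1, 0)
        with pytest.raises(ParameterError):
            gamma3p(2, 0, 0)
        with pytest.raises(ParameterError):
            uniform(2, 1)
        with pytest.raises(ParameterError):
            DistributionSpec(Family.STD_NORMAL_ERROR, shape=1.0)

    def test_negative_width(self):
        with pytest.raises(DomainError):
            stratum_weight(weibull3p(2, 1, 0), 0.5, -0.1)

    def test_massless_stratum(self):
        with pytest.raises(DegenerateStratumError):
            stratum_mean(uniform(0, 1), 5.0, 1.0)

    def test_order_above_closed_form(self):
        with pytest.raises(NotImplementedError):
            upper_partial_moment(weibull3p(2, 1, 0), 5, 0.0)

    def test_below_support_clips_exactly(self):
        dist = weibull3p(2, 1, 3.0)
        assert stratum_weight(dist, 0.0, 10.0) == pytest.approx(
            stratum_weight(dist, 3.0, 7.0), rel=1e-12
        )


class TestFitMLE:
    def test_weibull_recovery(self, rng):
        true = weibull3p(2.0, 1.0, 0.0)
        sample = draw(true, 5000, rng)
        report = fit_mle(sample, "weibull3p")
        assert report.spec.shape == pytest.approx(2.0, abs=0.1)
        assert report.spec.scale == pytest.approx(1.0, abs=0.1)
        assert report.ks_pvalue > 0.05

    def test_gamma_recovery(self, rng):
        true = gamma3p(2.5, 1.5, 1.0)
        sample = draw(true, 5000, rng)
        report = fit_mle(sample, "gamma3p")
        assert report.spec.shape == pytest.approx(2.5, abs=0.35)
        assert report.spec.scale == pytest.approx(1.5, abs=0.2)
        assert report.ks_pvalue > 0.05

    def test_ks_statistic_shrinks_with_n(self, rng):
        true = weibull3p(1.8, 2.0, 0.5)
        small = fit_mle(draw(true, 100, rng), "weibull3p")
        large = fit_mle(draw(true, 10000, rng), "weibull3p")
        assert large.ks_statistic < small.ks_statistic

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateDataError):
            fit_mle(np.ones(50), "weibull3p")
        with pytest.raises(DegenerateDataError):
            fit_mle(np.arange(5), "weibull3p")
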