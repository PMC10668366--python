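import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trialbf as tb
from conftest import make_summary

T_VALUES = st.floats(min_value=-6.0, max_value=6.0)
SIZES = st.sampled_from([4, 12, 40])


class TestReciprocity:
    def test_orientation_flip_negates_log_bf_exactly(self):
        res = tb.bf_superiority(make_summary(2.0, 12), "high")
        flip = res.flipped()
        assert flip.log_bf == -res.log_bf
        assert flip.orientation == "BF01"
        assert flip.flipped() == res

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(t=T_VALUES, m=SIZES)
    def test_holds_for_all_designs(self, t, m):
        s = make_summary(t, m)
        for res in (
            tb.bf_superiority(s, "high"),
            tb.bf_equivalence(s, 0.3),
            tb.bf_noninferiority(s, 0.5, direction="high"),
        ):
            assert res.flipped().log_bf == -res.log_bf


class TestDirectionSymmetry:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(t=T_VALUES, m=SIZES)
    def test_negating_difference_and_flipping_direction(self, t, m):
        s = make_summary(t, m)
        neg = tb.StudySummary(
            n_x=s.n_x, n_y=s.n_y, mean_x=-s.mean_x, mean_y=-s.mean_y,
            sd_x=s.sd_x, sd_y=s.sd_y,
        )
        a = tb.bf_superiority(s, "high").log_bf
        b = tb.bf_superiority(neg, "low").log_bf
        assert b == pytest.approx(a, abs=1e-12)
        a = tb.bf_noninferiority(s, 0.4, direction="high").log_bf
        b = tb.bf_noninferiority(neg, 0.4, direction="low").log_bf
        assert b == pytest.approx(a, abs=1e-12)


class TestMonotonicityAndReductions:
    def test_superiority_bf_strictly_increasing_in_t(self):
        ts = [-4.0, -1.0, 0.0, 1.0, 2.5, 5.0]
        bfs = [tb.bf_superiority(make_summary(t, 16), "high").log_bf for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_zero_margin_noninferiority_equals_superiority(self):
        s = make_summary(1.7, 20)
        ni = tb.bf_noninferiority(s, 0.0, direction="high")
        sup = tb.bf_superiority(s, "high")
        assert ni.log_bf == pytest.approx(sup.log_bf, abs=1e-9)

    def test_shrinking_interval_converges_to_point_savage_dickey(self):
        # the interval-odds form converges linearly in the half-width: the
        # leading error is 2*eps*(posterior - prior density at 0)
        s = make_summary(0.8, 25)
        point = tb.bf_equivalence(s, 0.0).log_bf
        errors = [
            abs(tb.bf_equivalence(s, eps).log_bf - point)
            for eps in (1e-2, 1e-3, 1e-4)
        ]
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-3
        assert errors[0] / errors[1] == pytest.approx(10.0, rel=0.15)

    def test_one_sided_average_equals_two_sided(self):
        for t in (-2.5, 0.3, 3.1):
            s = make_summary(t, 14)
            stat = tb.test_statistic(s)
            hi = tb.bf_superiority(s, "high")
            neg = tb.StudySummary(
                n_x=s.n_x, n_y=s.n_y, mean_x=-s.mean_x, mean_y=-s.mean_y,
                sd_x=s.sd_x, sd_y=s.sd_y,
            )
            lo = tb.bf_superiority(neg, "high")  # the delta < 0 side
            two_sided = (
                tb.marginal_likelihood(stat, tb.CauchyPrior())
                - tb.log_likelihood_t(stat.t, stat.df, 0.0, stat.n_eff)
            )
            avg = 0.5 * (math.exp(hi.log_bf) + math.exp(lo.log_bf))
            assert avg == pytest.approx(math.exp(two_sided), rel=1e-6)


class TestEquivalence:
    def test_point_null_matches_savage_dickey_curve_route(self):
        s = make_summary(0.5, 100)
        stat = tb.test_statistic(s)
        point = tb.bf_equivalence(s, 0.0)
        curve = tb.posterior_curve(stat, tb.CauchyPrior())
        sd = tb.savage_dickey_bf(curve, 0.0)
        assert sd.log_bf == pytest.approx(point.log_bf, abs=1e-4)

    def test_unstandardized_interval(self):
        s = tb.StudySummary(50, 50, 0.0, 0.1, sd_x=2.0, sd_y=2.0)
        raw = tb.bf_equivalence(s, 0.8, interval_std=False)
        std = tb.bf_equivalence(s, 0.4, interval_std=True)
        assert raw.log_bf == pytest.approx(std.log_bf, abs=1e-9)

    def test_matches_oracle_mass_ratio(self):
        s = make_summary(0.5, 100)
        spec = tb.build_design("equivalence", interval=0.2)
        eng = tb.bf_equivalence(s, 0.2).log_bf
        orc = tb.oracle_log_bf(s, spec)
        assert eng == pytest.approx(orc, abs=1e-3)


class TestPosteriorCurve:
    def test_posterior_normalizes_on_adequate_grid(self):
        stat = tb.test_statistic(make_summary(1.5, 30))
        for support, bound in (("full", None), ("greater_than", -0.5)):
            prior = tb.CauchyPrior(support=support, bound=bound)
            grid = np.linspace(max(-60.0, prior.lower), 60.0, 40001)
            curve = tb.posterior_curve(stat, prior, grid=grid)
            assert np.trapezoid(curve.posterior_density, grid) == pytest.approx(
                1.0, abs=1e-3
            )
            assert np.trapezoid(curve.prior_density, grid) == pytest.approx(
                1.0, abs=0.01
            )

    def test_posterior_mode_near_observed_effect_for_large_n(self):
        # n_eff = 500 -> equal groups of 1000
        s = make_summary(6.0, 1000)
        stat = tb.test_statistic(s)
        curve = tb.posterior_curve(stat, tb.CauchyPrior(), n_points=8001)
        mode = curve.grid[int(np.argmax(curve.posterior_density))]
        assert abs(mode - stat.d_obs) < 0.05

    def test_flat_likelihood_returns_prior(self):
        # a zero-information weighting on the grid leaves the prior untouched
        prior = tb.CauchyPrior()
        grid = np.linspace(-5, 5, 501)
        dens = prior.pdf(grid)
        curve = tb.DensityCurve(
            grid=grid, prior_density=dens, posterior_density=dens.copy()
        )
        assert tb.savage_dickey_bf(curve, 0.0).log_bf == pytest.approx(0.0, abs=1e-12)

    def test_savage_dickey_outside_support_is_error(self):
        stat = tb.test_statistic(make_summary(1.0, 10))
        prior = tb.CauchyPrior(support="greater_than", bound=0.0)
        curve = tb.posterior_curve(stat, prior)
        with pytest.raises(tb.InvalidInputError):
            tb.savage_dickey_bf(curve, -1.0)

    def test_savage_dickey_matches_marginal_ratio_route(self):
        s = make_summary(1.2, 40)
        stat = tb.test_statistic(s)
        prior = tb.CauchyPrior(support="greater_than", bound=-0.6)
        curve = tb.posterior_curve(stat, prior)
        sd = tb.savage_dickey_bf(curve, -0.6)
        ratio = tb.log_likelihood_t(stat.t, stat.df, -0.6, stat.n_eff) - \
            tb.marginal_likelihood(stat, prior)
        assert sd.log_bf == pytest.approx(ratio, abs=1e-4)


class TestWorkedExample:
    def test_noninferiority_bf_and_report_value(self, sleepiness_summary):
        out = tb.noninferiority_test(
            n_x=193, n_y=205, mean_x=4.7, mean_y=4.8,
            ci_margin=0.19, ci_level=0.95,
            ni_margin=1.0, ni_margin_std=False, direction="low",
        )
        assert tb.format_bf(out.bf) == "8.56e+17"
        assert out.bf.orientation == "BF10"

    def test_matches_oracle(self, sleepiness_summary):
        spec = tb.build_design("noninferiority", direction="low",
                               ni_margin=1.0, ni_margin_std=False)
        eng = tb.run_test(sleepiness_summary, spec).bf.log_bf
        orc = tb.oracle_log_bf(sleepiness_summary, spec)
        assert eng == pytest.approx(orc, abs=1e-3)
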