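import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mangrove_carbon.model import (
    FitConfig,
    ParameterDraw,
    PosteriorSamples,
    PriorSpec,
    age_at_ratio,
    bayes_r2,
    curve_ratio,
    log_likelihood,
    log_prior,
    prior_interval_mass,
    slope_probability,
    summarize_curve,
)
from mangrove_carbon.pairing import RatioObservation, StratumSpec


def ratio_obs(ratio, age, stratum=None):
    return RatioObservation(
        planted_id="p", compartment="bgb", ratio=ratio, age_yr=age,
        reference_ids=("u",), reference_distance_km=1.0, match_mode="local",
        stratum=stratum or StratumSpec("bgb", "all"), study_id="st",
    )


def make_samples(rmax, beta0, beta1, sigma):
    """PosteriorSamples from explicit draw arrays (2 pseudo-chains)."""
    n = len(rmax)
    return PosteriorSamples(
        stratum=StratumSpec("bgb", "all"),
        rmax=np.asarray(rmax, float),
        beta0=np.asarray(beta0, float),
        beta1=np.asarray(beta1, float),
        sigma=np.asarray(sigma, float),
        chain=np.arange(n) % 2,
        iteration=np.arange(n) // 2,
        diagnostics=pd.DataFrame(
            {"rhat": 1.0, "ess": float(n)},
            index=["log_rmax", "beta0", "beta1", "log_sigma"],
        ),
    )


class TestCurveRatio:
    def test_flat_curve_midpoint(self):
        theta = ParameterDraw(1.0, 0.0, 0.0, 1.0)
        for age in (0.5, 1.0, 17.0):
            assert curve_ratio(theta, age) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        theta = ParameterDraw(0.8, -2.0, 1.0, 1.0)
        expected = 0.8 / (1.0 + math.exp(2.0 - math.log(20.0)))
        assert curve_ratio(theta, 20.0) == pytest.approx(expected)
        assert curve_ratio(theta, 20.0) == pytest.approx(0.58418, abs=1e-5)

    def test_asymptote(self):
        theta = ParameterDraw(0.8, -2.0, 1.0, 1.0)
        assert curve_ratio(theta, 1e12) == pytest.approx(0.8, rel=1e-6)

    @pytest.mark.parametrize(
        "beta1, expected", [(1.0, 0.0), (0.0, 0.5), (-1.0, 1.0)]
    )
    def test_age_zero_limits(self, beta1, expected):
        theta = ParameterDraw(1.0, 0.0, beta1, 1.0)
        assert curve_ratio(theta, 0.0) == pytest.approx(expected)

    @given(
        rmax=st.floats(0.05, 20.0),
        beta0=st.floats(-5.0, 5.0),
        beta1=st.floats(0.05, 4.0),
        a1=st.floats(0.01, 40.0),
        a2=st.floats(0.01, 40.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, rmax, beta0, beta1, a1, a2):
        theta = ParameterDraw(rmax, beta0, beta1, 1.0)
        lo, hi = sorted((a1, a2))
        r_lo, r_hi = curve_ratio(theta, lo), curve_ratio(theta, hi)
        if lo < hi:
            assert r_lo < r_hi
        assert 0.0 < r_lo < rmax and 0.0 < r_hi < rmax


class TestAgeAtRatio:
    def test_midpoint_age_one(self):
        assert age_at_ratio(ParameterDraw(1.0, 0.0, 1.0, 1.0), 0.5) == pytest.approx(1.0)

    def test_round_trip_with_curve_example(self):
        theta = ParameterDraw(0.8, -2.0, 1.0, 1.0)
        assert age_at_ratio(theta, curve_ratio(theta, 20.0)) == pytest.approx(20.0)

    def test_unreachable_ratio_is_infinite(self):
        theta = ParameterDraw(0.8, -2.0, 1.0, 1.0)
        assert math.isinf(age_at_ratio(theta, 0.8))
        assert math.isinf(age_at_ratio(theta, 1.5))

    def test_flat_curve_has_no_solution(self):
        with pytest.raises(ValueError):
            age_at_ratio(ParameterDraw(1.0, 0.0, 0.0, 1.0), 0.4)

    @given(
        rmax=st.floats(0.05, 20.0),
        beta0=st.floats(-5.0, 5.0),
        beta1=st.floats(0.05, 4.0),
        age=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_inversion(self, rmax, beta0, beta1, age):
        from hypothesis import assume

        theta = ParameterDraw(rmax, beta0, beta1, 1.0)
        r = curve_ratio(theta, age)
        # near saturation Rmax - R underflows in float64; the identity is
        # exact algebraically but only testable away from the asymptote
        assume(r < rmax * (1.0 - 1e-6))
        assert age_at_ratio(theta, r) == pytest.approx(age, rel=1e-9)


class TestLogLikelihood:
    def test_zero_residual_constant(self):
        theta = ParameterDraw(1.0, 0.0, 0.0, 1.0)
        # mu = -ln 2 = ln(0.5): density at its mode
        got = log_likelihood(theta, ratio_obs(0.5, 1.0))
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-9)
        assert got == pytest.approx(-0.91894, abs=5e-6)

    def test_symmetry_in_log_space(self):
        theta = ParameterDraw(1.0, 0.0, 0.0, 1.0)
        up = log_likelihood(theta, ratio_obs(0.5 * math.e, 1.0))
        down = log_likelihood(theta, ratio_obs(0.5 / math.e, 1.0))
        assert up == pytest.approx(down, rel=1e-12)

    def test_extreme_beta0_stays_finite(self):
        theta = ParameterDraw(1.0, -745.0, 0.0, 1.0)
        assert math.isfinite(log_likelihood(theta, ratio_obs(0.5, 1.0)))

    def test_age_floor_applied_below_floor(self):
        theta = ParameterDraw(0.8, -2.0, 1.0, 0.3)
        at_zero = log_likelihood(theta, ratio_obs(0.4, 0.0), age_floor_yr=0.25)
        at_floor = log_likelihood(theta, ratio_obs(0.4, 0.25), age_floor_yr=0.25)
        assert at_zero == at_floor

    def test_scale_invariance_of_stocks(self):
        # likelihood depends only on the ratio: scaling planted and intact
        # stocks together leaves it unchanged
        theta = ParameterDraw(0.8, -2.0, 1.0, 0.3)
        for c in (0.1, 3.0, 250.0):
            r1 = (50.0 * c) / (100.0 * c)
            assert log_likelihood(theta, ratio_obs(r1, 12.0)) == pytest.approx(
                log_likelihood(theta, ratio_obs(0.5, 12.0)), rel=1e-12
            )


class TestLogPrior:
    def test_value_at_prior_means(self):
        theta = ParameterDraw(1.0, 0.0, 0.0, 1.0)
        expected = -2 * (math.log(2.5) + 0.5 * math.log(2 * math.pi)) - (
            math.log(5.0) + 0.5 * math.log(2 * math.pi)
        )
        assert log_prior(theta) == pytest.approx(expected, rel=1e-12)
        assert log_prior(theta) == pytest.approx(-6.19884, abs=1e-5)

    def test_flat_in_log_sigma(self):
        base = ParameterDraw(1.0, 0.0, 0.0, 1.0)
        for c in (0.01, 0.5, 7.0):
            scaled = ParameterDraw(1.0, 0.0, 0.0, c)
            assert log_prior(scaled) == pytest.approx(log_prior(base))

    def test_out_of_support(self):
        with pytest.raises(ValueError):
            ParameterDraw(-1.0, 0.0, 0.0, 1.0)
        assert log_prior(ParameterDraw(1.0, 0.0, 0.0, math.exp(11.0))) == -math.inf


class TestPriorIntervalMass:
    @pytest.mark.parametrize(
        "sd, lo, hi, scale, expected",
        [
            (5.0, -10.0, 10.0, "identity", 0.95450),
            (2.5, -5.0, 5.0, "identity", 0.95450),
            (2.5, 0.001, 148.0, "exp", 0.97433),
        ],
    )
    def test_analytic_values(self, sd, lo, hi, scale, expected):
        assert prior_interval_mass(sd, lo, hi, scale) == pytest.approx(expected, abs=5e-5)

    def test_full_line_normalizes(self):
        assert prior_interval_mass(3.7, -math.inf, math.inf) == pytest.approx(1.0)

    def test_nonpositive_exp_lower_bound_is_left_tail(self):
        full = prior_interval_mass(2.5, 0.0, 148.0, "exp")
        assert full == pytest.approx(stats.norm.cdf(math.log(148.0) / 2.5))

    @pytest.mark.parametrize(
        "sd, lo, hi, scale",
        [(5.0, -10.0, 10.0, "identity"), (2.5, 0.001, 148.0, "exp"), (2.5, 0.08, 12.0, "exp")],
    )
    def test_agrees_with_monte_carlo(self, sd, lo, hi, scale):
        rng = np.random.default_rng(1234)
        draws = rng.normal(0.0, sd, 1_000_000)
        if scale == "exp":
            draws = np.exp(draws)
        p_hat = np.mean((draws >= lo) & (draws <= hi))
        se = math.sqrt(p_hat * (1 - p_hat) / draws.size)
        assert abs(prior_interval_mass(sd, lo, hi, scale) - p_hat) <= 3 * se


class TestPosteriorSummaries:
    def test_identical_draws_zero_width(self):
        s = make_samples([0.8] * 4, [-2.0] * 4, [1.0] * 4, [0.3] * 4)
        table = summarize_curve(s, [5.0, 20.0])
        point = curve_ratio(ParameterDraw(0.8, -2.0, 1.0, 0.3), np.array([5.0, 20.0]))
        assert np.allclose(table["mean"], point)
        assert np.allclose(table["q2.5"], table["q97.5"])

    def test_two_draw_saturating_mean(self):
        # beta0 huge -> expit ~ 1, so the curve is just Rmax per draw
        s = make_samples([0.6, 0.8], [40.0, 40.0], [0.0, 0.0], [0.3, 0.3])
        table = summarize_curve(s, [1.0, 10.0, 40.0])
        assert np.allclose(table["mean"], 0.7)

    def test_quantiles_are_ordered(self, truth_fit):
        table = summarize_curve(truth_fit, [0.5, 1, 5, 10, 20, 40])
        assert (table["q2.5"] <= table["mean"]).all()
        assert (table["mean"] <= table["q97.5"]).all()

    def test_slope_probability_counting(self):
        b1 = np.concatenate([np.full(13, -0.1), np.full(87, 0.1)])
        s = make_samples(np.ones(100), np.zeros(100), b1, np.ones(100))
        p = slope_probability(s)
        assert p["tail"] == pytest.approx(0.13)
        assert p["p_positive"] == pytest.approx(0.87)

    def test_slope_probability_degenerate(self):
        s = make_samples(np.ones(100), np.zeros(100), np.full(100, 0.5), np.ones(100))
        assert slope_probability(s)["tail"] == 0.0


class TestBayesR2:
    def test_zero_residuals_give_one(self):
        theta = ParameterDraw(0.8, -2.0, 1.0, 0.3)
        obs = [ratio_obs(curve_ratio(theta, a), a) for a in (2.0, 5.0, 20.0)]
        s = make_samples([0.8] * 4, [-2.0] * 4, [1.0] * 4, [0.3] * 4)
        assert bayes_r2(s, obs) == pytest.approx(1.0)

    def test_equal_variances_give_half(self):
        # two ages whose fitted ln R are mu_lo/mu_hi; observed ln R pushed
        # outward by half the fitted spread, so Var(fit) = Var(residual)
        theta = ParameterDraw(1.0, 0.0, 1.0, 1.0)
        mu_lo, mu_hi = -0.7, -0.1
        a_lo = age_at_ratio(theta, math.exp(mu_lo))
        a_hi = age_at_ratio(theta, math.exp(mu_hi))
        d = (mu_hi - mu_lo) / 2.0
        obs = [
            ratio_obs(math.exp(mu_lo - d), a_lo),
            ratio_obs(math.exp(mu_hi + d), a_hi),
        ]
        s = make_samples([1.0] * 4, [0.0] * 4, [1.0] * 4, [1.0] * 4)
        assert bayes_r2(s, obs) == pytest.approx(0.5)

    def test_needs_two_observations(self):
        s = make_samples([1.0] * 4, [0.0] * 4, [1.0] * 4, [1.0] * 4)
        with pytest.raises(ValueError):
            bayes_r2(s, [ratio_obs(0.5, 1.0)])
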