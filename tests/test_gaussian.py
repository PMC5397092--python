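"""Univariate Gaussian decision core: thresholds, tails, overall error."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from celldecide import (
    DecisionPriors,
    EQUAL_PRIORS,
    GaussianResponseModel,
    CellDecideError,
    DegenerateDataError,
    NoThresholdError,
    OrientationError,
    analyze_gaussian_pair,
    error_probabilities,
    error_vs_threshold,
    exact_region_error_probabilities,
    fit_gaussian,
    ml_threshold,
    overall_error,
    q_function,
)
from celldecide.gaussian import decide_h1_region


class TestQFunction:
    def test_half_at_zero(self):
        assert q_function(0.0) == pytest.approx(0.5, abs=1e-15)

    def test_reference_value(self):
        # frozen from numerical quadrature of the upper-tail integral
        assert q_function(1.96) == pytest.approx(0.0249979, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-8, 8))
    def test_complement_identity(self, eta):
        assert q_function(eta) + q_function(-eta) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing(self):
        grid = np.linspace(-6, 6, 200)
        vals = q_function(grid)
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_rejects_non_finite(self, bad):
        with pytest.raises(CellDecideError):
            q_function(bad)


class TestFitGaussian:
    def test_mean_of_two_points(self):
        model = fit_gaussian([0.0, 2.0])
        assert model.mean == pytest.approx(1.0)
        assert model.variance == pytest.approx(2.0)  # unbiased, n-1 denominator

    def test_zero_spread_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_gaussian([1.5] * 20)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_gaussian([1.0])

    def test_parameter_recovery_at_large_n(self, rng):
        draws = rng.normal(3.0, 2.0, size=100_000)
        model = fit_gaussian(draws)
        assert model.mean == pytest.approx(3.0, abs=0.05)
        assert model.variance == pytest.approx(4.0, abs=0.15)


class TestMLThreshold:
    def test_symmetric_midpoint(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        assert ml_threshold(m0, m1) == pytest.approx(1.0, abs=1e-12)

    def test_radar_equivalent_amplitude_over_two(self):
        # constant signal A=2 in unit noise: optimal threshold A/2 = 1
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        assert ml_threshold(m0, m1, EQUAL_PRIORS) == pytest.approx(1.0)

    def test_unequal_variances_matches_bisection_oracle(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(3.0, 4.0)
        oracle = optimize.brentq(
            lambda x: m1.pdf(x) - m0.pdf(x), 0.0, 3.0, xtol=1e-10
        )
        assert ml_threshold(m0, m1) == pytest.approx(oracle, abs=1e-6)

    def test_prior_weighted_density_equality_holds(self):
        m0 = GaussianResponseModel(0.2, 0.5)
        m1 = GaussianResponseModel(1.7, 2.5)
        priors = DecisionPriors(0.7, 0.3)
        th = ml_threshold(m0, m1, priors)
        d0 = priors.p_h0 * m0.pdf(th)
        d1 = priors.p_h1 * m1.pdf(th)
        assert abs(d0 - d1) <= 1e-9 * max(d0, d1)

    def test_skewed_priors_shift_threshold_toward_rarer_hypothesis(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        # more prior mass on H0 pushes the decide-H1 region further out
        assert ml_threshold(m0, m1, DecisionPriors(0.8, 0.2)) > 1.0

    def test_identical_models_rejected(self):
        m = GaussianResponseModel(1.0, 1.0)
        with pytest.raises(NoThresholdError):
            ml_threshold(m, m)

    def test_no_crossing_between_means_reported(self):
        # narrow H1 right next to a broad H0: densities do not cross
        # between the means, so the single-threshold treatment is refused
        m0 = GaussianResponseModel(0.0, 4.0)
        m1 = GaussianResponseModel(0.1, 0.01)
        with pytest.raises(NoThresholdError, match="between the means"):
            ml_threshold(m0, m1)

    @settings(derandomize=True, max_examples=50)
    @given(
        mu0=st.floats(0, 5),
        delta=st.floats(0.5, 5),
        v0=st.floats(0.2, 4),
        v1=st.floats(0.2, 4),
    )
    def test_threshold_lies_between_the_means(self, mu0, delta, v0, v1):
        m0 = GaussianResponseModel(mu0, v0)
        m1 = GaussianResponseModel(mu0 + delta, v1)
        try:
            th = ml_threshold(m0, m1)
        except NoThresholdError:
            return  # legitimate degenerate geometry
        assert mu0 < th < mu0 + delta


class TestErrorProbabilities:
    def test_symmetric_case_equals_q_of_one(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        p_fa, p_m = error_probabilities(m0, m1, 1.0)
        assert p_fa == pytest.approx(0.1587, abs=1e-4)
        assert p_m == pytest.approx(0.1587, abs=1e-4)

    def test_infinite_threshold_limits(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        assert error_probabilities(m0, m1, math.inf) == (0.0, 1.0)
        assert error_probabilities(m0, m1, -math.inf) == (1.0, 0.0)

    def test_orientation_violation_raises(self):
        m0 = GaussianResponseModel(2.0, 1.0)
        m1 = GaussianResponseModel(0.0, 1.0)
        with pytest.raises(OrientationError):
            error_probabilities(m0, m1, 1.0)

    @pytest.mark.parametrize(
        "m0, m1",
        [
            (GaussianResponseModel(0.0, 1.0), GaussianResponseModel(2.0, 1.0)),
            (GaussianResponseModel(0.3, 0.4), GaussianResponseModel(2.1, 2.9)),
            (GaussianResponseModel(1.0, 2.0), GaussianResponseModel(4.0, 0.5)),
        ],
    )
    def test_closed_form_matches_tail_quadrature(self, m0, m1):
        th = ml_threshold(m0, m1)
        p_fa, p_m = error_probabilities(m0, m1, th)
        q_fa = integrate.quad(m0.pdf, th, np.inf)[0]
        q_m = integrate.quad(m1.pdf, -np.inf, th)[0]
        assert p_fa == pytest.approx(q_fa, abs=1e-8)
        assert p_m == pytest.approx(q_m, abs=1e-8)


class TestExactRegion:
    def test_reduces_to_single_threshold_for_equal_variances(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        exact = exact_region_error_probabilities(m0, m1)
        closed = error_probabilities(m0, m1, ml_threshold(m0, m1))
        assert exact == pytest.approx(closed, abs=1e-12)

    def test_region_masses_match_quadrature(self):
        m0 = GaussianResponseModel(0.0, 4.0)
        m1 = GaussianResponseModel(0.8, 0.25)  # decide-H1 region is an interval
        region = decide_h1_region(m0, m1)
        p_fa, p_m = exact_region_error_probabilities(m0, m1)
        q_fa = sum(integrate.quad(m0.pdf, a, b)[0] for a, b in region)
        q_m = 1.0 - sum(integrate.quad(m1.pdf, a, b)[0] for a, b in region)
        assert p_fa == pytest.approx(q_fa, abs=1e-8)
        assert p_m == pytest.approx(q_m, abs=1e-8)

    def test_exact_bayes_never_beaten_by_single_threshold(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(3.0, 4.0)
        p_fa, p_m = exact_region_error_probabilities(m0, m1)
        bayes_pe = overall_error(p_fa, p_m)
        th_pe = analyze_gaussian_pair(m0, m1).p_e
        assert bayes_pe <= th_pe + 1e-12


class TestOverallError:
    def test_late_response_example(self):
        assert overall_error(0.2, 0.29) == pytest.approx(0.245)

    def test_early_response_example(self):
        assert overall_error(0.04, 0.1) == pytest.approx(0.07)

    def test_zero_errors(self):
        assert overall_error(0.0, 0.0, DecisionPriors(0.9, 0.1)) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        p_fa=st.floats(0, 1),
        p_m=st.floats(0, 1),
        p_h0=st.floats(0.01, 0.99),
    )
    def test_linear_in_priors(self, p_fa, p_m, p_h0):
        priors = DecisionPriors(p_h0, 1.0 - p_h0)
        expected = p_h0 * p_fa + (1.0 - p_h0) * p_m
        assert overall_error(p_fa, p_m, priors) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_prior_limit(self):
        # as P(H0) -> 1 the overall error approaches the false-alarm rate
        assert overall_error(0.3, 0.9, DecisionPriors(1 - 1e-9, 1e-9)) == \
            pytest.approx(0.3, abs=1e-8)

    def test_out_of_range_rejected(self):
        with pytest.raises(CellDecideError):
            overall_error(1.2, 0.1)


class TestErrorVsThreshold:
    def test_minimizer_matches_optimal_threshold(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(3.0, 4.0)
        grid = np.linspace(-2, 6, 4001)
        curve = error_vs_threshold(m0, m1, EQUAL_PRIORS, grid)
        best = curve[np.argmin(curve[:, 1]), 0]
        assert abs(best - ml_threshold(m0, m1)) <= grid[1] - grid[0]

    def test_symmetric_models_give_symmetric_curve(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        grid = np.linspace(-1, 3, 401)
        curve = error_vs_threshold(m0, m1, EQUAL_PRIORS, grid)
        assert curve[:, 1] == pytest.approx(curve[::-1, 1], abs=1e-12)

    def test_values_are_probabilities(self, rng):
        m0 = GaussianResponseModel(0.0, 0.5)
        m1 = GaussianResponseModel(1.0, 2.0)
        grid = np.sort(rng.uniform(-5, 5, 100))
        curve = error_vs_threshold(m0, m1, EQUAL_PRIORS, grid)
        assert np.all((curve[:, 1] >= 0) & (curve[:, 1] <= 1))

    def test_empty_grid_rejected(self):
        m0 = GaussianResponseModel(0.0, 1.0)
        m1 = GaussianResponseModel(2.0, 1.0)
        with pytest.raises(CellDecideError):
            error_vs_threshold(m0, m1, EQUAL_PRIORS, [])


class TestInvariants:
    def test_errors_vanish_with_growing_separation(self):
        seps = np.linspace(1.0, 12.0, 12)
        p_fas, p_ms = [], []
        for d in seps:
            m0 = GaussianResponseModel(0.0, 1.0)
            m1 = GaussianResponseModel(float(d), 2.0)
            p_fa, p_m = error_probabilities(m0, m1, ml_threshold(m0, m1))
            p_fas.append(p_fa)
            p_ms.append(p_m)
        assert np.all(np.diff(p_fas) < 0)
        assert np.all(np.diff(p_ms) < 0)
        assert p_fas[-1] < 1e-6 and p_ms[-1] < 1e-6

    def test_equal_prior_error_at_most_half(self, rng):
        for _ in range(100):
            mu = np.sort(rng.uniform(0, 5, 2))
            v = rng.uniform(0.1, 4, 2)
            m0 = GaussianResponseModel(mu[0], v[0])
            m1 = GaussianResponseModel(mu[1], v[1])
            try:
                th = ml_threshold(m0, m1)
            except NoThresholdError:
                continue
            p_fa, p_m = error_probabilities(m0, m1, th)
            assert overall_error(p_fa, p_m) <= 0.5 + 1e-12
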