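"""Link functions, standardization, and likelihood machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dynocc.model_core import (
    CovariateSet,
    DetectionHistory,
    DOMParams,
    brute_force_loglik,
    complete_data_loglik,
    detection_prob,
    inv_logit,
    logit,
    marginal_loglik,
    occupancy_prob,
    recursive_occupancy,
    standardize,
)

from conftest import STD_IDENTITY, make_covs, make_history


def single_cell_setup(n_reps=1, psi=0.5, p=0.5, n_sites=1, n_seasons=1,
                      phi=(), gamma=()):
    """Intercept-only parameters hitting exactly psi and p, with zeroed
    covariates so the linear predictors reduce to their intercepts."""
    params = DOMParams(alpha=[logit(p), 0, 0, 0], beta=[logit(psi)],
                       phi=phi, gamma=gamma)
    covs = CovariateSet(
        depth=np.zeros(n_sites), rdmv=np.zeros(n_sites),
        curmax=np.zeros(n_sites),
        bottom_type=np.array(["canopy"] * n_sites),
        current=np.zeros((n_sites, n_seasons, n_reps)),
        effort=np.zeros((n_sites, n_seasons, n_reps)),
        standardization_constants=STD_IDENTITY)
    return params, covs


class TestLinks:
    def test_symmetry_point(self):
        assert inv_logit(0.0) == 0.5

    def test_detection_intercept_value(self):
        # 1 / (1 + e^1.57), the canopy-at-mean-current detection rate
        assert inv_logit(-1.57) == pytest.approx(1 / (1 + math.exp(1.57)), abs=1e-12)
        assert inv_logit(-1.57) == pytest.approx(0.17222, abs=1e-4)

    @given(st.floats(0.001, 0.999))
    def test_round_trip(self, p):
        assert inv_logit(logit(p)) == pytest.approx(p, rel=1e-9)

    def test_saturation(self):
        assert inv_logit(800.0) == 1.0 and inv_logit(-800.0) == 0.0


class TestStandardize:
    def test_hand_example(self):
        covs = make_covs(3, 1, 1, standardized=False)
        covs.depth = np.array([1.0, 2.0, 3.0])
        out = standardize(covs)
        np.testing.assert_allclose(out.depth, [-1.0, 0.0, 1.0])
        assert out.standardization_constants["depth"] == (2.0, 1.0)

    def test_mean_zero_sd_one(self):
        covs = standardize(make_covs(20, 3, 2, np.random.default_rng(1),
                                     standardized=False))
        for name in ("depth", "rdmv", "curmax"):
            v = getattr(covs, name)
            assert abs(v.mean()) < 1e-10 and abs(v.std(ddof=1) - 1) < 1e-10

    def test_already_standardized_constants(self):
        covs = make_covs(50, 2, 2, np.random.default_rng(2), standardized=False)
        covs.depth = (covs.depth - covs.depth.mean()) / covs.depth.std(ddof=1)
        out = standardize(covs)
        mean, sd = out.standardization_constants["depth"]
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out.depth, covs.depth, atol=1e-12)

    def test_constant_covariate_errors(self):
        covs = make_covs(3, 1, 1, standardized=False)
        covs.rdmv = np.array([5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="rdmv"):
            standardize(covs)


class TestLinearPredictors:
    def test_intercept_only_occupancy(self):
        params = DOMParams(alpha=[0] * 4, beta=[0, 0, 0, 0, 0], phi=[], gamma=[])
        assert occupancy_prob(params, 1.3, -0.2, 0.8) == 0.5

    def test_occupancy_fitted_intercept(self):
        # model-B occupancy coefficients at covariate means
        params = DOMParams(alpha=[0] * 4, beta=[1.41, -1.66, 0.99, 0.04, 0.17],
                           phi=[], gamma=[])
        assert occupancy_prob(params, 0, 0, 0) == pytest.approx(0.80377, abs=1e-4)

    def test_indicator_zeroing(self):
        params = DOMParams(alpha=[0] * 4, beta=[1.41, -1.66, 0.99, 0.04, 0.17],
                           phi=[], gamma=[], w_beta=[1, 0, 0, 0, 0])
        assert occupancy_prob(params, 2.0, -1.0, 3.0) == pytest.approx(
            inv_logit(1.41), rel=1e-12)

    def test_detection_all_zero(self):
        params = DOMParams(alpha=[0, 0, 0, 0], beta=[0], phi=[], gamma=[])
        assert detection_prob(params, 1.7, 1.0) == 0.5

    def test_detection_fitted_values(self):
        params = DOMParams(alpha=[-1.57, -1.26, 3.01, 1.77], beta=[0],
                           phi=[], gamma=[])
        # canopy-absent at +1 sd current: logit p = 1.95
        assert detection_prob(params, 1.0, 1.0) == pytest.approx(0.87544, abs=1e-4)
        # canopy at mean current: logit p = -1.57
        assert detection_prob(params, 0.0, 0.0) == pytest.approx(0.17222, abs=1e-4)

    def test_missing_covariate_errors(self):
        params = DOMParams(alpha=[0] * 5, beta=[0], phi=[], gamma=[])
        with pytest.raises(ValueError, match="effort"):
            detection_prob(params, 0.0, 0.0, effort=None)
        with pytest.raises(ValueError, match="missing"):
            detection_prob(params, np.nan, 0.0, effort=0.0)

    @pytest.mark.parametrize("slope_sign", [1.0, -1.0])
    def test_monotone_in_current(self, slope_sign):
        params = DOMParams(alpha=[0.3, slope_sign * 0.8, 0, 0], beta=[0],
                           phi=[], gamma=[])
        grid = np.linspace(-2, 2, 9)
        p = detection_prob(params, grid, np.zeros_like(grid))
        diffs = np.diff(p) * slope_sign
        assert (diffs > 0).all()


class TestCompleteDataLoglik:
    def test_single_detection(self):
        params, covs = single_cell_setup(psi=1.0, p=0.5)
        hist = make_history([[[1]]])
        ll = complete_data_loglik(params, np.array([[1]]), hist, covs)
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_impossible_history(self):
        # occupied with perfect detection yet no detection in season 2
        params, covs = single_cell_setup(psi=0.5, p=1.0, n_seasons=2,
                                         phi=[1.0], gamma=[0.0])
        hist = make_history([[[1], [0]]])
        ll = complete_data_loglik(params, np.array([[1, 1]]), hist, covs)
        assert ll == -np.inf

    def test_two_replicates(self):
        params, covs = single_cell_setup(n_reps=2, psi=0.5, p=0.5)
        hist = make_history([[[0, 0]]])
        ll = complete_data_loglik(params, np.array([[1]]), hist, covs)
        assert ll == pytest.approx(math.log(0.125), abs=1e-12)

    def test_dimension_mismatch(self):
        params, covs = single_cell_setup()
        hist = make_history([[[0]]])
        with pytest.raises(ValueError):
            complete_data_loglik(params, np.zeros((2, 2)), hist, covs)


class TestMarginalLoglik:
    def test_hand_enumeration(self):
        params, covs = single_cell_setup(psi=0.5, p=0.5)
        hist = make_history([[[0]]])
        assert marginal_loglik(params, hist, covs) == pytest.approx(
            math.log(0.75), abs=1e-12)

    def test_certain_history(self):
        params, covs = single_cell_setup(psi=1.0, p=1.0, n_reps=2)
        hist = make_history([[[1, 1]]])
        assert marginal_loglik(params, hist, covs) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            hist, covs, params = _random_instance(rng, 2, 2)
            assert marginal_loglik(params, hist, covs) == pytest.approx(
                brute_force_loglik(params, hist, covs), abs=1e-8)

    def test_perfect_detection_reduces_to_complete_data(self):
        # p=1 and a replicate everywhere: z is fully determined by the data
        rng = np.random.default_rng(3)
        params, covs = single_cell_setup(psi=0.6, p=1.0, n_sites=4,
                                         n_seasons=3, phi=[0.7, 0.7],
                                         gamma=[0.3, 0.3])
        covs.current = np.zeros((4, 3, 1))
        covs.effort = np.zeros((4, 3, 1))
        z = (rng.random((4, 3)) < 0.5).astype(np.int8)
        hist = make_history(z[:, :, None])
        assert marginal_loglik(params, hist, covs) == pytest.approx(
            complete_data_loglik(params, z, hist, covs), abs=1e-9)


class TestBruteForce:
    def test_single_cell_closed_form(self):
        psi, p = 0.37, 0.62
        params, covs = single_cell_setup(n_reps=2, psi=psi, p=p)
        hist = make_history([[[1, 0]]])
        expected = psi * p * (1 - p)
        assert brute_force_loglik(params, hist, covs) == pytest.approx(
            math.log(expected), abs=1e-10)

    def test_enumeration_bound(self):
        params, covs = single_cell_setup(n_sites=5, n_seasons=4,
                                         phi=[0.5] * 3, gamma=[0.5] * 3)
        hist = make_history(np.zeros((5, 4, 1)))
        with pytest.raises(ValueError, match="enumeration"):
            brute_force_loglik(params, hist, covs)


class TestIndicatorEquivalence:
    def test_w_zero_equals_dropped_column(self):
        rng = np.random.default_rng(7)
        hist, covs, params = _random_instance(rng, 3, 2)
        for k in range(1, 4):
            w = np.ones(4, dtype=np.int8)
            w[k] = 0
            with_w = DOMParams(alpha=params.alpha, beta=params.beta,
                               phi=params.phi, gamma=params.gamma, w_alpha=w)
            alpha0 = params.alpha.copy()
            alpha0[k] = 0.0
            if k in (1, 2):
                alpha0[3] = 0.0  # product rule silences the interaction too
            zeroed = DOMParams(alpha=alpha0, beta=params.beta,
                               phi=params.phi, gamma=params.gamma)
            assert marginal_loglik(with_w, hist, covs) == pytest.approx(
                marginal_loglik(zeroed, hist, covs), abs=1e-10)


class TestRecursiveOccupancy:
    def test_hand_recursion(self):
        np.testing.assert_allclose(
            recursive_occupancy(0.5, [1, 1], [1, 1]), [0.5, 1.0, 1.0])

    def test_fixed_point(self):
        out = recursive_occupancy(0.9, [0.3] * 4, [0.3] * 4)
        np.testing.assert_allclose(out[1:], 0.3, atol=1e-12)

    def test_certain_extinction(self):
        np.testing.assert_allclose(
            recursive_occupancy(1.0, [0, 0], [0, 0]), [1.0, 0.0, 0.0])

    def test_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        out = recursive_occupancy(rng.random(10), rng.random(6), rng.random(6))
        assert ((out >= 0) & (out <= 1)).all()


def _random_instance(rng, n_sites, n_seasons, max_reps=2):
    mask = rng.random((n_sites, n_seasons, max_reps)) < 0.8
    mask[:, :, 0] = True
    y = ((rng.random(mask.shape) < 0.4) & mask).astype(np.int8)
    covs = make_covs(n_sites, n_seasons, max_reps, rng)
    params = DOMParams(
        alpha=rng.normal(size=4), beta=rng.normal(size=5),
        phi=rng.uniform(size=n_seasons - 1), gamma=rng.uniform(size=n_seasons - 1))
    return make_history(y, mask), covs, params
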