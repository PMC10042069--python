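"""Calibrator tests: closed-form oracles, density-ratio checks, split protocol."""

import math

import numpy as np
import pytest
from scipy import stats

from detcal.detection_io import CalibrationRecord
from detcal.calibration import (
    CalibratorParams,
    FeatureSpec,
    FittingError,
    SplitProtocol,
    apply_calibration,
    build_feature_vector,
    calibration_map,
    fit_dependent_logistic,
    fit_gaussian_lr,
    log_likelihood_ratio,
    split_fit_test,
)

from conftest import random_records

SPEC_3D_RAW = FeatureSpec(("conf", "cx", "cy"), logit_conf=False)


def manual_params(mu_p, mu_m, sig_p, sig_m, c, spec=None, n_p=10, n_m=10):
    d = len(mu_p)
    if spec is None:
        spec = FeatureSpec(tuple(["conf", "cx", "cy"][:d]), logit_conf=False)
    return CalibratorParams(spec, np.array(mu_p, float), np.array(mu_m, float),
                            np.array(sig_p, float), np.array(sig_m, float),
                            c=c, regularization=0.0, n_plus=n_p, n_minus=n_m)


class TestFeatureSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            FeatureSpec(())
        with pytest.raises(ValueError):
            FeatureSpec(("conf", "conf"))
        with pytest.raises(ValueError):
            FeatureSpec(("width",))
        with pytest.raises(ValueError):
            FeatureSpec(("conf",), eps=0.5)


class TestBuildFeatureVector:
    def test_assembly_order(self):
        r = CalibrationRecord("a", 0, 0.9, 0.25, 0.5, 1)
        s = build_feature_vector(r, SPEC_3D_RAW)
        assert s.tolist() == [0.9, 0.25, 0.5]
        s2 = build_feature_vector(r, FeatureSpec(("cy", "conf"), logit_conf=False))
        assert s2.tolist() == [0.5, 0.9]

    def test_logit_transform(self):
        r = CalibrationRecord("a", 0, 0.5, 0.5, 0.5, 1)
        spec = FeatureSpec(("conf",), logit_conf=True, eps=1e-6)
        assert build_feature_vector(r, spec)[0] == pytest.approx(0.0, abs=1e-12)
        r1 = CalibrationRecord("a", 0, 1.0, 0.5, 0.5, 1)
        expected = math.log((1 - 1e-6) / 1e-6)
        assert build_feature_vector(r1, spec)[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(13.8155, abs=1e-4)


class TestLogLikelihoodRatio:
    def test_symmetric_1d_midpoint_and_hand_value(self):
        p = manual_params([1.0], [0.0], [[1.0]], [[1.0]], c=0.0)
        assert log_likelihood_ratio(p, np.array([0.5])) == pytest.approx(0.0, abs=1e-12)
        assert log_likelihood_ratio(p, np.array([1.5])) == pytest.approx(1.0, abs=1e-12)

    def test_density_ratio_oracle_random_params(self, rng):
        """lr must equal the explicit two-Gaussian log density ratio plus prior log-odds."""
        for _ in range(50):
            d = int(rng.integers(1, 4))
            mu_p, mu_m = rng.normal(0, 1, d), rng.normal(0, 1, d)
            A, B = rng.normal(0, 1, (d, d)), rng.normal(0, 1, (d, d))
            sig_p = A @ A.T + 0.3 * np.eye(d)
            sig_m = B @ B.T + 0.3 * np.eye(d)
            n_p, n_m = int(rng.integers(5, 500)), int(rng.integers(5, 500))
            c = 0.5 * (np.linalg.slogdet(sig_m)[1] - np.linalg.slogdet(sig_p)[1]) \
                + math.log(n_p / n_m)
            params = manual_params(mu_p, mu_m, sig_p, sig_m, c, n_p=n_p, n_m=n_m)
            s = rng.normal(0, 2, d)
            expected = (
                stats.multivariate_normal(mu_p, sig_p).logpdf(s) + math.log(n_p)
                - stats.multivariate_normal(mu_m, sig_m).logpdf(s) - math.log(n_m)
            )
            assert log_likelihood_ratio(params, s) == pytest.approx(expected, abs=1e-9)

    def test_dimension_mismatch(self):
        p = manual_params([1.0], [0.0], [[1.0]], [[1.0]], c=0.0)
        with pytest.raises(ValueError):
            log_likelihood_ratio(p, np.zeros(3))


class TestCalibrationMap:
    def test_sigmoid_values(self):
        p = manual_params([1.0], [0.0], [[1.0]], [[1.0]], c=0.0)
        assert calibration_map(p, np.array([0.5])) == pytest.approx(0.5, abs=1e-12)
        assert calibration_map(p, np.array([1.5])) == pytest.approx(0.731059, abs=1e-6)

    def test_output_in_open_unit_interval_and_monotone_in_lr(self, rng):
        p = manual_params([1.0, 0.0], [0.0, 0.0], np.eye(2), np.eye(2), c=0.3)
        # equal covariances: lr is affine, so g is monotone along the gradient
        ts = np.linspace(-5, 5, 41)
        grid = np.column_stack([ts, 0.2 * ts])
        g = calibration_map(p, grid)
        lr = log_likelihood_ratio(p, grid)
        order = np.argsort(lr)
        assert np.all(np.diff(g[order]) > 0)
        assert np.all((g > 0) & (g < 1))


class TestFit:
    def test_identical_populations_give_flat_half(self, rng):
        n = 20_000
        X = rng.normal(0, 1, (2 * n, 2))
        z = np.r_[np.ones(n), np.zeros(n)]
        spec = FeatureSpec(("conf", "cx"), logit_conf=False)
        params = fit_gaussian_lr(X, z, spec)
        grid = rng.normal(0, 1, (500, 2))
        g = calibration_map(params, grid)
        assert np.abs(g - 0.5).mean() <= 0.02
        assert abs(params.c) <= 0.05  # equal sizes: prior log-odds is 0

    def test_equal_variance_1d_recovers_sigmoid_posterior(self, rng):
        n = 50_000
        X = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)].reshape(-1, 1)
        z = np.r_[np.ones(n), np.zeros(n)]
        params = fit_gaussian_lr(X, z, FeatureSpec(("conf",), logit_conf=False))
        grid = np.linspace(-2, 3, 200).reshape(-1, 1)
        g = calibration_map(params, grid)
        truth = 1 / (1 + np.exp(-(grid[:, 0] - 0.5)))
        assert np.abs(g - truth).mean() <= 0.01

    def test_population_minimum_enforced(self, rng):
        recs = random_records(rng, 50)
        only_pos = [r for r in recs if r.z == 1][:3] + [r for r in recs if r.z == 0]
        # 3 correct records < K+2 = 4 for the 3-feature spec
        with pytest.raises(FittingError, match="z=1"):
            fit_dependent_logistic(only_pos[:3] + [r for r in recs if r.z == 0][:20],
                                   SPEC_3D_RAW)

    def test_nonfinite_features_rejected(self):
        with pytest.raises(FittingError):
            fit_gaussian_lr(np.array([[np.nan], [0.0], [1.0], [2.0]]),
                            np.array([1, 1, 0, 0]), FeatureSpec(("conf",), logit_conf=False))

    def test_matches_independent_qda_posterior(self, rng):
        """Cross-check against scikit-learn's QDA posterior on the same data."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        n = 3000
        X = np.vstack([
            rng.multivariate_normal([0.5, 0.2, -0.1], np.diag([1.0, 0.5, 2.0]), n),
            rng.normal(0, 1, (n, 3)),
        ])
        z = np.r_[np.ones(n), np.zeros(n)]
        params = fit_gaussian_lr(X, z, SPEC_3D_RAW, regularization=0.0)
        qda = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, z)
        grid = rng.normal(0, 1.5, (300, 3))
        np.testing.assert_allclose(
            calibration_map(params, grid), qda.predict_proba(grid)[:, 1], atol=1e-8)

    def test_prior_term_matches_population_imbalance(self, rng):
        n_p, n_m = 30_000, 10_000
        X = np.r_[rng.normal(0, 1, n_p), rng.normal(0, 1, n_m)].reshape(-1, 1)
        z = np.r_[np.ones(n_p), np.zeros(n_m)]
        spec = FeatureSpec(("conf",), logit_conf=False)
        params = fit_gaussian_lr(X, z, spec)
        assert params.c == pytest.approx(math.log(3.0), abs=0.05)
        strict = fit_gaussian_lr(X, z, spec, include_prior=False)
        assert strict.c == pytest.approx(0.0, abs=0.05)


class TestApplyCalibration:
    def test_records_keep_original_confidence(self, rng):
        recs = random_records(rng, 500)
        params = fit_dependent_logistic(recs, SPEC_3D_RAW)
        out = apply_calibration(params, recs)
        for before, after in zip(recs, out):
            assert after.confidence == before.confidence
            assert 0.0 < after.calibrated_confidence < 1.0

    def test_empty_input(self, rng):
        params = fit_dependent_logistic(random_records(rng, 100), SPEC_3D_RAW)
        assert apply_calibration(params, []) == []


class TestParamsSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        recs = random_records(rng, 2000)
        params = fit_dependent_logistic(recs, FeatureSpec(("conf", "cx", "cy")))
        path = tmp_path / "params.json"
        params.to_json(path)
        back = CalibratorParams.from_json(path)
        assert back.feature_spec == params.feature_spec
        np.testing.assert_allclose(back.mu_plus, params.mu_plus, atol=0)
        np.testing.assert_allclose(back.sigma_minus, params.sigma_minus, atol=0)
        assert back.c == params.c and back.n_plus == params.n_plus
        s = np.array([0.3, 0.4, 0.5])
        assert log_likelihood_ratio(back, s) == log_likelihood_ratio(params, s)


class TestSplitProtocol:
    def test_sixty_forty_sizes(self, rng):
        recs = random_records(rng, 10)
        fit, test = split_fit_test(recs, SplitProtocol(0.6, seed=4, stratify_by_z=False))
        assert (len(fit), len(test)) == (6, 4)
        assert sorted((r.confidence for r in fit + test)) == sorted(
            r.confidence for r in recs)

    def test_deterministic_given_seed(self, rng):
        recs = random_records(rng, 101)
        a = split_fit_test(recs, SplitProtocol(0.6, seed=9))
        b = split_fit_test(recs, SplitProtocol(0.6, seed=9))
        assert a == b
        c = split_fit_test(recs, SplitProtocol(0.6, seed=10))
        assert a != c

    def test_stratified_preserves_z_ratio(self, rng):
        recs = random_records(rng, 1000)
        recs = [r for r in recs if r.z == 1][:30] + [r for r in recs if r.z == 0][:70]
        fit, test = split_fit_test(recs, SplitProtocol(0.6, seed=0, stratify_by_z=True))
        n_pos_fit = sum(r.z for r in fit)
        assert abs(n_pos_fit - 18) <= 1
        assert len(fit) + len(test) == 100

    def test_degenerate_splits_error(self, rng):
        with pytest.raises(ValueError):
            split_fit_test(random_records(rng, 1), SplitProtocol(0.5))
        with pytest.raises(ValueError):
            SplitProtocol(fit_fraction=1.0)
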