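import numpy as np
import pytest

from cognorm import crossval_normative, fit_gp, predict_gp
from cognorm.normative import mean_standardized_log_loss


def make_covariates(n, seed=0, age_range=(8, 21)):
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, n)
    sex = (rng.random(n) < 0.5).astype(float)
    return np.column_stack([age, sex]), rng


class TestFitGP:
    def test_noise_free_linear_recovery(self):
        X, _ = make_covariates(60, seed=1)
        y = 0.3 * X[:, 0]
        model = fit_gp(X, y, seed=0)
        assert model.noise_variance < 1e-4 * model.signal_variance

    def test_null_signal_fit(self):
        X, rng = make_covariates(1000, seed=2)
        y = rng.standard_normal(1000)
        model = fit_gp(X, y, seed=0)
        assert model.signal_variance / model.noise_variance < 0.1

    def test_exactly_two_predictors_required(self):
        X, rng = make_covariates(50, seed=3)
        y = rng.standard_normal(50)
        with pytest.raises(ValueError):
            fit_gp(np.column_stack([X, X[:, 0]]), y)
        with pytest.raises(ValueError):
            fit_gp(X[:, :1], y)

    def test_sex_must_be_binary(self):
        X, rng = make_covariates(50, seed=4)
        X[:, 1] = rng.uniform(0, 2, 50)
        with pytest.raises(ValueError, match="sex"):
            fit_gp(X, rng.standard_normal(50))

    def test_too_few_subjects_rejected(self):
        X, rng = make_covariates(10, seed=5)
        with pytest.raises(ValueError):
            fit_gp(X, rng.standard_normal(10))

    def test_noise_sd_parameter_recovery(self):
        # constant residual SD sigma: fitted noise SD within 10% at n=2000
        X, rng = make_covariates(2000, seed=6)
        sigma = 0.5
        y = -4.0 + 1.5 * np.log(X[:, 0]) + 0.2 * X[:, 1] + sigma * rng.standard_normal(2000)
        model = fit_gp(X, y, seed=0)
        fitted_noise_sd = np.sqrt(model.noise_variance) * model.y_sd
        assert abs(fitted_noise_sd - sigma) / sigma < 0.10


class TestPredictGP:
    def test_interpolates_training_points_with_tiny_noise(self):
        X, _ = make_covariates(40, seed=7)
        y = np.sin(X[:, 0] / 2.0) + 0.3 * X[:, 1]
        model = fit_gp(X, y, seed=0)
        pred = predict_gp(model, X)
        sd_units = np.abs(pred.mean - y) / np.std(y)
        assert np.max(sd_units) < 1e-2

    def test_uncertainty_grows_off_support(self):
        X, rng = make_covariates(200, seed=8, age_range=(10, 15))
        y = 0.5 * X[:, 0] + rng.standard_normal(200) * 0.3
        model = fit_gp(X, y, seed=0)
        median_age = np.median(X[:, 0])
        inside = predict_gp(model, np.array([[median_age, 0.0]]))
        outside = predict_gp(model, np.array([[45.0, 0.0]]))
        assert outside.sd[0] >= inside.sd[0]

    def test_empty_covariates_give_empty_distribution(self):
        X, rng = make_covariates(40, seed=9)
        model = fit_gp(X, rng.standard_normal(40), seed=0)
        pred = predict_gp(model, np.empty((0, 2)))
        assert pred.mean.size == 0 and pred.sd.size == 0

    def test_nonfinite_covariates_rejected(self):
        X, rng = make_covariates(40, seed=10)
        model = fit_gp(X, rng.standard_normal(40), seed=0)
        with pytest.raises(ValueError):
            predict_gp(model, np.array([[np.inf, 0.0]]))

    def test_predictive_sd_includes_noise(self):
        X, rng = make_covariates(100, seed=11)
        y = rng.standard_normal(100)
        model = fit_gp(X, y, seed=0)
        pred = predict_gp(model, X)
        noise_sd = np.sqrt(model.noise_variance) * model.y_sd
        assert np.all(pred.sd >= noise_sd - 1e-12)

    def test_matches_dense_linear_algebra_oracle(self):
        # brute-force GP posterior via a direct solve of the kernel system
        X, rng = make_covariates(60, seed=12)
        y = 0.4 * np.log(X[:, 0]) + 0.2 * X[:, 1] + 0.2 * rng.standard_normal(60)
        model = fit_gp(X, y, seed=0)
        Xt, _ = make_covariates(5, seed=13)

        a_tr, s_tr = model.train_age, model.train_sex
        a_te = (Xt[:, 0] - model.age_mean) / model.age_sd
        s_te = Xt[:, 1] - model.sex_mean
        vf, ls = model.signal_variance, model.length_scale
        vl, vn = model.sex_variance, model.noise_variance

        def kern(a1, s1, a2, s2):
            return vf * np.exp(-((a1[:, None] - a2[None, :]) ** 2) / (2 * ls**2)) + vl * np.outer(s1, s2)

        K = kern(a_tr, s_tr, a_tr, s_tr) + (vn + 1e-10) * np.eye(a_tr.size)
        Ks = kern(a_te, s_te, a_tr, s_tr)
        Kss = kern(a_te, s_te, a_te, s_te)
        ys = (y - model.y_mean) / model.y_sd
        mean = Ks @ np.linalg.solve(K, ys)
        cov = Kss - Ks @ np.linalg.solve(K, Ks.T)
        sd = np.sqrt(np.diag(cov) + vn)

        pred = predict_gp(model, Xt)
        np.testing.assert_allclose(pred.mean, model.y_mean + model.y_sd * mean, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(pred.sd, model.y_sd * sd, rtol=1e-8)


class TestCrossval:
    def test_k_below_two_rejected(self):
        X, rng = make_covariates(100, seed=14)
        with pytest.raises(ValueError):
            crossval_normative(X, rng.standard_normal(100), k=1)

    def test_insufficient_n_rejected(self):
        X, rng = make_covariates(90, seed=15)
        with pytest.raises(ValueError):
            crossval_normative(X, rng.standard_normal(90), k=10)

    def test_metrics_report_exactly_four_fields(self, gp_calibration):
        metrics = gp_calibration["metrics"].to_dict()
        assert set(metrics) == {"explained_variance", "msll", "rmse", "smse"}

    def test_calibrated_z_on_well_specified_cohort(self, gp_calibration):
        z = gp_calibration["deviations"].z
        assert -0.05 < z.mean() < 0.05
        assert 0.9 < z.std() < 1.1

    def test_msll_negative_when_ev_positive(self, gp_calibration):
        metrics = gp_calibration["metrics"]
        assert metrics.explained_variance > 0.1
        assert metrics.msll < 0

    def test_each_subject_scored_once_by_out_of_fold_model(self, gp_calibration):
        dev = gp_calibration["deviations"]
        assert dev.z.size == 2000
        assert np.all(np.isfinite(dev.z))
        assert set(np.unique(dev.fold_id)) == set(range(1, 11))

    def test_null_targets_give_null_metrics(self):
        X, rng = make_covariates(1000, seed=16)
        y = rng.standard_normal(1000)
        _, metrics = crossval_normative(X, y, k=10, seed=2, max_opt_points=300)
        assert -0.05 < metrics.explained_variance < 0.05
        assert 0.95 < metrics.smse < 1.10

    def test_z_antisymmetry(self):
        rng = np.random.default_rng(17)
        y = rng.standard_normal(50)
        mu = rng.standard_normal(50)
        sd = rng.uniform(0.5, 2.0, 50)
        z = (y - mu) / sd
        z_neg = ((2 * mu - y) - mu) / sd  # negated residuals
        np.testing.assert_allclose(z_neg, -z, atol=1e-14)

    def test_trivial_predictor_has_zero_msll(self):
        rng = np.random.default_rng(18)
        y = rng.standard_normal(200)
        mu, sd = y.mean(), y.std()
        assert mean_standardized_log_loss(y, np.full(200, mu), np.full(200, sd), mu, sd) == 0.0
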