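import numpy as np
import pandas as pd
import pytest

from cognorm import extract_g, fit_pca, impute_cognitive


def make_matrix(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"t{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, columns=columns)
    frame.insert(0, "subject_id", [f"S{i}" for i in range(len(frame))])
    return frame


def exact_corr_pair(r, n=200, seed=0):
    """Two columns whose sample correlation is exactly r."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n, 2))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    z1, z2 = q[:, 0], q[:, 1]  # exactly orthonormal, mean ~0
    x2 = r * z1 + np.sqrt(1 - r**2) * z2
    return make_matrix(np.column_stack([z1, x2]))


class TestImpute:
    def test_complete_rows_untouched(self):
        frame = make_matrix([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        out, excluded = impute_cognitive(frame, max_missing=1)
        pd.testing.assert_frame_equal(out, frame)
        assert excluded == []

    def test_row_exceeding_max_missing_excluded(self):
        values = np.ones((3, 7))
        values[1, :6] = np.nan  # 6 missing > max_missing=5
        out, excluded = impute_cognitive(make_matrix(values), max_missing=5)
        assert excluded == ["S1"]
        assert list(out["subject_id"]) == ["S0", "S2"]

    def test_column_mean_imputation(self):
        values = np.array([[2.0, 1.0], [4.0, 1.0], [np.nan, 1.0]])
        out, _ = impute_cognitive(make_matrix(values), max_missing=1)
        assert out.iloc[2, 1] == pytest.approx(3.0)

    def test_observed_cells_never_change(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((40, 6))
        mask = rng.random((40, 6)) < 0.1
        values[mask] = np.nan
        frame = make_matrix(values)
        out, excluded = impute_cognitive(frame, max_missing=5)
        kept = frame[~frame["subject_id"].isin(excluded)].reset_index(drop=True)
        obs = kept.iloc[:, 1:].notna().to_numpy()
        np.testing.assert_array_equal(
            out.iloc[:, 1:].to_numpy()[obs], kept.iloc[:, 1:].to_numpy()[obs]
        )

    def test_entirely_missing_column_rejected(self):
        values = np.ones((5, 3))
        values[:, 1] = np.nan
        with pytest.raises(ValueError, match="t1"):
            impute_cognitive(make_matrix(values), max_missing=2)

    def test_max_missing_must_be_below_test_count(self):
        with pytest.raises(ValueError):
            impute_cognitive(make_matrix(np.ones((5, 3))), max_missing=3)


class TestFitPCA:
    def test_two_variable_closed_form(self):
        model = fit_pca(exact_corr_pair(0.6))
        assert model.explained_variance[0] == pytest.approx((1 + 0.6) / 2, abs=1e-10)

    def test_orthogonal_columns_give_equal_variance(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((60, 6)) - 0.0)
        q -= q.mean(axis=0)
        model = fit_pca(make_matrix(q))
        # nearly-orthogonal standardized columns: all shares close to 1/6
        np.testing.assert_allclose(model.explained_variance, np.full(6, 1 / 6), atol=0.05)

    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(2)
        model = fit_pca(make_matrix(rng.standard_normal((50, 8))))
        np.testing.assert_allclose(model.contributions.sum(axis=0), 100.0, atol=1e-9)

    def test_explained_variance_nonincreasing_and_sums_to_one(self):
        rng = np.random.default_rng(4)
        model = fit_pca(make_matrix(rng.standard_normal((80, 9))))
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        assert model.explained_variance.sum() == pytest.approx(1.0)

    def test_matches_bruteforce_eigendecomposition(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 7)) @ rng.standard_normal((7, 7))
        model = fit_pca(make_matrix(X))
        eigvals = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(model.explained_variance, eigvals / eigvals.sum(), atol=1e-8)

    def test_zero_variance_column_rejected(self):
        values = np.random.default_rng(6).standard_normal((30, 3))
        values[:, 2] = 5.0
        with pytest.raises(ValueError, match="t2"):
            fit_pca(make_matrix(values))

    def test_missing_values_rejected(self):
        values = np.ones((30, 3)) + np.random.default_rng(0).standard_normal((30, 3))
        values[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_pca(make_matrix(values))

    def test_more_tests_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(make_matrix(np.random.default_rng(0).standard_normal((5, 7))))


class TestExtractG:
    def _correlated_matrix(self, seed=7, n=150, p=5):
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal(n)
        X = latent[:, None] * np.linspace(0.9, 0.5, p) + 0.4 * rng.standard_normal((n, p))
        return make_matrix(X), latent

    def test_sign_invariance_under_negation(self):
        frame, _ = self._correlated_matrix()
        neg = frame.copy()
        neg.iloc[:, 1:] = -neg.iloc[:, 1:]
        g1 = extract_g(fit_pca(frame), frame, anchor_test="t0").g
        g2 = extract_g(fit_pca(neg), neg, anchor_test="t0").g
        # anchor orientation: g correlates positively with the anchor in both
        np.testing.assert_allclose(np.corrcoef(g1, -g2)[0, 1], 1.0, atol=1e-10)

    def test_anchor_correlation_positive(self):
        frame, _ = self._correlated_matrix()
        g = extract_g(fit_pca(frame), frame, anchor_test="t0").g
        assert np.corrcoef(g, frame["t0"])[0, 1] > 0

    def test_recovers_truth_g(self, complete_cohort):
        from cognorm import impute_cognitive

        imputed, _ = impute_cognitive(complete_cohort.cognition)
        g = extract_g(fit_pca(imputed), imputed, anchor_test="WRAT").g
        truth = complete_cohort.truth.set_index("subject_id").loc[g.index, "g"]
        assert abs(np.corrcoef(g, truth)[0, 1]) >= 0.9

    def test_standardized_output(self):
        frame, _ = self._correlated_matrix()
        g = extract_g(fit_pca(frame), frame, anchor_test="t0").g
        assert g.mean() == pytest.approx(0.0, abs=1e-12)
        assert g.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_column_reordering(self):
        frame, _ = self._correlated_matrix()
        cols = ["subject_id", "t3", "t1", "t0", "t4", "t2"]
        reordered = frame[cols]
        g1 = extract_g(fit_pca(frame), frame, anchor_test="t0").g
        g2 = extract_g(fit_pca(reordered), reordered, anchor_test="t0").g
        np.testing.assert_allclose(g1.to_numpy(), g2.to_numpy(), atol=1e-8)

    def test_unknown_anchor_rejected(self):
        frame, _ = self._correlated_matrix()
        with pytest.raises(ValueError, match="anchor"):
            extract_g(fit_pca(frame), frame, anchor_test="nope")
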