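"""PLSC model: residualization, fitting, scores, loadings."""

import numpy as np
import pytest
from scipy import stats

from subpls import (
    DataBlocks,
    ScoreSet,
    SYMPTOM_ITEMS,
    compute_loadings,
    compute_scores,
    fit_pls,
    residualize,
)


class TestResidualize:
    def test_intercept_only_centers_columns(self, rng):
        block = rng.normal(loc=5.0, size=(40, 6))
        out = residualize(block, None)
        np.testing.assert_allclose(out, block - block.mean(axis=0), atol=1e-12)

    def test_exact_linear_dependence_gives_zero_residual(self, rng):
        cov = rng.normal(size=40)
        block = np.column_stack([3.0 * cov + 2.0, rng.normal(size=40)])
        out = residualize(block, cov)
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariate_span(self, rng):
        block = rng.normal(size=(50, 10))
        cov = rng.normal(size=(50, 3))
        out = residualize(block, cov)
        design = np.column_stack([np.ones(50), cov])
        assert np.max(np.abs(design.T @ out)) < 1e-8

    def test_rank_deficient_covariates_raise(self, rng):
        cov = rng.normal(size=(30, 2))
        cov = np.column_stack([cov, cov[:, 0] * 2])
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.normal(size=(30, 4)), cov)


class TestFitPls:
    def test_component_count_is_min_of_items_and_rank(self, rng):
        blocks = DataBlocks(X=rng.normal(size=(100, 200)),
                            Y=rng.normal(size=(100, 37)))
        assert fit_pls(blocks).k == 37

    def test_hand_computed_two_by_two_svd(self):
        # small integer blocks; oracle = per-pair Pearson r (the z-scored
        # cross-covariance) + closed-form 2x2 singular values
        X = np.array([[1, 2], [2, 1], [3, 5], [4, 3], [5, 4]], dtype=float)
        Y = np.array([[2, 1], [1, 3], [4, 2], [3, 5], [5, 4]], dtype=float)
        R = np.array([
            [stats.pearsonr(Y[:, j], X[:, i]).statistic for i in range(2)]
            for j in range(2)
        ])
        g = R @ R.T
        tr, det = g[0, 0] + g[1, 1], g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
        disc = np.sqrt(tr**2 - 4 * det)
        expected = np.sqrt([(tr + disc) / 2, (tr - disc) / 2])
        model = fit_pls(DataBlocks(X=X, Y=Y))
        np.testing.assert_allclose(model.singular_values, expected, atol=1e-10)

    def test_identical_blocks_match_eigendecomposition(self, rng):
        X = rng.normal(size=(40, 6))
        model = fit_pls(DataBlocks(X=X, Y=X.copy()))
        corr = np.corrcoef(X, rowvar=False)
        eig = np.sort(np.abs(np.linalg.eigvalsh(corr)))[::-1]
        np.testing.assert_allclose(model.singular_values, eig, atol=1e-8)
        np.testing.assert_allclose(model.explained_cov, eig**2 / np.sum(eig**2),
                                   atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_singulars_match_brute_force_eigendecomposition(self, seed):
        # independent oracle: per-pair Pearson correlations, then eigh(R'R)
        g = np.random.default_rng(seed)
        n, p, q = g.integers(5, 11), g.integers(2, 6), g.integers(2, 6)
        X, Y = g.normal(size=(n, p)), g.normal(size=(n, q))
        R = np.array([
            [stats.pearsonr(Y[:, j], X[:, i]).statistic for i in range(p)]
            for j in range(q)
        ])
        expected = np.sqrt(np.clip(np.sort(np.linalg.eigvalsh(R.T @ R))[::-1], 0, None))
        model = fit_pls(DataBlocks(X=X, Y=Y))
        k = model.k
        np.testing.assert_allclose(model.singular_values, expected[:k], atol=1e-8)

    def test_salience_orthonormality_and_reconstruction(self, small_blocks):
        model = fit_pls(small_blocks)
        U, V, s = model.mood_saliences, model.fc_saliences, model.singular_values
        np.testing.assert_allclose(U.T @ U, np.eye(model.k), atol=1e-10)
        np.testing.assert_allclose(V.T @ V, np.eye(model.k), atol=1e-10)
        Xs = (small_blocks.X - model.x_mean) / model.x_sd
        Ys = (small_blocks.Y - model.y_mean) / model.y_sd
        R = Ys.T @ Xs / (small_blocks.n - 1)
        np.testing.assert_allclose(U.T @ R @ V, np.diag(s), atol=1e-8)

    def test_explained_covariance_sums_to_one_nonincreasing(self, small_blocks):
        model = fit_pls(small_blocks)
        assert model.explained_cov.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(model.singular_values) <= 1e-12)

    def test_scale_invariance_of_zscored_fit(self, rng):
        X = rng.normal(size=(25, 4))
        Y = rng.normal(size=(25, 3))
        m1 = fit_pls(DataBlocks(X=X, Y=Y))
        X2 = X.copy()
        X2[:, 1] *= 13.5
        m2 = fit_pls(DataBlocks(X=X2, Y=Y))
        np.testing.assert_allclose(m1.singular_values, m2.singular_values, atol=1e-10)
        np.testing.assert_allclose(m1.fc_saliences, m2.fc_saliences, atol=1e-9)

    def test_sign_convention_positive_score_covariance(self, small_blocks):
        model = fit_pls(small_blocks)
        fc, mood = model.training_fc_scores, model.training_mood_scores
        for k in range(model.k):
            cov = np.mean(
                (fc[:, k] - fc[:, k].mean()) * (mood[:, k] - mood[:, k].mean())
            )
            assert cov >= -1e-12
            j = np.argmax(np.abs(model.mood_saliences[:, k]))
            assert model.mood_saliences[j, k] > 0

    def test_degenerate_inputs_raise(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 2] = 4.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pls(DataBlocks(X=X, Y=rng.normal(size=(10, 2))))
        with pytest.raises(ValueError, match="3 subjects"):
            fit_pls(DataBlocks(X=rng.normal(size=(2, 3)), Y=rng.normal(size=(2, 2))))

    def test_missing_values_refused_unless_imputed(self, rng):
        X = rng.normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            DataBlocks(X=X, Y=rng.normal(size=(10, 2)))
        blocks = DataBlocks(X=X.copy(), Y=rng.normal(size=(10, 2)), impute_mean=True)
        assert np.isfinite(blocks.X).all()


class TestScores:
    def test_training_projection_self_consistent(self, small_blocks):
        model = fit_pls(small_blocks)
        scores = compute_scores(model, small_blocks)
        np.testing.assert_allclose(scores.fc_scores, model.training_fc_scores,
                                   atol=1e-12)
        np.testing.assert_allclose(scores.mood_scores, model.training_mood_scores,
                                   atol=1e-12)

    def test_mean_subject_scores_zero(self, small_blocks):
        model = fit_pls(small_blocks)
        mean_blocks = DataBlocks(X=small_blocks.X.mean(axis=0)[None, :],
                                 Y=small_blocks.Y.mean(axis=0)[None, :])
        scores = compute_scores(model, mean_blocks)
        np.testing.assert_allclose(scores.fc_scores, 0.0, atol=1e-12)
        np.testing.assert_allclose(scores.mood_scores, 0.0, atol=1e-12)

    def test_duplicated_subject_scores_identically(self, small_blocks):
        model = fit_pls(small_blocks)
        dup = DataBlocks(X=small_blocks.X[[3, 3]], Y=small_blocks.Y[[3, 3]])
        scores = compute_scores(model, dup)
        np.testing.assert_array_equal(scores.fc_scores[0], scores.fc_scores[1])

    def test_dimension_mismatch_raises(self, small_blocks, rng):
        model = fit_pls(small_blocks)
        with pytest.raises(ValueError, match="mismatch"):
            compute_scores(model, DataBlocks(X=rng.normal(size=(5, 3)),
                                             Y=rng.normal(size=(5, 5))))


class TestLoadings:
    def test_score_equal_to_feature_gives_unit_loading(self, rng):
        X = rng.normal(size=(20, 4))
        Y = rng.normal(size=(20, 3))
        scores = ScoreSet(fc_scores=X[:, [0]], mood_scores=Y[:, [1]])
        loads = compute_loadings(DataBlocks(X=X, Y=Y), scores)
        assert loads.fc_loadings[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert loads.mood_loadings[1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_feature_has_zero_loading(self):
        n = 40
        score = np.tile([1.0, -1.0], n // 2)
        feat = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal by construction
        X = np.column_stack([feat, score])
        scores = ScoreSet(fc_scores=score[:, None], mood_scores=score[:, None])
        loads = compute_loadings(DataBlocks(X=X, Y=X.copy()), scores)
        assert loads.fc_loadings[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_recorded_as_nan_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 2.0
        scores = ScoreSet(fc_scores=rng.normal(size=(20, 1)),
                          mood_scores=rng.normal(size=(20, 1)))
        with pytest.warns(UserWarning, match="constant"):
            loads = compute_loadings(DataBlocks(X=X, Y=rng.normal(size=(20, 2))),
                                     scores)
        assert np.isnan(loads.fc_loadings[1, 0])
        assert np.all(np.abs(loads.fc_loadings[[0, 2], 0]) <= 1.0)

    def test_planted_pattern_recovered_in_loadings(self, planted_cohort, planted_model):
        blocks, _, truth = planted_cohort
        lc1 = planted_model.fc_loadings[:, 0]
        u = truth["true_fc_salience"]
        r = stats.pearsonr(np.sign(np.sum(lc1 * u)) * lc1, u).statistic
        assert r > 0.9


def test_symptom_item_layout():
    assert len(SYMPTOM_ITEMS) == 37
    assert sum(name.startswith("PA_") for name in SYMPTOM_ITEMS) == 10
    assert sum(name.startswith("NA_") for name in SYMPTOM_ITEMS) == 10
    assert sum(name.startswith("HRSD_") for name in SYMPTOM_ITEMS) == 17
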