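import numpy as np
import pytest

from nirscpm.errors import ConfigurationError, InputError
from nirscpm.prediction import (
    CVConfig,
    cv_mse_fixed_alpha,
    default_alpha_grid,
    fit_predict_cv,
    fold_sensitivity,
    loocv_mse_grid,
    ridge_fit,
    select_alpha_nested,
    stratified_folds,
)


def _closed_form(X, y, alpha):
    """Independent oracle: centered normal equations (X'X + aI) w = X'y."""
    xm, ym = X.mean(axis=0), y.mean()
    Xc = X - xm
    w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ (y - ym))
    return w, ym - xm @ w


class TestRidgeFit:
    def test_matches_closed_form_on_small_instance(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        w, b = ridge_fit(X, y, 0.7)
        w0, b0 = _closed_form(X, y, 0.7)
        assert np.allclose(w, w0, atol=1e-10)
        assert b == pytest.approx(b0, abs=1e-10)

    def test_primal_and_dual_paths_agree(self, rng):
        X = rng.normal(size=(6, 40))  # p > n triggers the dual path
        y = rng.normal(size=6)
        w, b = ridge_fit(X, y, 0.3)
        w0, b0 = _closed_form(X, y, 0.3)
        assert np.allclose(w, w0, atol=1e-9)
        assert b == pytest.approx(b0, abs=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.linear_model import Ridge

        X = rng.normal(size=(30, 50))
        y = rng.normal(size=30)
        w, b = ridge_fit(X, y, 2.5)
        sk = Ridge(alpha=2.5).fit(X, y)
        assert np.allclose(w, sk.coef_, atol=1e-8)
        assert b == pytest.approx(sk.intercept_, abs=1e-8)

    def test_infinite_regularization_limit(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        w_big, b_big = ridge_fit(X, y, 1e9)
        w_small, _ = ridge_fit(X, y, 0.01)
        assert np.linalg.norm(w_big) < 1e-6 * np.linalg.norm(w_small)
        assert X @ w_big + b_big == pytest.approx(np.full(20, y.mean()), abs=1e-5)

    def test_duplicated_columns_share_weight(self, rng):
        x = rng.normal(size=(15, 1))
        X = np.hstack([x, x, rng.normal(size=(15, 1))])
        y = rng.normal(size=15)
        w, _ = ridge_fit(X, y, 1.0)
        assert w[0] == pytest.approx(w[1], rel=1e-8)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InputError):
            ridge_fit(np.array([[np.inf, 0.0]]), np.array([1.0]), 1.0)
        with pytest.raises(InputError):
            ridge_fit(np.zeros((3, 2)), np.zeros(3), -1.0)


class TestStratifiedFolds:
    def test_96_participants_in_8_folds_of_12(self, rng):
        folds = stratified_folds(rng.normal(size=96), 8, seed=0)
        assert np.array_equal(np.bincount(folds), np.full(8, 12))

    def test_n_equals_k_gives_singleton_folds(self, rng):
        folds = stratified_folds(rng.normal(size=7), 7, seed=0)
        assert sorted(folds) == list(range(7))

    def test_every_fold_spans_the_score_distribution(self, rng):
        scores = rng.normal(50, 10, 96)
        folds = stratified_folds(scores, 8, seed=3)
        lo, hi = np.percentile(scores, [15, 85])
        for f in range(8):
            assert scores[folds == f].min() < lo
            assert scores[folds == f].max() > hi

    def test_stratification_balances_fold_means_vs_random(self, rng):
        scores = rng.normal(50, 10, 96)
        strat, rand = [], []
        for seed in range(50):
            f = stratified_folds(scores, 8, seed=seed)
            strat.append(np.std([scores[f == k].mean() for k in range(8)]))
            g = np.random.default_rng(seed).permutation(np.repeat(np.arange(8), 12))
            rand.append(np.std([scores[g == k].mean() for k in range(8)]))
        assert np.mean(strat) < np.mean(rand)

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(InputError):
            stratified_folds(np.arange(3.0), 5)


class TestAlphaSelection:
    def test_default_grid_has_1000_candidates_spanning_001_to_10(self):
        grid = default_alpha_grid()
        assert grid.size == 1000
        assert grid[0] == pytest.approx(0.01)
        assert grid[-1] == pytest.approx(10.0)

    def test_loocv_grid_matches_brute_force_refits(self, rng):
        """The SVD hat-matrix shortcut equals explicitly refitting n models."""
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        alphas = np.array([0.1, 1.0, 5.0])
        fast = loocv_mse_grid(X, y, alphas, standardize=False)
        brute = []
        for a in alphas:
            errs = []
            for i in range(12):
                keep = np.arange(12) != i
                w, b = ridge_fit(X[keep], y[keep], a)
                errs.append((y[i] - (X[i] @ w + b)) ** 2)
            brute.append(np.mean(errs))
        assert np.allclose(fast, brute, rtol=1e-8)

    def test_flat_objective_returns_smallest_alpha(self):
        # with no informative features every alpha has the same LOOCV error
        X = np.zeros((10, 3))
        y = np.arange(10.0)
        assert select_alpha_nested(X, y, np.array([0.5, 1.0, 2.0])) == 0.5

    def test_pure_noise_pushes_selection_toward_grid_maximum(self):
        grid = default_alpha_grid()
        picks = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            picks.append(select_alpha_nested(r.normal(size=(40, 30)), r.normal(size=40), grid))
        assert np.median(picks) >= grid[int(0.9 * grid.size)]


class TestFitPredictCV:
    def _signal_cohort(self, rng, n=48, p=60, k_true=4, noise=0.2):
        X = rng.normal(size=(n, p))
        w = np.zeros(p)
        w[:k_true] = [1.5, -1.2, 1.0, 0.8]
        y = X @ w + noise * rng.normal(size=n)
        return X, y

    def test_out_of_fold_predictions_cover_everyone_once(self, rng):
        X, y = self._signal_cohort(rng)
        res = fit_predict_cv(X, y, CVConfig(n_folds=8))
        assert res.predictions.shape == (48,)
        assert res.fold_alphas.shape == (8,)
        assert res.alpha_star == pytest.approx(res.fold_alphas.mean())
        assert res.mse == pytest.approx(np.mean((y - res.predictions) ** 2))

    def test_strong_signal_is_predicted(self, rng):
        X, y = self._signal_cohort(rng, p=30, noise=0.1)
        res = fit_predict_cv(X, y, CVConfig(n_folds=6))
        assert res.r > 0.8

    def test_test_fold_rows_cannot_leak_into_fold_training(self, rng):
        """At a fixed penalty, poisoning a held-out participant's features
        leaves that fold's trained weights untouched (the fold model never
        sees its own test rows). Alpha selection is exercised separately:
        the averaged alpha* couples folds by design."""
        from nirscpm.prediction import _fit_fold

        X, y = self._signal_cohort(rng)
        folds = stratified_folds(y, 6, seed=1)
        te = folds == 0
        w1, b1, _ = _fit_fold(X[~te], y[~te], X[te], 1.0, False)
        X2 = X.copy()
        X2[np.flatnonzero(te)[0]] = 1e3  # poison one held-out row
        w2, b2, _ = _fit_fold(X2[~te], y[~te], X2[te], 1.0, False)
        assert np.array_equal(w1, w2)
        assert b1 == b2

    def test_label_shuffling_kills_the_correlation(self, rng):
        X, y = self._signal_cohort(rng, n=60, p=40)
        rs = []
        for _ in range(50):
            rs.append(fit_predict_cv(X, rng.permutation(y), CVConfig(n_folds=6)).r)
        assert abs(np.mean(rs)) < 2 / np.sqrt(60)

    def test_constant_target_rejected(self, rng):
        with pytest.raises(InputError):
            fit_predict_cv(rng.normal(size=(20, 4)), np.ones(20), CVConfig(n_folds=4))

    def test_invalid_fold_count_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            fit_predict_cv(rng.normal(size=(6, 4)), rng.normal(size=6), CVConfig(n_folds=10))

    def test_planted_features_receive_larger_weights(self, rng):
        """Across replicate cohorts, truly informative features get larger
        mean absolute weight than null features (rank-sum)."""
        from scipy.stats import mannwhitneyu

        informative, null = [], []
        for _ in range(10):
            X, y = self._signal_cohort(rng)
            res = fit_predict_cv(X, y, CVConfig(n_folds=6))
            mean_abs = np.abs(res.weights).mean(axis=0)
            informative.extend(mean_abs[:4])
            null.extend(mean_abs[4:])
        assert mannwhitneyu(informative, null, alternative="greater").pvalue < 1e-6


class TestFoldSensitivity:
    def test_one_row_per_fold_count_and_loo_limit(self, rng):
        X, y = rng.normal(size=(16, 8)), rng.normal(size=16)
        tab = fold_sensitivity(X, y, CVConfig(), fold_counts=(4, 8, 16))
        assert list(tab["n_folds"]) == [4, 8, 16]
        # k = N is leave-one-out: every fold holds exactly one participant
        folds = stratified_folds(y, 16, 0)
        assert np.bincount(folds).max() == 1

    def test_cv_mse_fixed_alpha_matches_manual(self, rng):
        X, y = rng.normal(size=(12, 6)), rng.normal(size=12)
        folds = stratified_folds(y, 3, 0)
        got = cv_mse_fixed_alpha(X, y, folds, 1.0, standardize=False)
        preds = np.empty(12)
        for f in range(3):
            te = folds == f
            w, b = ridge_fit(X[~te], y[~te], 1.0)
            preds[te] = X[te] @ w + b
        assert got == pytest.approx(np.mean((y - preds) ** 2), rel=1e-10)
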