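import numpy as np
import pytest

from nirscpm.errors import InputError
from nirscpm.inference import (
    bootstrap_edges,
    permutation_test,
    residual_specificity,
)
from nirscpm.prediction import CVConfig, fit_predict_cv


class TestPermutationTest:
    def test_constant_scores_give_p_of_one(self, rng):
        X = rng.normal(size=(16, 10))
        y = np.full(16, 42.0)
        res = permutation_test(X, y, 1.0, n_permutations=25, cfg=CVConfig(n_folds=4))
        assert res.p_value == 1.0
        assert np.allclose(res.permuted_mse, res.real_mse)

    def test_strong_signal_is_significant(self, rng):
        X = rng.normal(size=(40, 30))
        y = X[:, 0] * 3 + 0.1 * rng.normal(size=40)
        res = permutation_test(X, y, 0.5, n_permutations=200, cfg=CVConfig(n_folds=4), seed=1)
        assert res.p_value < 0.01
        assert res.real_mse < res.permuted_mean

    def test_add_one_convention(self, rng):
        X = rng.normal(size=(16, 5))
        y = np.full(16, 7.0)
        res = permutation_test(
            X, y, 1.0, n_permutations=9, cfg=CVConfig(n_folds=4), add_one=True
        )
        assert res.p_value == pytest.approx(10 / 10)
        assert res.convention == "add_one"

    def test_summary_fields(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        res = permutation_test(X, y, 1.0, n_permutations=20, cfg=CVConfig(n_folds=3))
        s = res.summary()
        assert 0 <= s["p_value"] <= 1
        assert s["n_permutations"] == 20
        assert res.permuted_mse.shape == (20,)


class TestBootstrapEdges:
    def test_feature_equal_to_target_is_flagged_positive(self, rng):
        n, n_channels = 60, 8  # 28 edges
        X = rng.normal(size=(n, 28)) * 0.2
        y = rng.normal(size=n)
        X[:, 5] = y
        res = bootstrap_edges(X, y, 0.5, n_channels, n_bootstrap=500, seed=0)
        row = res.table.iloc[5]
        assert bool(row.significant)
        assert row.sign == "positive"
        assert row.ci_low > 0

    def test_null_false_positive_rate_near_one_percent_classical_regime(self, rng):
        """With ample samples per feature the 99% percentile CI excludes zero
        for about 1% of pure-noise edges."""
        flagged = total = 0
        for rep in range(3):
            X = rng.normal(size=(300, 45)) * 0.16
            y = rng.normal(45, 9, 300)
            res = bootstrap_edges(X, y, 1.0, 10, n_bootstrap=400, seed=rep)
            flagged += int(res.table.significant.sum())
            total += 45
        assert flagged <= 6  # Bin(135, 0.01): P(X > 6) < 1e-3

    def test_column_permutation_permutes_rows_identically(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        perm = rng.permutation(10)
        a = bootstrap_edges(X, y, 1.0, 5, n_bootstrap=100, seed=3)
        b = bootstrap_edges(X[:, perm], y, 1.0, 5, n_bootstrap=100, seed=3)
        for col in ("weight", "ci_low", "ci_high"):
            assert np.allclose(a.table[col].to_numpy()[perm], b.table[col].to_numpy())

    def test_degenerate_resamples_are_redrawn(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array([1.0, 1.0, 1.0, 1.0, 2.0])
        res = bootstrap_edges(X, y, 1.0, 3, n_bootstrap=60, seed=0)
        assert res.n_redrawn > 0
        assert res.table.shape[0] == 3

    def test_significant_flag_consistent_with_ci(self, rng):
        X = rng.normal(size=(40, 15))
        y = rng.normal(size=40)
        res = bootstrap_edges(X, y, 1.0, 6, n_bootstrap=200, seed=1)
        t = res.table
        assert (
            t.significant == ((t.ci_low > 0) | (t.ci_high < 0))
        ).all()
        assert ((t.ci_low <= t.weight) & (t.weight <= t.ci_high)).all()

    def test_bca_interval_agrees_with_percentile_on_strong_effect(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, 0] * 2 + 0.3 * rng.normal(size=40)
        pct = bootstrap_edges(X, y, 0.5, 5, n_bootstrap=300, seed=1)
        bca = bootstrap_edges(X, y, 0.5, 5, n_bootstrap=300, seed=1, ci_method="bca")
        # same resamples, so the bias/acceleration correction only nudges
        # the percentile bounds; the strong edge stays flagged either way
        assert bool(bca.table.iloc[0].significant)
        assert bca.table.iloc[0].ci_low == pytest.approx(
            pct.table.iloc[0].ci_low, abs=0.5
        )

    def test_stable_selection_across_seeds_on_strong_signal(self, rng):
        n = 80
        X = rng.normal(size=(n, 45)) * 0.2
        y = rng.normal(size=n)
        for j in range(5):
            X[:, j] = y * (1.5 - 0.2 * j) + 0.3 * rng.normal(size=n)
        sets = []
        for seed in (0, 1):
            res = bootstrap_edges(X, y, 0.5, 10, n_bootstrap=1000, seed=seed)
            sets.append(set(res.table.loc[res.table.significant, "edge_id"]))
        jaccard = len(sets[0] & sets[1]) / max(1, len(sets[0] | sets[1]))
        assert jaccard > 0.8


class TestResidualSpecificity:
    def test_independent_trait_leaves_state_model_unchanged(self, rng):
        n = 60
        X = rng.normal(size=(n, 40))
        state = X[:, 0] * 2 + 0.5 * rng.normal(size=n)
        trait = rng.normal(size=n)  # independent of everything
        cfg = CVConfig(n_folds=6)
        res_resid = residual_specificity(X, state, trait, cfg)
        res_state = fit_predict_cv(X, state, cfg)
        assert res_resid.r == pytest.approx(res_state.r, abs=0.15)
        assert res_resid.r > 0.5

    def test_state_identical_to_trait_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        s = rng.normal(size=20)
        with pytest.raises(InputError):
            residual_specificity(X, s, s)

    def test_zero_trait_variance_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(InputError):
            residual_specificity(X, rng.normal(size=20), np.ones(20))
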