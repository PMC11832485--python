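"""Feature-selection cascade: Fisher scores, SVM-SMOTE, ensemble lasso
stability scores, forward search, and the PLS reduction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdfuse.qc import standardize_features
from pdfuse.selection import (
    EnLasso,
    EnLassoConfig,
    HybridSelector,
    PlsReducer,
    SubsetSelection,
    enlasso_scores,
    fisher_filter,
    fisher_scores,
    forward_search_select,
    score_table_from_selections,
    svm_smote_balance,
)


class TestFisherScores:
    def test_hand_computed_value(self):
        # equal class sizes, class means 0 and 1, within-class variances 1
        rng = np.random.default_rng(0)
        n = 50000
        x = np.concatenate(
            [rng.standard_normal(n), rng.standard_normal(n) + 1]
        )
        y = np.concatenate([np.zeros(n), np.ones(n)])
        score = fisher_scores(x[:, None], y).iloc[0]
        assert score == pytest.approx(0.25, abs=0.01)

    def test_exact_on_discrete_case(self):
        # classes {0,2} vs {4,6}: overall mean 3, class means 1 and 5,
        # class variances 1 each -> (2*4 + 2*4) / (2*1 + 2*1) = 4
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array([0, 0, 1, 1])
        assert fisher_scores(X, y).iloc[0] == pytest.approx(4.0)

    def test_identical_class_means_score_zero(self):
        X = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        y = np.array([0, 0, 1, 1])
        assert fisher_scores(X, y).iloc[0] == pytest.approx(0.0)

    def test_duplicated_column_scores_equal(self, rng):
        X = rng.standard_normal((40, 3))
        X = np.column_stack([X, X[:, 0]])
        y = (rng.random(40) > 0.5).astype(int)
        scores = fisher_scores(X, y)
        assert scores.iloc[0] == pytest.approx(scores.iloc[3])

    def test_zero_variance_feature_scores_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.array([0] * 5 + [1] * 5)
        assert fisher_scores(X, y).iloc[0] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fisher_scores(np.ones((5, 2)), np.ones(5))


class TestFisherFilter:
    def test_keep_all_is_identity(self):
        scores = pd.Series([3.0, 1.0, 2.0], index=["a", "b", "c"])
        assert set(fisher_filter(scores, 3)) == {"a", "b", "c"}

    def test_keep_one_is_argmax(self):
        scores = pd.Series([3.0, 1.0, 2.0], index=["a", "b", "c"])
        assert fisher_filter(scores, 1) == ["a"]

    def test_ties_break_lexicographically(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=["c", "a", "b"])
        assert fisher_filter(scores, 2) == ["a", "b"]

    def test_invalid_keep_rejected(self):
        scores = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            fisher_filter(scores, 0)
        with pytest.raises(ValueError):
            fisher_filter(scores, 2)


class TestSvmSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([0] * 10 + [1] * 10)
        X2, y2 = svm_smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_counts_and_originals_preserved(self, rng):
        X = rng.standard_normal((14, 4))
        y = np.array([0] * 10 + [1] * 4)
        X2, y2 = svm_smote_balance(X, y, seed=1)
        assert int((y2 == 0).sum()) == 10
        assert int((y2 == 1).sum()) == 10
        np.testing.assert_array_equal(X2[:14], X)
        np.testing.assert_array_equal(y2[:14], y)

    def test_synthetic_points_lie_between_minority_pairs(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array([0] * 22 + [1] * 8)
        X2, y2 = svm_smote_balance(X, y, seed=2)
        X_min = X[y == 1]
        for synth in X2[30:]:
            # on a segment between two minority points: coordinate-wise
            # bounded by the min/max of SOME minority pair
            ok = False
            for i in range(len(X_min)):
                for j in range(len(X_min)):
                    lo = np.minimum(X_min[i], X_min[j]) - 1e-12
                    hi = np.maximum(X_min[i], X_min[j]) + 1e-12
                    if np.all(synth >= lo) and np.all(synth <= hi):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((18, 3))
        y = np.array([0] * 12 + [1] * 6)
        a = svm_smote_balance(X, y, seed=5)
        b = svm_smote_balance(X, y, seed=5)
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_minority_falls_back_to_duplication(self, rng):
        X = rng.standard_normal((6, 2))
        y = np.array([0, 0, 0, 0, 0, 1])
        X2, y2 = svm_smote_balance(X, y, seed=0)
        assert int((y2 == 1).sum()) == 5
        # duplicates of the single minority sample
        np.testing.assert_array_equal(
            X2[6:], np.tile(X[5], (4, 1))
        )


def naive_fsq_fsw(selections):
    """Brute-force enumeration oracle for FSq / FSw over stored subsets."""
    names = selections[0].weights.index
    M = len(selections)
    fsq, fsw = {}, {}
    for f in names:
        count = 0
        wsum = 0.0
        for s in selections:
            w = s.weights
            if w[f] != 0:
                count += 1
            mx = w.abs().max()
            wsum += (abs(w[f]) / mx) if mx > 0 else 0.0
        fsq[f] = count / M
        fsw[f] = wsum / M
    return pd.Series(fsq), pd.Series(fsw)


class TestEnLassoScores:
    @pytest.fixture(scope="class")
    def fitted(self, small_cohort):
        cohort, truth, _ = small_cohort
        X = standardize_features(cohort.modalities["snp"])[0]
        kept = fisher_filter(fisher_scores(X, cohort.labels), 60)
        est = EnLasso(n_repeats=2, n_folds=5, seed=0)
        return est.fit(X[kept], cohort.labels), truth

    def test_vectorized_scores_match_enumeration_oracle(self, fitted):
        est, _ = fitted
        fsq, fsw = naive_fsq_fsw(est.selections_)
        table = est.score_table_
        pd.testing.assert_series_equal(
            table["FSq"].sort_index(), fsq.sort_index(),
            check_names=False, check_exact=True,
        )
        np.testing.assert_allclose(
            table["FSw"].sort_index(), fsw.sort_index(), atol=1e-15
        )

    def test_is_identity_and_bounds(self, fitted):
        est, _ = fitted
        table = est.score_table_
        np.testing.assert_array_equal(
            table["IS"].to_numpy(), ((table["FSq"] + table["FSw"]) / 2).to_numpy()
        )
        assert table[["FSq", "FSw", "IS"]].to_numpy().min() >= 0
        assert table[["FSq", "FSw", "IS"]].to_numpy().max() <= 1
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))

    def test_column_order_invariance(self, small_cohort):
        cohort, _, _ = small_cohort
        X = standardize_features(cohort.modalities["mri"])[0]
        config = EnLassoConfig(n_folds=5, n_repeats=1, seed=3)
        a = enlasso_scores(X, cohort.labels, config)
        b = enlasso_scores(
            X[list(reversed(X.columns))], cohort.labels, config
        )
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_never_selected_feature_scores_zero(self):
        sels = [
            SubsetSelection(pd.Series({"a": 0.5, "b": 0.0})),
            SubsetSelection(pd.Series({"a": 1.0, "b": 0.0})),
        ]
        table = score_table_from_selections(sels)
        assert table.loc["b", ["FSq", "FSw", "IS"]].tolist() == [0, 0, 0]
        assert table.loc["a", "FSq"] == 1.0

    def test_fsq_arithmetic(self):
        sels = [
            SubsetSelection(pd.Series({"a": 1.0 if i < 3 else 0.0}))
            for i in range(10)
        ]
        table = score_table_from_selections(sels)
        assert table.loc["a", "FSq"] == pytest.approx(0.3)

    def test_is_arithmetic(self):
        fsq, fsw = 0.8, 0.4
        assert (fsq + fsw) / 2 == pytest.approx(0.6)


class TestForwardSearch:
    def _table(self, names):
        is_vals = pd.Series(
            np.linspace(1, 0.1, len(names)), index=names, name="IS"
        )
        table = is_vals.to_frame()
        table["rank"] = np.arange(1, len(names) + 1)
        return table

    def test_full_grid_returns_all_features(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 5)),
                         columns=list("abcde"))
        y = (rng.random(40) > 0.5).astype(int)
        table = self._table(list("abcde"))
        selected = forward_search_select(
            table, X.iloc[:30], y[:30], X.iloc[30:], y[30:], k_grid=(5,)
        )
        assert selected == list("abcde")

    def test_ties_return_smallest_k(self, rng):
        # pure-noise features: validation Bacc is flat, so smallest k wins
        X = pd.DataFrame(np.zeros((40, 5)), columns=list("abcde"))
        y = np.array([0, 1] * 20)
        table = self._table(list("abcde"))
        selected = forward_search_select(
            table, X.iloc[:30], y[:30], X.iloc[30:], y[30:],
            k_grid=(1, 2, 3, 4, 5),
        )
        assert len(selected) == 1

    def test_planted_signal_enriched_beyond_chance(self, small_cohort):
        cohort, truth, _ = small_cohort
        y = cohort.labels
        X = standardize_features(cohort.modalities["snp"])[0]
        scores = fisher_scores(X, y)
        kept = fisher_filter(scores, 60)
        table = enlasso_scores(
            X[kept], y, EnLassoConfig(n_folds=5, n_repeats=2, seed=1)
        )
        rng = np.random.default_rng(0)
        tr = rng.permutation(len(y))
        train, val = tr[:130], tr[130:]
        selected = forward_search_select(
            table, X[kept].iloc[train], y[train],
            X[kept].iloc[val], y[val], k_grid=(5, 10, 20, 40),
        )
        overlap = len(set(selected) & truth.causal_snp_names)
        # hypergeometric tail: overlap among |selected| draws from 400
        # features of which 10 are causal
        p = stats.hypergeom.sf(
            overlap - 1, 400, len(truth.causal_snp_names), len(selected)
        )
        assert p < 0.01

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            forward_search_select(None, None, None, None, None, k_grid=())


class TestPlsReducer:
    def test_perfect_predictor_first_component(self, rng):
        n = 60
        y = (rng.random(n) > 0.5).astype(float)
        yc = y - y.mean()
        noise = rng.standard_normal((n, 4))
        # noise orthogonal to the label so the first weight vector is e1
        noise -= np.outer(yc, yc @ noise) / (yc @ yc)
        X = np.column_stack([yc, noise])
        reducer = PlsReducer(n_components=1).fit(X, y)
        r = np.corrcoef(reducer.training_scores_[:, 0], y)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8

    def test_zero_components_rejected(self, rng):
        with pytest.raises(ValueError):
            PlsReducer(n_components=0).fit(
                rng.standard_normal((10, 3)), rng.random(10)
            )

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            PlsReducer(n_components=5).fit(
                rng.standard_normal((4, 3)), rng.random(4)
            )

    def test_transform_reproduces_training_scores(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.random(30)
        reducer = PlsReducer(n_components=3).fit(X, y)
        np.testing.assert_allclose(
            reducer.transform(X), reducer.training_scores_, atol=1e-10
        )


class TestHybridSelector:
    def test_ensglasso_smoke_on_bimodal_cohort(self, small_cohort):
        cohort, _, _ = small_cohort
        y = cohort.labels
        X = pd.concat(
            [
                standardize_features(cohort.modalities["snp"])[0],
                standardize_features(cohort.modalities["mri"])[0],
            ],
            axis=1,
        )
        groups = {
            f: m
            for m in ("snp", "mri")
            for f in cohort.modalities[m].columns
        }
        selector = HybridSelector(
            mode="ensglasso", fisher_keep=40, n_repeats=1, n_folds=5,
            k_grid=(5, 10), max_pls_components=3, seed=0,
        )
        selector.fit(X, y, groups=groups)
        assert len(selector.selected_features_) >= 1
        scores = selector.transform(X)
        assert scores.shape == (len(y), selector.n_components_)

    def test_selection_ignores_validation_labels(self, small_cohort):
        # leakage contract: the IS table is fitted on train only, so
        # shuffling validation labels must leave it unchanged
        cohort, _, _ = small_cohort
        y = cohort.labels.copy()
        X = standardize_features(cohort.modalities["mri"])[0]
        idx = np.arange(len(y))
        train, val = idx[:130], idx[130:]
        kwargs = dict(
            mode="enlasso", fisher_keep=20, n_repeats=1, n_folds=5,
            k_grid=(5, 10), max_pls_components=3, seed=0,
        )
        a = HybridSelector(**kwargs).fit(
            X.iloc[train], y[train], X_val=X.iloc[val], y_val=y[val]
        )
        y_shuf = y.copy()
        y_shuf[val] = np.random.default_rng(1).permutation(y[val])
        b = HybridSelector(**kwargs).fit(
            X.iloc[train], y[train], X_val=X.iloc[val], y_val=y_shuf[val]
        )
        pd.testing.assert_frame_equal(a.score_table_, b.score_table_)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            HybridSelector(mode="pca").fit(
                pd.DataFrame(rng.standard_normal((20, 4))),
                np.array([0, 1] * 10),
            )
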