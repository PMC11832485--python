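"""Adaptive stacking: selection rule, performance weights, out-of-fold
training without leakage, and test-time aggregation."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from pdfuse.stacking import (
    AdaptiveStackingClassifier,
    BaseLearnerReport,
    BaseLearnerSpec,
    adaptive_select,
    balanced_accuracy_counts,
    fit_stacking,
    learner_weights,
    make_classifier_registry,
    oof_train,
    predict_stacking,
)


def make_report(name, baccs, oof=None):
    return BaseLearnerReport(
        spec=BaseLearnerSpec(name, "all", LogisticRegression()),
        fold_baccs=np.asarray(baccs, float),
        oof_proba=np.zeros(4) if oof is None else np.asarray(oof),
    )


@pytest.fixture()
def toy_xy(rng):
    n = 80
    X = rng.standard_normal((n, 4))
    y = (X[:, 0] + 0.5 * rng.standard_normal(n) > 0).astype(int)
    return X, y


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((9, 1, 8, 2), 0.85),
            ((5, 5, 5, 5), 0.5),
            ((10, 0, 7, 0), 1.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert balanced_accuracy_counts(*counts) == pytest.approx(expected)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy_counts(0, 0, 5, 5)


class TestAdaptiveSelect:
    def test_strict_grand_mean_rule(self):
        reports = [
            make_report("a", [0.9]),
            make_report("b", [0.8]),
            make_report("c", [0.7]),
        ]
        selected = adaptive_select(reports)
        # grand mean 0.8; only 0.9 strictly exceeds it
        assert [r.spec.name for r in selected] == ["a"]
        assert reports[0].selected and not reports[1].selected

    def test_all_equal_falls_back_to_single(self):
        reports = [make_report(n, [0.8]) for n in "abc"]
        selected = adaptive_select(reports)
        assert len(selected) == 1
        assert selected[0].spec.name == "a"  # first in spec order on ties

    def test_single_report_selected_via_fallback(self):
        reports = [make_report("only", [0.6])]
        assert adaptive_select(reports) == reports

    def test_selects_between_one_and_n_minus_one_when_unequal(self, rng):
        for _ in range(20):
            means = rng.uniform(0.4, 1.0, size=6)
            reports = [make_report(str(i), [m]) for i, m in enumerate(means)]
            selected = adaptive_select(reports)
            if not np.allclose(means, means[0]):
                assert 1 <= len(selected) <= 5


class TestLearnerWeights:
    def test_mu_half_single_learner(self):
        lam = learner_weights([make_report("a", [0.5])])
        assert lam[0] == pytest.approx(1 / 3)

    def test_mu_09_two_learners(self):
        reports = [make_report("a", [0.9]), make_report("b", [0.9])]
        lam = learner_weights(reports)
        np.testing.assert_allclose(lam, 0.5 / (1 / 0.81 - 1), rtol=1e-6)

    def test_strictly_increasing_in_mu(self):
        mus = np.linspace(0.501, 0.999, 60)
        lams = [
            learner_weights([make_report("a", [mu])])[0] for mu in mus
        ]
        assert np.all(np.diff(lams) > 0)
        assert np.all(np.asarray(lams) > 0)

    def test_perfect_learner_clipped_not_singular(self):
        lam = learner_weights([make_report("a", [1.0])])
        assert np.isfinite(lam[0]) and lam[0] > 0

    def test_literal_index_reading_gives_equal_weights(self):
        reports = [make_report("a", [0.9]), make_report("b", [0.6])]
        lam = learner_weights(reports, literal_mu=True)
        assert lam[0] == pytest.approx(lam[1])


class TestOofTrain:
    def test_every_sample_predicted_exactly_once(self, toy_xy):
        X, y = toy_xy
        specs = [BaseLearnerSpec("lr", "all", LogisticRegression())]
        reports, folds = oof_train(X, y, specs, K=5, seed=0)
        assert not np.isnan(reports[0].oof_proba).any()
        covered = np.concatenate([te for _, te in folds])
        assert sorted(covered) == list(range(len(y)))

    def test_deterministic_given_seed(self, toy_xy):
        X, y = toy_xy
        specs = [BaseLearnerSpec("lr", "all", LogisticRegression())]
        a, _ = oof_train(X, y, specs, K=5, seed=3)
        b, _ = oof_train(X, y, specs, K=5, seed=3)
        np.testing.assert_array_equal(a[0].oof_proba, b[0].oof_proba)
        np.testing.assert_array_equal(a[0].fold_baccs, b[0].fold_baccs)

    def test_constant_classifier_scores_chance(self, toy_xy):
        X, y = toy_xy

        class Constant(LogisticRegression):
            def predict_proba(self, X):
                return np.column_stack(
                    [np.zeros(len(X)), np.ones(len(X))]
                )

        specs = [BaseLearnerSpec("const", "all", Constant())]
        reports, _ = oof_train(X, y, specs, K=5, seed=0)
        np.testing.assert_allclose(reports[0].fold_baccs, 0.5)

    def test_oof_column_matches_naive_recomputation(self, toy_xy):
        # leakage oracle: recompute one learner's OOF column fold by fold
        X, y = toy_xy
        est = DecisionTreeClassifier(random_state=0)
        specs = [BaseLearnerSpec("tree", "all", est)]
        reports, folds = oof_train(X, y, specs, K=5, seed=7)
        naive = np.full(len(y), np.nan)
        for train_idx, test_idx in folds:
            m = clone(est).fit(X[train_idx], y[train_idx])
            naive[test_idx] = m.predict_proba(X[test_idx])[:, 1]
        np.testing.assert_array_equal(reports[0].oof_proba, naive)

    def test_missing_modality_rejected(self, toy_xy):
        X, y = toy_xy
        specs = [BaseLearnerSpec("lr", "absent", LogisticRegression())]
        with pytest.raises(KeyError):
            oof_train({"all": X}, y, specs, K=5, seed=0)


class TestStackingModel:
    def test_meta_feature_dimension_equals_selection(self, toy_xy):
        X, y = toy_xy
        registry = make_classifier_registry(seed=0, names=("lr", "rf"))
        specs = [
            BaseLearnerSpec(n, "all", est) for n, est in registry.items()
        ]
        model = fit_stacking(X, y, specs, K=5, seed=0)
        assert model.meta_features_train().shape == (
            len(y), len(model.selected)
        )
        assert len(model.selected) >= 1

    def test_separable_oof_gives_perfect_training_bacc(self):
        y = np.array([0] * 20 + [1] * 20)
        report = make_report("sep", [1.0] * 5, oof=y.astype(float))
        report.selected = True
        learner_weights([report])
        from sklearn.linear_model import LogisticRegression as LR

        meta = LR(C=1.0, max_iter=1000)
        meta.fit((report.weight * report.oof_proba)[:, None], y)
        pred = meta.predict((report.weight * report.oof_proba)[:, None])
        assert balanced_accuracy_counts(
            int(((pred == 1) & (y == 1)).sum()),
            int(((pred == 0) & (y == 1)).sum()),
            int(((pred == 0) & (y == 0)).sum()),
            int(((pred == 1) & (y == 0)).sum()),
        ) == 1.0

    def test_same_seed_identical_model(self, toy_xy):
        X, y = toy_xy
        clf_a = AdaptiveStackingClassifier(
            classifier_names=("lr", "rf"), K=5, seed=9
        ).fit(X, y)
        clf_b = AdaptiveStackingClassifier(
            classifier_names=("lr", "rf"), K=5, seed=9
        ).fit(X, y)
        np.testing.assert_array_equal(
            clf_a.predict_proba(X), clf_b.predict_proba(X)
        )
        assert clf_a.selected_keys_ == clf_b.selected_keys_


class TestPredictStacking:
    def test_agreeing_fold_models_reproduce_common_probability(self, toy_xy):
        X, y = toy_xy
        model = fit_stacking(
            X, y,
            [BaseLearnerSpec("lr", "all", LogisticRegression())],
            K=5, seed=0,
        )
        r = model.selected[0]

        class Fixed:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack(
                    [1 - np.full(len(X), self.p), np.full(len(X), self.p)]
                )

        r.fold_models = [Fixed(0.7)] * model.K
        Xt = X[:10]
        preds = np.stack(
            [m.predict_proba(Xt)[:, 1] for m in r.fold_models]
        )
        w = r.fold_baccs / r.fold_baccs.sum()
        np.testing.assert_allclose(w @ preds, 0.7)

    def test_probabilities_within_unit_interval(self, toy_xy):
        X, y = toy_xy
        clf = AdaptiveStackingClassifier(
            classifier_names=("lr", "svm"), K=5, seed=0
        ).fit({"a": X}, y)
        p = clf.predict_proba({"a": X})
        assert np.all(p >= 0) and np.all(p <= 1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_missing_test_modality_rejected(self, toy_xy):
        X, y = toy_xy
        clf = AdaptiveStackingClassifier(
            classifier_names=("lr",), K=5, seed=0
        ).fit({"a": X}, y)
        with pytest.raises(KeyError):
            clf.predict_proba({"b": X})

    def test_single_learner_predictions_monotone_in_q(self, toy_xy):
        # with one selected learner the meta-model is a monotone map of q
        X, y = toy_xy
        model = fit_stacking(
            X, y,
            [BaseLearnerSpec("lr", "all", LogisticRegression())],
            K=5, seed=0,
        )
        p = predict_stacking(model, X)
        r = model.selected[0]
        preds = np.stack([m.predict_proba(X)[:, 1] for m in r.fold_models])
        q = (r.fold_baccs / r.fold_baccs.sum()) @ preds
        from scipy.stats import spearmanr

        rho = spearmanr(q, p).statistic
        assert rho == pytest.approx(1.0)


def test_stratification_failure_raises():
    X = np.random.default_rng(0).standard_normal((8, 2))
    y = np.array([0] * 7 + [1])
    specs = [BaseLearnerSpec("lr", "all", LogisticRegression())]
    with pytest.raises(ValueError):
        oof_train(X, y, specs, K=5, seed=0)
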