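"""Adaptive-selection-enhanced stacking for decision-level fusion.

A two-layer ensemble over a pool of N candidate (classifier, modality)
base learners:

1. Each candidate is trained out-of-fold under stratified K-fold
   cross-validation, yielding leakage-free out-of-fold class
   probabilities and per-fold balanced accuracies.
2. Candidates whose mean fold balanced accuracy strictly exceeds the
   grand mean over all candidates are selected (with a single-best
   fallback when none do).
3. Each selected learner i receives a weight
   lambda_i = -(1/M) * 1 / (1 - 1/mu_i^2), a positive, strictly
   increasing function of its mean balanced accuracy mu_i on (0, 1),
   so stronger learners dominate the meta-features.
4. A logistic-regression meta-learner (class-balanced, so the 0.5
   decision threshold stays calibrated under case/control imbalance) is
   fitted on the weighted out-of-fold probability columns; at test time
   each learner's K fold models predict, their outputs are combined by
   fold-accuracy-weighted averaging, scaled by lambda_i, and passed to
   the meta-learner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = (
    "lr", "svm", "mlp", "adaboost", "rf", "gbdt", "xgboost", "lightgbm",
)


def make_classifier_registry(
    seed: int = 0, names: tuple[str, ...] = CLASSIFIER_NAMES
) -> dict[str, BaseEstimator]:
    """Candidate base classifiers, all exposing ``predict_proba``."""
    registry: dict[str, BaseEstimator] = {}
    for name in names:
        if name == "lr":
            est = LogisticRegression(max_iter=1000)
        elif name == "svm":
            est = SVC(probability=True, random_state=seed)
        elif name == "mlp":
            est = MLPClassifier(
                hidden_layer_sizes=(32,), max_iter=500, random_state=seed
            )
        elif name == "adaboost":
            est = AdaBoostClassifier(random_state=seed)
        elif name == "rf":
            est = RandomForestClassifier(n_estimators=200, random_state=seed)
        elif name == "gbdt":
            est = GradientBoostingClassifier(random_state=seed)
        elif name == "xgboost":
            from xgboost import XGBClassifier

            est = XGBClassifier(
                n_estimators=100,
                eval_metric="logloss",
                verbosity=0,
                random_state=seed,
            )
        elif name == "lightgbm":
            from lightgbm import LGBMClassifier

            est = LGBMClassifier(verbose=-1, random_state=seed)
        else:
            raise ValueError(
                f"unknown classifier {name!r}; registry offers "
                f"{CLASSIFIER_NAMES}"
            )
        registry[name] = est
    return registry


def balanced_accuracy_counts(tp: int, fn: int, tn: int, fp: int) -> float:
    """Balanced accuracy from confusion counts: (Sen + Spe) / 2."""
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("each class must contribute at least one sample")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


@dataclass
class BaseLearnerSpec:
    """One candidate: a classifier applied to one modality's features."""

    name: str
    modality: str
    estimator: BaseEstimator

    @property
    def key(self) -> str:
        return f"{self.name}@{self.modality}"


@dataclass
class BaseLearnerReport:
    """Out-of-fold performance record of one candidate learner."""

    spec: BaseLearnerSpec
    fold_baccs: np.ndarray
    oof_proba: np.ndarray  # P(class 1) per training sample, out of fold
    fold_models: list = field(default_factory=list)
    mu: float | None = None
    selected: bool = False
    weight: float | None = None

    @property
    def mean_bacc(self) -> float:
        return float(np.mean(self.fold_baccs))


def _as_modality_dict(X) -> dict:
    if isinstance(X, dict):
        return dict(X)
    return {"all": X}


def _rows(Xm, idx=None):
    if hasattr(Xm, "iloc"):
        return Xm if idx is None else Xm.iloc[idx]
    Xm = np.asarray(Xm, float)
    return Xm if idx is None else Xm[idx]


class _FoldModel:
    """One fold's fitted (front end, classifier) pair."""

    def __init__(self, classifier, front_end=None):
        self.classifier = classifier
        self.front_end = front_end

    def predict_proba(self, X):
        if self.front_end is not None:
            X = self.front_end.transform(X)
        return self.classifier.predict_proba(np.asarray(X, float))


def oof_train(
    X,
    y,
    specs: list[BaseLearnerSpec],
    K: int = 5,
    seed: int = 0,
    front_ends: dict | None = None,
) -> tuple[list[BaseLearnerReport], list[np.ndarray]]:
    """Train every candidate out-of-fold on its modality's features.

    Returns the per-learner reports and the shared fold index pairs (so
    all learners see identical fold assignments).

    ``front_ends`` optionally maps a modality name to a factory
    ``f(fold_index) -> transformer`` (with ``fit(X, y)`` and
    ``transform``). The transformer is refitted on each fold's training
    part before the fold's classifiers, so supervised reductions (feature
    selection, PLS) do not leak held-out labels into the fold balanced
    accuracies used for learner selection.
    """
    modalities = _as_modality_dict(X)
    y = np.asarray(y)
    anchor = np.asarray(next(iter(modalities.values())), float)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    folds = list(skf.split(anchor, y))
    for _, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError(
                "a fold contains a single class; reduce K or rebalance"
            )

    # per-(modality, fold) transformed matrices, front ends fitted on the
    # fold's training part only
    fold_views: dict[tuple[str, int], tuple] = {}
    for m, Xm in modalities.items():
        for k, (train_idx, test_idx) in enumerate(folds):
            if front_ends and m in front_ends:
                fe = front_ends[m](k)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fe.fit(_rows(Xm, train_idx), y[train_idx])
                Z_tr = np.asarray(fe.transform(_rows(Xm, train_idx)), float)
                Z_te = np.asarray(fe.transform(_rows(Xm, test_idx)), float)
                fold_views[m, k] = (Z_tr, Z_te, fe)
            else:
                Xa = np.asarray(Xm, float)
                fold_views[m, k] = (Xa[train_idx], Xa[test_idx], None)

    reports = []
    for spec in specs:
        if spec.modality not in modalities:
            raise KeyError(
                f"modality {spec.modality!r} missing from training data"
            )
        oof = np.full(len(y), np.nan)
        fold_baccs = np.empty(K)
        fold_models = []
        for k, (train_idx, test_idx) in enumerate(folds):
            Z_tr, Z_te, fe = fold_views[spec.modality, k]
            model = clone(spec.estimator)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Z_tr, y[train_idx])
            proba = model.predict_proba(Z_te)[:, 1]
            oof[test_idx] = proba
            fold_baccs[k] = balanced_accuracy_score(
                y[test_idx], (proba >= 0.5).astype(int)
            )
            fold_models.append(_FoldModel(model, fe))
        reports.append(
            BaseLearnerReport(
                spec=spec,
                fold_baccs=fold_baccs,
                oof_proba=oof,
                fold_models=fold_models,
            )
        )
    return reports, folds


def adaptive_select(reports: list[BaseLearnerReport]) -> list[BaseLearnerReport]:
    """Keep learners whose mean fold Bacc strictly exceeds the grand mean.

    The grand mean averages every candidate's mean fold balanced
    accuracy. If no learner strictly exceeds it (e.g. all equal), the
    single best by mean is kept (ties broken by spec order).
    """
    if not reports:
        raise ValueError("at least one report required")
    means = np.array([r.mean_bacc for r in reports])
    grand = means.mean()
    selected = [r for r, m in zip(reports, means) if m > grand]
    if not selected:
        selected = [reports[int(np.argmax(means))]]
    for r in reports:
        r.selected = r in selected
    return selected


def learner_weights(
    selected: list[BaseLearnerReport],
    eps: float = 1e-3,
    literal_mu: bool = False,
) -> np.ndarray:
    """Performance weights lambda_i = -(1/M) / (1 - 1/mu_i^2).

    mu_i is the learner's mean fold balanced accuracy, clipped into
    [eps, 1 - eps] to avoid the singularity at mu = 1. With
    ``literal_mu`` every learner shares the pooled mean over selected
    learners (the printed index-pattern reading, which makes all weights
    identical).
    """
    M = len(selected)
    if M < 1:
        raise ValueError("at least one selected learner required")
    mus = np.array([r.mean_bacc for r in selected])
    if literal_mu:
        mus = np.full(M, mus.mean())
    mus = np.clip(mus, eps, 1 - eps)
    lams = -(1.0 / M) / (1.0 - 1.0 / mus**2)
    for r, mu, lam in zip(selected, mus, lams):
        r.mu = float(mu)
        r.weight = float(lam)
    return lams


@dataclass
class StackingModel:
    """Fitted two-layer ensemble: selected learners plus meta-learner."""

    reports: list[BaseLearnerReport]  # all candidates, selection flags set
    selected: list[BaseLearnerReport]
    weights: np.ndarray
    meta_learner: LogisticRegression
    K: int
    seed: int
    test_agg: str = "bacc"

    def meta_features_train(self) -> np.ndarray:
        return np.column_stack(
            [r.weight * r.oof_proba for r in self.selected]
        )


def fit_stacking(
    X,
    y,
    specs: list[BaseLearnerSpec],
    K: int = 5,
    seed: int = 0,
    eps: float = 1e-3,
    literal_mu: bool = False,
    meta_C: float = 1.0,
    test_agg: str = "bacc",
    front_ends: dict | None = None,
) -> StackingModel:
    """Compose out-of-fold training, adaptive selection and weighting."""
    reports, _ = oof_train(X, y, specs, K=K, seed=seed, front_ends=front_ends)
    selected = adaptive_select(reports)
    weights = learner_weights(selected, eps=eps, literal_mu=literal_mu)
    meta_X = np.column_stack([r.weight * r.oof_proba for r in selected])
    meta = LogisticRegression(C=meta_C, max_iter=1000, class_weight="balanced")
    meta.fit(meta_X, np.asarray(y))
    return StackingModel(
        reports=reports,
        selected=selected,
        weights=weights,
        meta_learner=meta,
        K=K,
        seed=seed,
        test_agg=test_agg,
    )


def predict_stacking(model: StackingModel, X) -> np.ndarray:
    """Class-1 probabilities for a test set.

    Per selected learner the K fold models each predict; their outputs
    are averaged with fold-Bacc-proportional weights (or a simple mean
    when ``test_agg == "mean"``), scaled by lambda_i, and fed to the
    meta-learner.
    """
    modalities = _as_modality_dict(X)
    columns = []
    for r in model.selected:
        if r.spec.modality not in modalities:
            raise KeyError(
                f"modality {r.spec.modality!r} missing from test data"
            )
        Xm = modalities[r.spec.modality]
        preds = np.stack(
            [np.asarray(m.predict_proba(Xm))[:, 1] for m in r.fold_models]
        )
        if model.test_agg == "mean":
            w = np.full(model.K, 1.0 / model.K)
        else:
            total = r.fold_baccs.sum()
            w = (
                r.fold_baccs / total
                if total > 0
                else np.full(model.K, 1.0 / model.K)
            )
        q = w @ preds
        columns.append(r.weight * q)
    meta_X = np.column_stack(columns)
    return model.meta_learner.predict_proba(meta_X)[:, 1]


class AdaptiveStackingClassifier(BaseEstimator, ClassifierMixin):
    """Estimator facade over the adaptive stacking ensemble.

    ``fit``/``predict_proba`` accept either a single feature matrix or a
    mapping of modality name to matrix (all row-aligned). When ``specs``
    is None a candidate pool is built at fit time from the classifier
    registry crossed with every modality present in the input.
    """

    def __init__(
        self,
        specs: list[BaseLearnerSpec] | None = None,
        classifier_names: tuple[str, ...] = CLASSIFIER_NAMES,
        K: int = 5,
        seed: int = 0,
        eps: float = 1e-3,
        literal_mu: bool = False,
        meta_C: float = 1.0,
        test_agg: str = "bacc",
        front_ends: dict | None = None,
    ):
        self.specs = specs
        self.classifier_names = classifier_names
        self.K = K
        self.seed = seed
        self.eps = eps
        self.literal_mu = literal_mu
        self.meta_C = meta_C
        self.test_agg = test_agg
        self.front_ends = front_ends

    def _build_specs(self, modalities: dict) -> list[BaseLearnerSpec]:
        if self.specs is not None:
            return self.specs
        registry = make_classifier_registry(
            seed=self.seed, names=tuple(self.classifier_names)
        )
        return [
            BaseLearnerSpec(name=n, modality=m, estimator=est)
            for m in modalities
            for n, est in registry.items()
        ]

    def fit(self, X, y):
        modalities = _as_modality_dict(X)
        self.classes_ = np.unique(np.asarray(y))
        self.specs_ = self._build_specs(modalities)
        self.model_ = fit_stacking(
            modalities,
            y,
            self.specs_,
            K=self.K,
            seed=self.seed,
            eps=self.eps,
            literal_mu=self.literal_mu,
            meta_C=self.meta_C,
            test_agg=self.test_agg,
            front_ends=self.front_ends,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        p1 = predict_stacking(self.model_, X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (predict_stacking(self.model_, X) >= 0.5).astype(int)

    @property
    def selected_keys_(self) -> list[str]:
        return [r.spec.key for r in self.model_.selected]
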