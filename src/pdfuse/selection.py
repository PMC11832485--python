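"""Hybrid stability feature selection for high-dimensional two-class data.

The cascade has three refinement stages:

1. A Fisher-score filter discards features with little marginal class
   separation.
2. An ensemble lasso (stability selection over perturbation subsets)
   scores each surviving feature by how often it is selected (FSq), its
   mean normalized weight (FSw), and their average, the importance score
   IS = (FSq + FSw) / 2; class imbalance inside each subset is optionally
   corrected with SVM-SMOTE oversampling.
3. A forward search over the descending-IS ranking picks the top-k that
   maximizes validation balanced accuracy, and partial least squares
   projects the survivors onto a few supervised components.

A sparse-group-lasso base learner can replace the plain lasso inside the
ensemble when features carry a group structure (e.g. one group per
modality), giving the group-aware variant used for feature-level fusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .sglasso import SparseGroupLasso

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher score filter


def fisher_scores(X, y) -> pd.Series:
    """Two-class Fisher criterion per feature.

    score_f = sum_c n_c (mu_cf - mu_f)^2 / sum_c n_c var_cf, with class
    sizes n_c, class means mu_cf and (population) class variances var_cf.
    Features with zero variance in both classes score 0.
    """
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"f{j}" for j in range(np.asarray(X).shape[1])]
    )
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("fisher_scores requires both classes present")
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        n_c = len(Xc)
        num += n_c * (Xc.mean(axis=0) - mu) ** 2
        den += n_c * Xc.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / den, 0.0)
    return pd.Series(scores, index=names, name="fisher_score")


def fisher_filter(scores: pd.Series, keep: int | float) -> list[str]:
    """Top features by descending Fisher score.

    ``keep`` is a count (int) or a quantile fraction in (0, 1]; ties are
    broken toward the lexicographically smaller feature name.
    """
    n = len(scores)
    if isinstance(keep, float) and 0 < keep <= 1 and keep != 1:
        k = max(1, int(round(keep * n)))
    else:
        k = int(keep)
    if k <= 0:
        raise ValueError("keep must be positive")
    if k > n:
        raise ValueError(f"keep={k} exceeds number of features {n}")
    order = sorted(scores.index, key=lambda f: (-scores[f], f))
    return order[:k]


class FisherFilter(BaseEstimator, TransformerMixin):
    """Transformer form of the Fisher-score filter."""

    def __init__(self, keep: int | float = 0.05):
        self.keep = keep

    def fit(self, X, y):
        self.scores_ = fisher_scores(X, y)
        self.selected_features_ = fisher_filter(self.scores_, self.keep)
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_]
        idx = [list(self.scores_.index).index(f) for f in self.selected_features_]
        return np.asarray(X)[:, idx]


# ---------------------------------------------------------------------------
# SVM-SMOTE rebalancing


def svm_smote_balance(
    X,
    y,
    seed: int = 0,
    k_neighbors: int = 5,
    svm_c: float = 1.0,
):
    """Oversample the minority class to parity by SVM-guided interpolation.

    Support vectors of an SVM fitted to the data identify minority
    samples near the class boundary; each synthetic sample is a convex
    combination of one such support vector and one of its minority-class
    nearest neighbors. Original samples are preserved verbatim; output is
    deterministic given ``seed``. Falls back to duplication (with a
    logged warning) when the minority class is too small for neighbor
    search.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("svm_smote_balance requires exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    rng = np.random.default_rng(seed)

    if len(X_min) < 2:
        logger.warning(
            "minority class has %d sample(s); duplicating instead of "
            "interpolating", len(X_min),
        )
        dup = X_min[rng.integers(0, len(X_min), size=n_needed)]
        return (
            np.vstack([X, dup]),
            np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]),
        )

    svc = SVC(C=svm_c, kernel="rbf", gamma="scale")
    svc.fit(X, y)
    sv_idx = svc.support_
    minority_sv = X[sv_idx][y[sv_idx] == minority]
    seeds = minority_sv if len(minority_sv) else X_min

    k = min(k_neighbors + 1, len(X_min))
    nn = NearestNeighbors(n_neighbors=k).fit(X_min)
    _, neigh = nn.kneighbors(seeds)

    synth = np.empty((n_needed, X.shape[1]))
    for i in range(n_needed):
        s = rng.integers(0, len(seeds))
        # skip the first neighbor when the seed is itself a minority point
        choices = [j for j in neigh[s] if not np.array_equal(X_min[j], seeds[s])]
        if not choices:
            choices = list(neigh[s])
        j = choices[rng.integers(0, len(choices))]
        gap = rng.random()
        synth[i] = seeds[s] + gap * (X_min[j] - seeds[s])
    return (
        np.vstack([X, synth]),
        np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]),
    )


# ---------------------------------------------------------------------------
# Ensemble lasso stability scoring


@dataclass(frozen=True)
class EnLassoConfig:
    """Perturbation-ensemble settings: M = n_repeats * n_folds subsets.

    Each subset is a K-fold training complement (90% of samples at
    K = 10) of a repeated stratified K-fold partition, optionally
    rebalanced with SVM-SMOTE before the L1 fit.
    """

    n_folds: int = 10
    n_repeats: int = 10
    penalty_grid: tuple[float, ...] = (0.01, 0.1, 1.0)  # inverse strength C
    rebalance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.penalty_grid:
            raise ValueError("penalty grid must be non-empty")

    @property
    def n_subsets(self) -> int:
        return self.n_repeats * self.n_folds


@dataclass
class SubsetSelection:
    """Selection outcome of one perturbation subset."""

    weights: pd.Series  # |coefficient| per feature; zero off the selected set

    @property
    def selected(self) -> set[str]:
        return set(self.weights.index[self.weights != 0])


def _rank_descending(values: pd.Series) -> pd.Series:
    """Dense 1..n ranking, descending by value, ties by feature name."""
    order = sorted(values.index, key=lambda f: (-values[f], f))
    return pd.Series(
        np.arange(1, len(order) + 1), index=order, name="rank"
    ).reindex(values.index)


def score_table_from_selections(
    selections: list[SubsetSelection],
    fisher: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate subset selections into FSq / FSw / IS scores and ranks."""
    W = pd.DataFrame([s.weights for s in selections])
    fsq = (W != 0).mean(axis=0)
    max_w = W.abs().max(axis=1)
    normalized = W.abs().div(max_w.replace(0, np.inf), axis=0)
    fsw = normalized.mean(axis=0)
    is_score = (fsq + fsw) / 2
    table = pd.DataFrame(
        {"FSq": fsq, "FSw": fsw, "IS": is_score}
    )
    if fisher is not None:
        table.insert(0, "fisher_score", fisher.reindex(table.index))
    table["rank"] = _rank_descending(table["IS"])
    return table.sort_values("rank")


class EnLasso(BaseEstimator):
    """Ensemble-lasso stability selector.

    Fits an L1-penalized model on each of M = R * K perturbation subsets
    (the training complements of R repeated stratified K-fold partitions)
    and aggregates per-feature selection frequency (FSq), mean normalized
    absolute weight (FSw) and importance score IS = (FSq + FSw) / 2.

    ``base`` chooses the subset-level learner: ``"lasso"`` is an
    L1-regularized logistic model with its penalty picked per subset by
    internal cross-validation over ``penalty_grid``; ``"sglasso"`` is a
    sparse group lasso on +/-1-coded labels (requires ``groups``).
    """

    def __init__(
        self,
        n_folds: int = 10,
        n_repeats: int = 10,
        penalty_grid: tuple[float, ...] = (0.01, 0.1, 1.0),
        rebalance: bool = True,
        seed: int = 0,
        base: str = "lasso",
        groups: np.ndarray | None = None,
        lam1: float = 0.1,
        lam2: float = 0.1,
    ):
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.penalty_grid = penalty_grid
        self.rebalance = rebalance
        self.seed = seed
        self.base = base
        self.groups = groups
        self.lam1 = lam1
        self.lam2 = lam2

    def _config(self) -> EnLassoConfig:
        return EnLassoConfig(
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            penalty_grid=tuple(self.penalty_grid),
            rebalance=self.rebalance,
            seed=self.seed,
        )

    def _fit_subset(self, X_sub, y_sub, rng) -> np.ndarray:
        if self.base == "lasso":
            model = LogisticRegressionCV(
                Cs=list(self.penalty_grid),
                penalty="l1",
                solver="liblinear",
                cv=3,
                scoring="balanced_accuracy",
                random_state=int(rng.integers(0, 2**31 - 1)),
                max_iter=500,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_sub, y_sub)
            return model.coef_.ravel()
        if self.base == "sglasso":
            if self.groups is None:
                raise ValueError("sglasso base requires groups")
            y_coded = np.where(np.asarray(y_sub) == 1, 1.0, -1.0)
            model = SparseGroupLasso(
                groups=self.groups, lam1=self.lam1, lam2=self.lam2
            )
            model.fit(X_sub, y_coded)
            return model.coef_
        raise ValueError(f"unknown base learner {self.base!r}")

    def fit(self, X: pd.DataFrame, y):
        config = self._config()
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X), columns=[f"f{j}" for j in range(np.shape(X)[1])]
            )
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("EnLasso requires both classes present")
        # canonical column order so scores are keyed by name, not position
        if self.base != "sglasso":
            X = X[sorted(X.columns)]
        names = list(X.columns)
        values = X.to_numpy(float)
        rng = np.random.default_rng(config.seed)
        selections: list[SubsetSelection] = []
        for r in range(config.n_repeats):
            skf = StratifiedKFold(
                n_splits=config.n_folds,
                shuffle=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            for train_idx, _ in skf.split(values, y):
                X_sub, y_sub = values[train_idx], y[train_idx]
                if len(np.unique(y_sub)) < 2:  # pragma: no cover - stratified
                    logger.warning("degenerate single-class subset; redrawing")
                    keep = rng.permutation(len(y))[: len(train_idx)]
                    X_sub, y_sub = values[keep], y[keep]
                if config.rebalance:
                    X_sub, y_sub = svm_smote_balance(
                        X_sub, y_sub, seed=int(rng.integers(0, 2**31 - 1))
                    )
                coef = self._fit_subset(X_sub, y_sub, rng)
                selections.append(
                    SubsetSelection(
                        weights=pd.Series(np.abs(coef), index=names)
                    )
                )
        self.selections_ = selections
        self.score_table_ = score_table_from_selections(selections)
        return self


def enlasso_scores(
    X: pd.DataFrame, y, config: EnLassoConfig | None = None, **kwargs
) -> pd.DataFrame:
    """Functional wrapper over :class:`EnLasso`; returns the score table."""
    config = config or EnLassoConfig()
    est = EnLasso(
        n_folds=config.n_folds,
        n_repeats=config.n_repeats,
        penalty_grid=config.penalty_grid,
        rebalance=config.rebalance,
        seed=config.seed,
        **kwargs,
    )
    return est.fit(X, y).score_table_


# ---------------------------------------------------------------------------
# Forward search over the IS ranking


def forward_search_select(
    score_table: pd.DataFrame,
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    classifier=None,
    k_grid: tuple[int, ...] = (5, 10, 20, 30, 50),
) -> list[str]:
    """Pick the top-k prefix of the IS ranking maximizing validation Bacc.

    Grid is scanned in ascending k; ties keep the smallest k.
    """
    if not len(k_grid):
        raise ValueError("k_grid must be non-empty")
    classifier = classifier if classifier is not None else LogisticRegression(
        max_iter=1000
    )
    ranking = score_table.sort_values("rank").index.tolist()
    available = [f for f in ranking if f in X_train.columns]
    best_k, best_bacc = None, -np.inf
    for k in sorted(set(int(k) for k in k_grid)):
        k = min(k, len(available))
        feats = available[:k]
        model = clone(classifier)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_train[feats], y_train)
        bacc = balanced_accuracy_score(y_val, model.predict(X_val[feats]))
        if bacc > best_bacc:
            best_k, best_bacc = k, bacc
    return available[:best_k]


# ---------------------------------------------------------------------------
# Partial least squares reduction


class PlsReducer(BaseEstimator, TransformerMixin):
    """Supervised projection onto components maximizing label covariance.

    A thin wrapper over NIPALS partial least squares keeping only what is
    needed to project new samples; the projection is linear and reusable
    on held-out data.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        limit = min(X.shape[0] - 1, X.shape[1])
        if not (1 <= self.n_components <= limit):
            raise ValueError(
                f"n_components must lie in [1, {limit}] for this matrix"
            )
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(X, y)
        self.training_scores_ = self._pls.x_scores_
        return self

    def transform(self, X):
        return self._pls.transform(np.asarray(X, float))


def pls_fit(X, y, n_components: int) -> PlsReducer:
    return PlsReducer(n_components=n_components).fit(X, y)


def pls_transform(reducer: PlsReducer, X):
    return reducer.transform(X)


# ---------------------------------------------------------------------------
# The full cascade


class HybridSelector(BaseEstimator, TransformerMixin):
    """Fisher filter -> ensemble (sg)lasso -> forward search -> PLS.

    Expects standardized inputs. ``fit`` accepts an optional validation
    set (used for the forward search and the PLS component choice); when
    absent an internal stratified 80/20 split of the training data is
    used. ``transform`` projects a matrix with the same feature columns
    onto the fitted PLS components.

    mode ``"enlasso"`` uses the plain lasso ensemble; ``"ensglasso"``
    uses sparse-group-lasso base fits and requires per-feature group
    labels (aligned with the columns of X).
    """

    def __init__(
        self,
        mode: str = "enlasso",
        fisher_keep: int | float = 0.05,
        n_folds: int = 10,
        n_repeats: int = 10,
        penalty_grid: tuple[float, ...] = (0.01, 0.1, 1.0),
        rebalance: bool = True,
        k_grid: tuple[int, ...] = (5, 10, 20, 30, 50),
        max_pls_components: int = 15,
        lam1: float = 0.1,
        lam2: float = 0.1,
        seed: int = 0,
    ):
        self.mode = mode
        self.fisher_keep = fisher_keep
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.penalty_grid = penalty_grid
        self.rebalance = rebalance
        self.k_grid = k_grid
        self.max_pls_components = max_pls_components
        self.lam1 = lam1
        self.lam2 = lam2
        self.seed = seed

    def fit(
        self,
        X: pd.DataFrame,
        y,
        X_val: pd.DataFrame | None = None,
        y_val=None,
        groups: dict[str, object] | None = None,
    ):
        if self.mode not in ("enlasso", "ensglasso"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ensglasso" and groups is None:
            raise ValueError("mode 'ensglasso' requires per-feature groups")
        y = np.asarray(y)
        if X_val is None:
            X, X_val, y, y_val = train_test_split(
                X, y, test_size=0.2, stratify=y, random_state=self.seed
            )

        # stage 1: Fisher filter
        self.fisher_scores_ = fisher_scores(X, y)
        kept = fisher_filter(self.fisher_scores_, self.fisher_keep)
        X_kept = X[kept]

        # stage 2: stability scoring
        if self.mode == "enlasso":
            base_kwargs = {"base": "lasso"}
        else:
            group_labels = np.asarray([groups[f] for f in kept])
            base_kwargs = {
                "base": "sglasso",
                "groups": group_labels,
                "lam1": self.lam1,
                "lam2": self.lam2,
            }
        enlasso = EnLasso(
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            penalty_grid=tuple(self.penalty_grid),
            rebalance=self.rebalance,
            seed=self.seed,
            **base_kwargs,
        ).fit(X_kept, y)
        self.enlasso_ = enlasso
        table = enlasso.score_table_.copy()
        table.insert(0, "fisher_score", self.fisher_scores_.reindex(table.index))
        self.score_table_ = table

        # stage 3: forward search on the IS ranking
        self.selected_features_ = forward_search_select(
            table, X_kept, y, X_val[kept], y_val, k_grid=self.k_grid
        )

        # stage 4: PLS, component count chosen by validation Bacc
        X_sel, Xv_sel = X[self.selected_features_], X_val[self.selected_features_]
        limit = min(
            self.max_pls_components, len(self.selected_features_), len(X_sel) - 1
        )
        best = (None, -np.inf, None)
        for nc in range(1, max(limit, 1) + 1):
            reducer = PlsReducer(n_components=nc).fit(X_sel, y)
            probe = LogisticRegression(max_iter=1000)
            probe.fit(reducer.training_scores_, y)
            bacc = balanced_accuracy_score(
                y_val, probe.predict(reducer.transform(Xv_sel))
            )
            if bacc > best[1]:
                best = (nc, bacc, reducer)
        self.n_components_, _, self.pls_ = best
        return self

    def transform(self, X: pd.DataFrame):
        return self.pls_.transform(X[self.selected_features_])


def hybrid_select(
    X: pd.DataFrame,
    y,
    mode: str = "enlasso",
    X_val: pd.DataFrame | None = None,
    y_val=None,
    groups: dict[str, object] | None = None,
    **params,
) -> tuple[list[str], PlsReducer]:
    """Run the full cascade; returns (selected features, fitted reducer)."""
    selector = HybridSelector(mode=mode, **params)
    selector.fit(X, y, X_val=X_val, y_val=y_val, groups=groups)
    return selector.selected_features_, selector.pls_
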