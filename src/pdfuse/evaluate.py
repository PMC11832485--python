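"""Evaluation protocol: repeated stratified splits, nested tuning,
classification metrics, paired model comparison, and cross-run feature
stability.

The protocol mirrors a small-cohort study design: the data is split
8:1:1 into train/validation/test with stratification, repeated (default
ten times) under different sub-seeds; the validation set drives feature
and hyperparameter choices; six test-set metrics (Bacc, Sen, Spe,
G-mean, F1, AUC) are reported as mean +/- SD over repeats.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import balanced_accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import (
    ParameterGrid,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)

METRIC_NAMES = ("bacc", "sen", "spe", "gmean", "f1", "auc")


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified train/validation/test split settings."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def partition_sizes(self, n: int) -> tuple[int, int, int]:
        """Nearest-integer val/test sizes; the remainder goes to train."""
        n_val = int(round(self.ratios[1] * n))
        n_test = int(round(self.ratios[2] * n))
        return n - n_val - n_test, n_val, n_test


def repeated_split(
    labels, plan: SplitPlan | None = None
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Stratified (train, val, test) index triples, one per repeat.

    Each triple partitions the sample set; class proportions are
    preserved within +/-1 sample per partition. Deterministic given the
    plan's master seed, with per-repeat sub-seeds.
    """
    plan = plan or SplitPlan()
    y = np.asarray(labels)
    n = len(y)
    _, n_val, n_test = plan.partition_sizes(n)
    if n_val < 1 or n_test < 1:
        raise ValueError("validation/test partitions would be empty")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("each class needs >= 3 samples for a 3-way split")
    seeds = np.random.SeedSequence(plan.seed).generate_state(plan.n_repeats)
    triples = []
    indices = np.arange(n)
    for r in range(plan.n_repeats):
        sub = int(seeds[r] % (2**31 - 1))
        strat = y if plan.stratified else None
        rest, test = train_test_split(
            indices, test_size=n_test, stratify=strat, random_state=sub
        )
        strat_rest = y[rest] if plan.stratified else None
        train, val = train_test_split(
            rest, test_size=n_val, stratify=strat_rest, random_state=sub
        )
        triples.append((np.sort(train), np.sort(val), np.sort(test)))
    return triples


def nested_tune(
    X,
    y,
    estimator,
    grid: dict | list[dict],
    inner_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Grid search by mean inner-CV balanced accuracy on training data.

    Exhaustive over the grid, tie-broken by grid order (first point with
    the strictly best score wins); uses only the provided training data.
    """
    points = list(ParameterGrid(grid))
    if not points:
        raise ValueError("grid must be non-empty")
    X = np.asarray(X, float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in points:
        model = clone(estimator).set_params(**params)
        score = cross_val_score(
            model, X, y, cv=cv, scoring="balanced_accuracy"
        ).mean()
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def compute_metrics(
    y_true, y_prob, threshold: float = 0.5
) -> dict[str, float]:
    """Six metrics for one repeat from class-1 probabilities.

    Sen = TP/(TP+FN), Spe = TN/(TN+FP), Bacc = (Sen+Spe)/2,
    G-mean = sqrt(Sen*Spe), F1 = 2TP/(2TP+FP+FN), AUC by the rank
    statistic with midranks on ties.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {
        "bacc": 0.5 * (sen + spe),
        "sen": sen,
        "spe": spe,
        "gmean": float(np.sqrt(sen * spe)),
        "f1": f1,
        "auc": float(roc_auc_score(y_true, y_prob)),
    }


def roc_points(y_true, y_prob) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(y_true, y_prob)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class MetricsReport:
    """Per-repeat metrics plus mean +/- sample SD aggregation."""

    per_repeat: pd.DataFrame  # rows = repeats, columns = METRIC_NAMES
    roc: list[pd.DataFrame] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.per_repeat.mean(),
                "sd": self.per_repeat.std(ddof=1),
            }
        )

    def formatted(self) -> pd.Series:
        agg = self.aggregate()
        return pd.Series(
            {
                m: f"{agg.loc[m, 'mean']:.4f} ± {agg.loc[m, 'sd']:.4f}"
                for m in self.per_repeat.columns
            }
        )


def compare_models(
    metrics_a,
    metrics_b,
    test: str = "wilcoxon",
) -> float:
    """Two-sided p-value comparing paired per-repeat metric vectors.

    Default is the paired Wilcoxon signed-rank (exact null distribution
    for n <= 25, all-zero differences give p = 1); ``test ==
    "mannwhitney"`` runs the unpaired Mann-Whitney U alternative.
    """
    a = np.asarray(metrics_a, float)
    b = np.asarray(metrics_b, float)
    if a.shape != b.shape:
        raise ValueError("metric vectors must have equal repeat counts")
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test != "wilcoxon":
        raise ValueError(f"unknown test {test!r}")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    method = "exact" if len(diff) <= 25 and not np.any(diff == 0) else "auto"
    return float(
        stats.wilcoxon(a, b, alternative="two-sided", method=method).pvalue
    )


@dataclass
class StabilityReport:
    """Cross-run feature-weight stability and top-k overlap."""

    mean_weights: pd.Series  # descending order
    top_k: dict[str, list[str]]  # per modality
    overlaps: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        out = self.mean_weights.to_frame("mean_weight")
        out["rank"] = np.arange(1, len(out) + 1)
        return out


def feature_stability(
    weight_tables: list[pd.Series],
    modality_of: dict[str, str] | None = None,
    top_k: dict[str, int] | None = None,
    method_top_lists: dict[str, dict[str, list[str]]] | None = None,
) -> StabilityReport:
    """Average per-repeat feature weights and extract stable top lists.

    A feature absent from a repeat's table contributes weight 0 for that
    repeat. Mean weights are ranked descending (ties by name); top-k
    lists are extracted per modality (defaults: 10 MRI-type features, 30
    genotype loci). When ``method_top_lists`` supplies per-method top
    lists, pairwise and full intersections across methods are reported.
    """
    if len(weight_tables) < 2:
        raise ValueError("feature_stability requires >= 2 repeats")
    stacked = pd.DataFrame(weight_tables).fillna(0.0)
    means = stacked.mean(axis=0)
    order = sorted(means.index, key=lambda f: (-means[f], f))
    means = means.reindex(order)

    modality_of = modality_of or {}
    top_k = top_k or {"mri": 10, "snp": 30}
    tops: dict[str, list[str]] = {}
    for modality, k in top_k.items():
        feats = [
            f for f in order if modality_of.get(f, "all") == modality
        ] if modality_of else list(order)
        tops[modality] = feats[:k]

    overlaps: dict[tuple[str, ...], set[str]] = {}
    if method_top_lists:
        methods = sorted(method_top_lists)
        for modality in top_k:
            lists = {
                m: set(method_top_lists[m].get(modality, []))
                for m in methods
            }
            for a, b in itertools.combinations(methods, 2):
                overlaps[(modality, a, b)] = lists[a] & lists[b]
            if len(methods) >= 3:
                overlaps[(modality, *methods)] = set.intersection(
                    *lists.values()
                )
    return StabilityReport(mean_weights=means, top_k=tops, overlaps=overlaps)


def evaluate_probabilities(
    y_true_per_repeat: list[np.ndarray],
    y_prob_per_repeat: list[np.ndarray],
) -> MetricsReport:
    """Assemble a MetricsReport from per-repeat test outcomes."""
    rows = []
    rocs = []
    for y_true, y_prob in zip(y_true_per_repeat, y_prob_per_repeat):
        rows.append(compute_metrics(y_true, y_prob))
        rocs.append(roc_points(y_true, y_prob))
    return MetricsReport(
        per_repeat=pd.DataFrame(rows, columns=list(METRIC_NAMES)), roc=rocs
    )


def balanced_accuracy(y_true, y_pred) -> float:
    return float(balanced_accuracy_score(y_true, y_pred))
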