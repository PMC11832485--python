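"""Experiment orchestration for the four study arms.

An experiment runs: cohort simulation (or loading) -> genotype QC ->
repeated stratified 8:1:1 splits -> per-repeat feature selection, model
training and test-set evaluation -> metric aggregation and cross-run
feature stability. Arms:

- ``single_snp`` / ``single_mri``: one modality through the
  Fisher-EnLasso-PLS cascade and a single classifier.
- ``fusion1``: feature-level fusion; both modalities concatenated and
  passed through the same cascade.
- ``fusion2``: feature-level fusion with the sparse-group-lasso variant
  (one group per modality) inside the ensemble.
- ``ae_stacking``: decision-level fusion; each modality gets its own
  cascade front end and the adaptive stacking ensemble combines
  per-modality base classifiers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import clone

from .evaluate import (
    MetricsReport,
    SplitPlan,
    evaluate_probabilities,
    feature_stability,
    nested_tune,
)
from .qc import QcThresholds, snp_qc_filter, standardize_features
from .selection import HybridSelector
from .simulate import LabeledCohort, SimConfig, read_cohort, simulate_cohort
from .stacking import AdaptiveStackingClassifier, make_classifier_registry

logger = logging.getLogger(__name__)

ARMS = ("single_mri", "single_snp", "fusion1", "fusion2", "ae_stacking")

_SELECTOR_KEYS = {
    "fisher_keep", "n_folds", "n_repeats", "penalty_grid", "rebalance",
    "k_grid", "max_pls_components", "lam1", "lam2",
}


@dataclass
class RunConfig:
    """Validated configuration of one experiment run."""

    arm: str = "single_snp"
    cohort_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    classifier: str = "lr"
    classifier_names: tuple[str, ...] = ("lr", "svm", "rf", "xgboost")
    stacking_folds: int = 10
    tune_grid: dict | None = None
    selector: dict = field(default_factory=dict)
    qc: QcThresholds = field(default_factory=QcThresholds)
    split: SplitPlan = field(default_factory=SplitPlan)
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        bad = set(self.selector) - _SELECTOR_KEYS
        if bad:
            raise ValueError(f"unknown selector keys: {sorted(bad)}")
        registry_names = (
            "lr", "svm", "mlp", "adaboost", "rf", "gbdt", "xgboost",
            "lightgbm",
        )
        if self.classifier not in registry_names:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; registry offers "
                f"{registry_names}"
            )
        for n in self.classifier_names:
            if n not in registry_names:
                raise ValueError(
                    f"unknown classifier {n!r}; registry offers "
                    f"{registry_names}"
                )

    def canonical(self) -> dict:
        d = {
            "arm": self.arm,
            "cohort_path": self.cohort_path,
            "sim": dataclasses.asdict(self.sim),
            "classifier": self.classifier,
            "classifier_names": list(self.classifier_names),
            "stacking_folds": self.stacking_folds,
            "tune_grid": self.tune_grid,
            "selector": dict(sorted(self.selector.items())),
            "qc": dataclasses.asdict(self.qc),
            "split": {
                "ratios": list(self.split.ratios),
                "n_repeats": self.split.n_repeats,
                "stratified": self.split.stratified,
                "seed": self.split.seed,
            },
            "seed": self.seed,
        }
        d["sim"]["maf_range"] = list(d["sim"]["maf_range"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


_TOP_LEVEL_KEYS = {
    "arm", "cohort_path", "sim", "classifier", "classifier_names",
    "stacking_folds", "tune_grid", "selector", "qc", "split", "out_dir",
    "seed", "log_level", "force",
}


def validate_config(source: str | Path | dict) -> RunConfig:
    """Build a RunConfig from a YAML file or dict, rejecting unknown keys."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors = []
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("arm", "cohort_path", "classifier", "stacking_folds",
                "tune_grid", "out_dir", "seed", "log_level", "force"):
        if key in raw:
            kwargs[key] = raw[key]
    if "classifier_names" in raw:
        kwargs["classifier_names"] = tuple(raw["classifier_names"])
    if "selector" in raw:
        kwargs["selector"] = dict(raw["selector"])
    try:
        if "sim" in raw:
            sim = dict(raw["sim"])
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            kwargs["sim"] = SimConfig(**sim)
        if "qc" in raw:
            kwargs["qc"] = QcThresholds(**raw["qc"])
        if "split" in raw:
            split = dict(raw["split"])
            if "ratios" in split:
                split["ratios"] = tuple(split["ratios"])
            kwargs["split"] = SplitPlan(**split)
        config = RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        config = None
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return config


@dataclass
class ExperimentResult:
    """Bundle returned by :func:`run_experiment`."""

    config: RunConfig
    metrics: MetricsReport
    stability: "pd.Series | None"
    n_selected_per_repeat: list[int]
    qc_summary: dict
    provenance: dict


def _load_cohort(config: RunConfig) -> LabeledCohort:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    cohort, _ = simulate_cohort(config.sim)
    return cohort


def _apply_qc(cohort: LabeledCohort, config: RunConfig) -> tuple[LabeledCohort, dict]:
    summary: dict = {}
    modalities = dict(cohort.modalities)
    for name in cohort.genotype_modalities:
        filtered, report = snp_qc_filter(modalities[name], config.qc)
        modalities[name] = filtered
        summary[name] = report.summary()
        logger.info(
            "QC %s: retained %d / %d loci", name, report.n_retained,
            report.n_input,
        )
    return (
        LabeledCohort(
            sample_ids=cohort.sample_ids,
            labels=cohort.labels,
            modalities=modalities,
            genotype_modalities=set(cohort.genotype_modalities),
        ),
        summary,
    )


def _standardized_blocks(cohort, train_idx, val_idx, test_idx):
    """Per-modality z-scored train/val/test blocks (train-fitted)."""
    blocks = {}
    for name, frame in cohort.modalities.items():
        tr, va, te, _, _ = standardize_features(
            frame.iloc[train_idx], frame.iloc[val_idx], frame.iloc[test_idx]
        )
        blocks[name] = (tr, va, te)
    return blocks


def _make_selector(config: RunConfig, mode: str, seed: int) -> HybridSelector:
    params = dict(config.selector)
    if "penalty_grid" in params:
        params["penalty_grid"] = tuple(params["penalty_grid"])
    if "k_grid" in params:
        params["k_grid"] = tuple(params["k_grid"])
    return HybridSelector(mode=mode, seed=seed, **params)


def _fit_classifier(config, scores_train, y_train, seed):
    registry = make_classifier_registry(seed=seed)
    est = clone(registry[config.classifier])
    if config.tune_grid:
        best = nested_tune(
            scores_train, y_train, est, config.tune_grid, seed=seed
        )
        est.set_params(**best)
    est.fit(scores_train, y_train)
    return est


def _run_single_or_fusion(config, cohort, blocks, y, train, val, test, seed):
    if config.arm == "single_mri":
        names, mode = ["mri"], "enlasso"
    elif config.arm == "single_snp":
        names, mode = ["snp"], "enlasso"
    else:
        names = list(cohort.modalities)
        mode = "enlasso" if config.arm == "fusion1" else "ensglasso"
    X_tr = pd.concat([blocks[m][0] for m in names], axis=1)
    X_va = pd.concat([blocks[m][1] for m in names], axis=1)
    X_te = pd.concat([blocks[m][2] for m in names], axis=1)
    groups = None
    if mode == "ensglasso":
        groups = {
            f: m for m in names for f in cohort.modalities[m].columns
        }
    selector = _make_selector(config, mode, seed)
    selector.fit(X_tr, y[train], X_val=X_va, y_val=y[val], groups=groups)
    est = _fit_classifier(
        config, selector.transform(X_tr), y[train], seed
    )
    prob = est.predict_proba(selector.transform(X_te))[:, 1]
    weights = selector.score_table_["IS"]
    return prob, weights, len(selector.selected_features_)


class _ValBoundSelector:
    """Front-end adapter fixing the repeat's validation set.

    The validation split (outside the stacking training data) drives the
    forward search and PLS component choice, exactly as in the
    single-modality arms, while the selector itself is refit on each
    stacking fold's training part.
    """

    def __init__(self, selector, X_val, y_val):
        self.selector = selector
        self.X_val = X_val
        self.y_val = y_val

    def fit(self, X, y):
        self.selector.fit(X, y, X_val=self.X_val, y_val=self.y_val)
        return self

    def transform(self, X):
        return self.selector.transform(X)

    @property
    def score_table_(self):
        return self.selector.score_table_

    @property
    def selected_features_(self):
        return self.selector.selected_features_


def _run_stacking(config, cohort, blocks, y, train, val, test, seed):
    # the selection/PLS front end is refit inside every stacking fold so
    # the fold balanced accuracies driving learner selection are unbiased
    modality_names = list(cohort.modalities)
    front_ends = {
        m: (lambda k, i=i, m=m: _ValBoundSelector(
            _make_selector(config, "enlasso", seed + 97 * i + 31 * k),
            blocks[m][1], y[val],
        ))
        for i, m in enumerate(modality_names)
    }
    train_raw = {m: blocks[m][0] for m in modality_names}
    test_raw = {m: blocks[m][2] for m in modality_names}
    stacker = AdaptiveStackingClassifier(
        classifier_names=config.classifier_names,
        K=config.stacking_folds,
        seed=seed,
        front_ends=front_ends,
    )
    stacker.fit(train_raw, y[train])
    prob = stacker.predict_proba(test_raw)[:, 1]

    # stability weights: average the fold front ends' IS tables
    weights, n_selected = [], 0
    seen = set()
    for report in stacker.model_.reports:
        m = report.spec.modality
        if m in seen:
            continue
        seen.add(m)
        fes = [fm.front_end for fm in report.fold_models if fm.front_end]
        tables = [fe.score_table_["IS"] for fe in fes]
        weights.append(pd.DataFrame(tables).fillna(0.0).mean(axis=0))
        n_selected += int(
            round(np.mean([len(fe.selected_features_) for fe in fes]))
        )
    return prob, pd.concat(weights), n_selected


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Execute one experiment arm end to end.

    Deterministic given the config and master seed; when ``out_dir`` is
    set, results are written there and a completed run with the same
    config hash is not recomputed unless ``force``.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        prov_path = out_dir / "provenance.json"
        if prov_path.exists() and not config.force:
            existing = json.loads(prov_path.read_text())
            if existing.get("config_hash") == config.config_hash():
                logger.info("run already completed (use force to rerun)")
                return _load_result(config, out_dir, existing)

    t0 = time.time()
    cohort = _load_cohort(config)
    cohort, qc_summary = _apply_qc(cohort, config)
    y = cohort.labels
    plan = SplitPlan(
        ratios=config.split.ratios,
        n_repeats=config.split.n_repeats,
        stratified=config.split.stratified,
        seed=config.seed,
    )
    triples = repeated_split_for(y, plan)
    seeds = np.random.SeedSequence(config.seed).generate_state(len(triples))

    y_tests, probs, weight_tables, n_selected = [], [], [], []
    for r, (train, val, test) in enumerate(triples):
        rep_seed = int(seeds[r] % (2**31 - 1))
        t_rep = time.time()
        blocks = _standardized_blocks(cohort, train, val, test)
        if config.arm == "ae_stacking":
            prob, weights, n_sel = _run_stacking(
                config, cohort, blocks, y, train, val, test, rep_seed
            )
        else:
            prob, weights, n_sel = _run_single_or_fusion(
                config, cohort, blocks, y, train, val, test, rep_seed
            )
        y_tests.append(y[test])
        probs.append(prob)
        weight_tables.append(weights)
        n_selected.append(n_sel)
        logger.info(
            "repeat %d/%d: %d features selected, %.1fs",
            r + 1, len(triples), n_sel, time.time() - t_rep,
        )

    metrics = evaluate_probabilities(y_tests, probs)
    modality_of = {
        f: m for m, frame in cohort.modalities.items() for f in frame.columns
    }
    stability = feature_stability(weight_tables, modality_of=modality_of)
    provenance = {
        "config_hash": config.config_hash(),
        "config": config.canonical(),
        "seed": config.seed,
        "package_version": _package_version(),
        "numpy_version": np.__version__,
        "runtime_s": round(time.time() - t0, 2),
    }
    result = ExperimentResult(
        config=config,
        metrics=metrics,
        stability=stability.mean_weights,
        n_selected_per_repeat=n_selected,
        qc_summary=qc_summary,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_result(result, out_dir)
    return result


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("pdfuse")
    except Exception:  # pragma: no cover - editable edge cases
        return "unknown"


def repeated_split_for(labels, plan: SplitPlan):
    from .evaluate import repeated_split

    return repeated_split(labels, plan)


def _write_result(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.metrics.per_repeat.to_csv(
        out_dir / "metrics.tsv", sep="\t", index_label="repeat"
    )
    result.metrics.aggregate().to_csv(
        out_dir / "metrics_summary.tsv", sep="\t", index_label="metric"
    )
    if result.stability is not None:
        result.stability.to_frame("mean_weight").to_csv(
            out_dir / "stability.tsv", sep="\t", index_label="feature"
        )
    roc_dir = out_dir / "roc"
    roc_dir.mkdir(exist_ok=True)
    for i, roc in enumerate(result.metrics.roc):
        roc.to_csv(roc_dir / f"repeat_{i}.tsv", sep="\t", index=False)
    (out_dir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2)
    )
    pd.Series(result.n_selected_per_repeat, name="n_selected").to_csv(
        out_dir / "n_selected.tsv", sep="\t", index_label="repeat"
    )


def _load_result(config: RunConfig, out_dir: Path, provenance: dict):
    per_repeat = pd.read_csv(
        out_dir / "metrics.tsv", sep="\t", index_col="repeat"
    )
    stability_path = out_dir / "stability.tsv"
    stability = None
    if stability_path.exists():
        stability = pd.read_csv(
            stability_path, sep="\t", index_col="feature"
        )["mean_weight"]
    n_selected = pd.read_csv(
        out_dir / "n_selected.tsv", sep="\t", index_col="repeat"
    )["n_selected"].tolist()
    return ExperimentResult(
        config=config,
        metrics=MetricsReport(per_repeat=per_repeat),
        stability=stability,
        n_selected_per_repeat=n_selected,
        qc_summary={},
        provenance=provenance,
    )
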