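"""Reproduction protocol: the package's headline property checks.

These routines regenerate the study conditions from scratch (planted
signal: 2,000 SNPs with 10 causal loci at allele-frequency shift 0.25;
300 morphometry features with 8 informative at Cohen's d = 0.8; 113
cases / 54 controls) and measure what the toolkit is supposed to
deliver: recovery of planted features by the stability cascade, chance-
level behavior on null cohorts, and the decision-level-fusion ordering
against single-modality baselines. Both the test suite and
``scripts/acceptance.py`` call into this module.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .evaluate import SplitPlan
from .pipeline import RunConfig, run_experiment
from .qc import snp_qc_filter, standardize_features
from .selection import (
    EnLassoConfig,
    enlasso_scores,
    fisher_filter,
    fisher_scores,
)
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

# desk-scale ensemble size: 2 repeats x 10 folds = 20 perturbation subsets
DESK_SELECTOR = {
    "n_repeats": 2,
    "n_folds": 10,
    "k_grid": (5, 10, 20, 30, 50),
    "max_pls_components": 10,
}
DESK_POOL = ("lr", "svm", "rf", "xgboost")


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def signal_recovery(seed: int = 0, n_seeds: int = 10, top_k: int = 50) -> dict:
    """Recovery of planted features in the top-k of the IS ranking.

    For each sub-seed a fresh default cohort is drawn; per modality the
    QC'd, standardized matrix passes the Fisher filter (top 5%) and the
    ensemble lasso, and planted features found in the modality's top-k by
    importance score are counted. Returns the mean recovery fraction and
    the hypergeometric enrichment p-value of the pooled overlap.
    """
    fractions = []
    pooled_overlap = pooled_planted = 0
    pooled_population = pooled_draws = 0
    for s in _sub_seeds(seed, n_seeds):
        cohort, truth = simulate_cohort(SimConfig(seed=s))
        y = cohort.labels
        recovered = planted = 0
        for modality, truth_names in (
            ("snp", truth.causal_snp_names),
            ("mri", truth.informative_mri_names),
        ):
            X = cohort.modalities[modality]
            if modality in cohort.genotype_modalities:
                X, _ = snp_qc_filter(X)
            Xz = standardize_features(X)[0]
            kept = fisher_filter(fisher_scores(Xz, y), 0.05)
            table = enlasso_scores(
                Xz[kept], y,
                EnLassoConfig(n_folds=10, n_repeats=2, seed=s),
            )
            top = set(table.sort_values("rank").index[:top_k])
            overlap = len(truth_names & top)
            recovered += overlap
            planted += len(truth_names)
            pooled_overlap += overlap
            pooled_population += X.shape[1]
            pooled_draws += min(top_k, len(table))
        pooled_planted += planted
        fractions.append(recovered / planted)
    enrichment_p = float(
        stats.hypergeom.sf(
            pooled_overlap - 1, pooled_population, pooled_planted,
            pooled_draws,
        )
    )
    return {
        "recovery_fraction": float(np.mean(fractions)),
        "per_seed": fractions,
        "enrichment_p": enrichment_p,
        "n_seeds": n_seeds,
    }


def null_calibration(seed: int = 0, n_repeats: int = 10) -> dict:
    """Full-pipeline balanced accuracy on a zero-effect cohort.

    Guards against leakage through SMOTE, feature selection, PLS and
    threshold choices: with no planted signal the repeated-split test
    Bacc must sit within binomial noise of 0.5.
    """
    config = RunConfig(
        arm="single_snp",
        sim=SimConfig(snp_effect=0.0, mri_effect=0.0, seed=seed),
        selector=dict(DESK_SELECTOR),
        split=SplitPlan(n_repeats=n_repeats),
        seed=seed,
    )
    result = run_experiment(config)
    baccs = result.metrics.per_repeat["bacc"].to_numpy()
    # chance-level SE of one repeat's Bacc on a 17-sample test split
    n_test = SplitPlan().partition_sizes(167)[2]
    n_pos = round(n_test * 113 / 167)
    n_neg = n_test - n_pos
    se_repeat = 0.5 * np.sqrt(0.25 / n_pos + 0.25 / n_neg)
    return {
        "mean_bacc": float(baccs.mean()),
        "per_repeat": baccs.tolist(),
        "se_mean": float(se_repeat / np.sqrt(len(baccs))),
        "n_repeats": n_repeats,
    }


def architecture_ordering(seed: int = 0, n_repeats: int = 10) -> dict:
    """Decision-level fusion vs the best single-modality classifier.

    Runs the single-SNP, single-MRI and bimodal adaptive-stacking arms on
    the same default planted-signal cohort and identical repeated splits
    (shared master seed) and reports the mean test balanced accuracies.
    """
    means = {}
    for arm in ("single_snp", "single_mri", "ae_stacking"):
        config = RunConfig(
            arm=arm,
            sim=SimConfig(seed=seed),
            selector=dict(DESK_SELECTOR),
            classifier_names=DESK_POOL,
            split=SplitPlan(n_repeats=n_repeats),
            seed=seed,
        )
        result = run_experiment(config)
        means[arm] = float(result.metrics.per_repeat["bacc"].mean())
        logger.info("arm %s: mean Bacc %.4f", arm, means[arm])
    best_single = max(means["single_snp"], means["single_mri"])
    return {
        "stacking_bacc": means["ae_stacking"],
        "single_snp_bacc": means["single_snp"],
        "single_mri_bacc": means["single_mri"],
        "best_single_bacc": best_single,
        "margin": means["ae_stacking"] - best_single,
        "n_repeats": n_repeats,
    }
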