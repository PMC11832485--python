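"""Genotype locus quality control and feature standardization.

Locus filters follow the standard chip-genotyping protocol: a locus is
removed when its minor allele frequency is below 1%, its call rate is
below 95%, or its Hardy-Weinberg equilibrium exact-test p-value is below
1e-6. Thresholds are exclusive for failure: a locus exactly at a
threshold passes. MAF and HWE are computed over non-missing calls only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0 <= self.call_rate_min <= 1):
            raise ValueError("call_rate_min must lie in [0, 1]")
        if not (0 < self.hwe_p_min < 1):
            raise ValueError("hwe_p_min must lie in (0, 1)")


@dataclass
class QcReport:
    """Per-locus QC statistics and the removal decision per rule."""

    table: pd.DataFrame  # columns: maf, call_rate, hwe_p, fail_* , keep
    thresholds: QcThresholds

    @property
    def n_input(self) -> int:
        return len(self.table)

    @property
    def n_retained(self) -> int:
        return int(self.table["keep"].sum())

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def removed_per_rule(self) -> dict[str, int]:
        return {
            "maf": int(self.table["fail_maf"].sum()),
            "call_rate": int(self.table["fail_call_rate"].sum()),
            "hwe": int(self.table["fail_hwe"].sum()),
        }

    def summary(self) -> dict[str, float | int]:
        per_rule = self.removed_per_rule()
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "removed_maf": per_rule["maf"],
            "removed_call_rate": per_rule["call_rate"],
            "removed_hwe": per_rule["hwe"],
            "maf_min": self.thresholds.maf_min,
            "call_rate_min": self.thresholds.call_rate_min,
            "hwe_p_min": self.thresholds.hwe_p_min,
        }


def minor_allele_frequency(genotypes: np.ndarray | pd.Series) -> float:
    """Minor allele frequency of one additive-coded genotype column.

    Computed over non-missing calls: the alternate-allele frequency
    f = (#alt alleles) / (2 * #non-missing), folded to min(f, 1 - f).
    """
    g = np.asarray(genotypes, float)
    obs = g[~np.isnan(g)]
    if obs.size == 0:
        raise ValueError("all genotype calls are missing")
    f = obs.sum() / (2 * obs.size)
    return float(min(f, 1 - f))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg equilibrium test.

    Conditions on the observed allele counts and enumerates every
    heterozygote count with the same parity, summing the probabilities of
    all configurations no more likely than the observed one.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    # enumerate heterozygote counts sharing the parity of the rare-allele
    # count; unnormalized probabilities by the standard recurrence
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    probs = {}
    # start from the largest heterozygote count with weight 1, recur down
    h = hets[-1]
    probs[h] = 1.0
    while h > 1:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # P(h-2) / P(h) = h (h-1) / (4 (rare_hom + 1) (common_hom + 1))
        probs[h - 2] = probs[h] * h * (h - 1) / (
            4.0 * (rare_hom + 1) * (common_hom + 1)
        )
        h -= 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12))
    return float(min(1.0, p / total))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    obs = column[~np.isnan(column)]
    return (
        int(np.sum(obs == 0)),
        int(np.sum(obs == 1)),
        int(np.sum(obs == 2)),
    )


def snp_qc_filter(
    genotypes: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    controls_only_hwe: bool = False,
    labels: np.ndarray | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply per-locus QC filters to an additive-coded genotype matrix.

    A locus is removed iff MAF < ``maf_min`` OR call rate <
    ``call_rate_min`` OR HWE p < ``hwe_p_min``; surviving column order is
    preserved. With ``controls_only_hwe`` the HWE test is restricted to
    control samples (``labels`` == 0); by default all samples are used.
    """
    thresholds = thresholds or QcThresholds()
    if controls_only_hwe:
        if labels is None:
            raise ValueError("controls_only_hwe requires labels")
        hwe_rows = np.asarray(labels) == 0
    else:
        hwe_rows = np.ones(len(genotypes), bool)

    records = []
    values = genotypes.to_numpy(float)
    for j, name in enumerate(genotypes.columns):
        col = values[:, j]
        n_obs = int(np.sum(~np.isnan(col)))
        call_rate = n_obs / len(col) if len(col) else 0.0
        if n_obs == 0:
            maf, hwe_p = 0.0, 1.0
        else:
            maf = minor_allele_frequency(col)
            hwe_col = col[hwe_rows]
            if np.sum(~np.isnan(hwe_col)) == 0:
                hwe_p = 1.0
            else:
                hwe_p = hwe_exact_test(*_genotype_counts(hwe_col))
        records.append(
            {
                "locus": name,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "fail_maf": maf < thresholds.maf_min,
                "fail_call_rate": call_rate < thresholds.call_rate_min,
                "fail_hwe": hwe_p < thresholds.hwe_p_min,
            }
        )
    if records:
        table = pd.DataFrame.from_records(records).set_index("locus")
        table["keep"] = ~(
            table["fail_maf"] | table["fail_call_rate"] | table["fail_hwe"]
        )
        kept = [c for c in genotypes.columns if table.loc[c, "keep"]]
    else:
        table = pd.DataFrame(
            columns=[
                "maf", "call_rate", "hwe_p",
                "fail_maf", "fail_call_rate", "fail_hwe", "keep",
            ]
        )
        kept = []
    return genotypes[kept], QcReport(table=table, thresholds=thresholds)


class SnpQcFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`snp_qc_filter`.

    Fitting records which loci pass QC on the training matrix; transform
    subsets any matrix to the surviving loci (column order preserved).
    """

    def __init__(
        self,
        maf_min: float = 0.01,
        call_rate_min: float = 0.95,
        hwe_p_min: float = 1e-6,
        controls_only_hwe: bool = False,
    ):
        self.maf_min = maf_min
        self.call_rate_min = call_rate_min
        self.hwe_p_min = hwe_p_min
        self.controls_only_hwe = controls_only_hwe

    def fit(self, X: pd.DataFrame, y: np.ndarray | None = None):
        thresholds = QcThresholds(
            maf_min=self.maf_min,
            call_rate_min=self.call_rate_min,
            hwe_p_min=self.hwe_p_min,
        )
        _, report = snp_qc_filter(
            X, thresholds,
            controls_only_hwe=self.controls_only_hwe, labels=y,
        )
        self.report_ = report
        self.kept_loci_ = [c for c in X.columns if report.table.loc[c, "keep"]]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_loci_]


def standardize_features(
    train: pd.DataFrame | np.ndarray,
    *apply: pd.DataFrame | np.ndarray,
) -> tuple:
    """Per-feature z-scoring fitted on the training matrix only.

    Missing values are mean-imputed (per training-set feature mean) before
    scaling so genotype matrices with missing calls can feed penalized
    fits and distance-based oversampling. Zero-variance features map to 0.
    Returns ``(train_z, *apply_z, means, sds)``.
    """
    is_frame = isinstance(train, pd.DataFrame)
    train_values = np.asarray(train, float)
    means = np.nanmean(train_values, axis=0)
    scaler = StandardScaler()

    def _impute(values: np.ndarray) -> np.ndarray:
        out = values.copy()
        nan_r, nan_c = np.where(np.isnan(out))
        out[nan_r, nan_c] = means[nan_c]
        return out

    train_z = scaler.fit_transform(_impute(train_values))
    results = [train_z]
    for m in apply:
        results.append(scaler.transform(_impute(np.asarray(m, float))))
    if is_frame:
        results[0] = pd.DataFrame(
            results[0], index=train.index, columns=train.columns
        )
        for i, m in enumerate(apply, start=1):
            if isinstance(m, pd.DataFrame):
                results[i] = pd.DataFrame(
                    results[i], index=m.index, columns=m.columns
                )
    return (*results, scaler.mean_, scaler.scale_)
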