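"""Synthetic multimodal cohort generator.

Emulates the statistical shape of an imaging-genetics case/control study:
an additive-coded genotype matrix (0/1/2 with missing calls) with per-locus
allele frequencies, and a continuous morphometry matrix with correlated
feature blocks. A small set of class-informative features is planted per
modality so recovery by downstream feature selection can be scored against
known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.nan

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a desk-scale version of a 113-case / 54-control
    imaging-genetics cohort: 2,000 SNPs (10 causal, allele-frequency shift
    0.25 between classes) and 300 morphometry features (8 informative at
    Cohen's d = 0.8), keeping the p >> n regime.
    """

    n_cases: int = 113
    n_controls: int = 54
    n_snp: int = 2000
    n_mri: int = 300
    n_causal_snp: int = 10
    n_informative_mri: int = 8
    snp_effect: float = 0.25
    mri_effect: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    mri_block_size: int = 10
    mri_block_rho: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_snp <= 0 or self.n_mri <= 0:
            raise ValueError("n_snp and n_mri must be positive")
        if not (0 <= self.n_causal_snp <= self.n_snp):
            raise ValueError("n_causal_snp must lie in [0, n_snp]")
        if not (0 <= self.n_informative_mri <= self.n_mri):
            raise ValueError("n_informative_mri must lie in [0, n_mri]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.snp_effect < 0 or self.mri_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        if hi + self.snp_effect >= 1:
            raise ValueError(
                "maf_range upper bound plus snp_effect must stay below 1 "
                "(shifted allele frequencies would leave (0, 1))"
            )
        if self.mri_block_size <= 0:
            raise ValueError("mri_block_size must be positive")
        if not (0 <= self.mri_block_rho < 1):
            raise ValueError("mri_block_rho must lie in [0, 1)")


@dataclass
class LabeledCohort:
    """Per-modality feature matrices plus binary labels and sample IDs.

    ``modalities`` maps a modality name to a DataFrame indexed by
    ``sample_ids`` (rows aligned with ``labels``); genotype modalities use
    NaN as the missing-call marker and are listed in
    ``genotype_modalities``.
    """

    sample_ids: list[str]
    labels: np.ndarray  # 1 = case (PD), 0 = control (HC)
    modalities: dict[str, pd.DataFrame]
    genotype_modalities: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        self.labels = np.asarray(self.labels)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        n = len(self.sample_ids)
        if len(self.labels) != n:
            raise ValueError("labels length must match sample_ids")
        for name, frame in self.modalities.items():
            if frame.shape[0] != n or list(frame.index) != self.sample_ids:
                raise ValueError(
                    f"modality {name!r} rows must match sample_ids in order"
                )
            if frame.columns.duplicated().any():
                raise ValueError(f"modality {name!r} has duplicate feature names")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, indices: np.ndarray) -> "LabeledCohort":
        """Row-subset every modality (used to carve train/val/test sets)."""
        ids = [self.sample_ids[i] for i in indices]
        return LabeledCohort(
            sample_ids=ids,
            labels=self.labels[indices],
            modalities={m: f.iloc[indices] for m, f in self.modalities.items()},
            genotype_modalities=set(self.genotype_modalities),
        )

    def equals(self, other: "LabeledCohort") -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        if not np.array_equal(self.labels, other.labels):
            return False
        if set(self.modalities) != set(other.modalities):
            return False
        if self.genotype_modalities != other.genotype_modalities:
            return False
        for name, frame in self.modalities.items():
            of = other.modalities[name]
            if list(frame.columns) != list(of.columns):
                return False
            a, b = frame.to_numpy(float), of.to_numpy(float)
            eq = (a == b) | (np.isnan(a) & np.isnan(b))
            if not eq.all():
                return False
        return True


@dataclass
class SyntheticTruth:
    """Planted ground truth: which features carry class signal."""

    causal_snp_names: set[str]
    informative_mri_names: set[str]
    effect_sizes: dict[str, float]


def simulate_cohort(config: SimConfig) -> tuple[LabeledCohort, SyntheticTruth]:
    """Draw a multimodal cohort with planted class-informative features.

    Genotypes are Binomial(2, p) per locus with p uniform in
    ``maf_range`` for controls and shifted by ``snp_effect`` at causal
    loci for cases. Morphometry features are block-correlated Gaussians
    (compound symmetry with correlation ``mri_block_rho`` inside blocks of
    ``mri_block_size``) with mean shift ``mri_effect`` (in SD units) at
    informative features for cases. Missing genotype calls are injected
    completely at random. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    labels = np.concatenate(
        [np.ones(config.n_cases, int), np.zeros(config.n_controls, int)]
    )
    sample_ids = [f"S{i:04d}" for i in range(n)]
    is_case = labels == 1

    # --- genotypes ---
    snp_names = [f"snp{j:05d}" for j in range(config.n_snp)]
    p_control = rng.uniform(*config.maf_range, size=config.n_snp)
    causal_idx = rng.choice(config.n_snp, size=config.n_causal_snp, replace=False)
    p_case = p_control.copy()
    p_case[causal_idx] = p_control[causal_idx] + config.snp_effect
    if np.any(p_case <= 0) or np.any(p_case >= 1):
        raise ValueError("shifted allele frequencies leave (0, 1)")
    geno = np.empty((n, config.n_snp), float)
    geno[is_case] = rng.binomial(2, p_case, size=(config.n_cases, config.n_snp))
    geno[~is_case] = rng.binomial(
        2, p_control, size=(config.n_controls, config.n_snp)
    )
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING
    geno_df = pd.DataFrame(geno, index=sample_ids, columns=snp_names)

    # --- morphometry ---
    mri_names = [f"mri{j:04d}" for j in range(config.n_mri)]
    rho = config.mri_block_rho
    n_blocks = int(np.ceil(config.n_mri / config.mri_block_size))
    mri = np.empty((n, config.n_mri))
    for b in range(n_blocks):
        lo = b * config.mri_block_size
        hi = min(lo + config.mri_block_size, config.n_mri)
        width = hi - lo
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        mri[:, lo:hi] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    informative_idx = rng.choice(
        config.n_mri, size=config.n_informative_mri, replace=False
    )
    mri[np.ix_(is_case, informative_idx)] += config.mri_effect
    mri_df = pd.DataFrame(mri, index=sample_ids, columns=mri_names)

    cohort = LabeledCohort(
        sample_ids=sample_ids,
        labels=labels,
        modalities={"snp": geno_df, "mri": mri_df},
        genotype_modalities={"snp"},
    )
    effects = {snp_names[j]: config.snp_effect for j in causal_idx}
    effects.update({mri_names[j]: config.mri_effect for j in informative_idx})
    truth = SyntheticTruth(
        causal_snp_names={snp_names[j] for j in causal_idx},
        informative_mri_names={mri_names[j] for j in informative_idx},
        effect_sizes=effects,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# cohort I/O: one TSV per modality, a label table, and a manifest


def write_cohort(cohort: LabeledCohort, directory: str | Path) -> list[Path]:
    """Write a cohort as tab-separated tables plus a manifest.

    Layout: ``labels.tsv`` (sample_id, label), one ``<modality>.tsv`` per
    modality (first column sample_id), and ``manifest.tsv`` mapping
    modality name -> file name and genotype flag. Genotype missing calls
    are written as ``NA``; the round trip is lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    labels = pd.DataFrame(
        {"sample_id": cohort.sample_ids, "label": cohort.labels}
    )
    label_path = directory / "labels.tsv"
    labels.to_csv(label_path, sep="\t", index=False)
    written.append(label_path)

    manifest_rows = []
    for name, frame in cohort.modalities.items():
        path = directory / f"{name}.tsv"
        out = frame.copy()
        float_format = "%.17g"  # lossless float round trip
        if name in cohort.genotype_modalities:
            # keep integer tokens for genotype calls
            out = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
            float_format = None
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA", float_format=float_format)
        written.append(path)
        manifest_rows.append(
            {
                "modality": name,
                "file": path.name,
                "genotype": int(name in cohort.genotype_modalities),
            }
        )
    manifest_path = directory / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    written.append(manifest_path)
    return written


class CohortFormatError(ValueError):
    """A cohort file violates the expected dialect."""


def _validate_genotype_frame(frame: pd.DataFrame, path: str) -> pd.DataFrame:
    values = frame.to_numpy(float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise CohortFormatError(
            f"{path}: invalid genotype token {values[r, c]!r} at row "
            f"{frame.index[r]!r}, column {frame.columns[c]!r} "
            "(expected 0, 1, 2 or NA)"
        )
    return frame


def read_cohort(directory: str | Path) -> LabeledCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    labels = pd.read_csv(directory / "labels.tsv", sep="\t")
    sample_ids = [str(s) for s in labels["sample_id"]]
    modalities: dict[str, pd.DataFrame] = {}
    genotype_modalities: set[str] = set()
    for row in manifest.itertuples():
        path = directory / row.file
        frame = pd.read_csv(
            path, sep="\t", index_col="sample_id", na_values=["NA"],
            float_precision="round_trip",
        )
        frame.index = frame.index.map(str)
        if list(frame.index) != sample_ids:
            raise CohortFormatError(
                f"{path}: sample IDs do not match labels.tsv"
            )
        if row.genotype:
            try:
                frame = frame.astype(float)
            except (TypeError, ValueError) as exc:
                raise CohortFormatError(
                    f"{path}: non-numeric genotype token ({exc})"
                ) from exc
            _validate_genotype_frame(frame, str(path))
            genotype_modalities.add(row.modality)
        modalities[row.modality] = frame
    return LabeledCohort(
        sample_ids=sample_ids,
        labels=labels["label"].to_numpy(int),
        modalities=modalities,
        genotype_modalities=genotype_modalities,
    )


def read_plink_raw(path: str | Path, modality: str = "snp") -> LabeledCohort:
    """Read an additive-coded PLINK ``.raw``-style genotype table.

    Expects the standard header ``FID IID PAT MAT SEX PHENOTYPE`` followed
    by one column per variant, whitespace-delimited, genotypes coded
    0/1/2 with ``NA`` for missing. PHENOTYPE is mapped to binary labels
    (PLINK case/control coding 2/1 becomes 1/0; 0/1 coding is passed
    through).
    """
    path = Path(path)
    table = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    missing_cols = [c for c in _PLINK_META_COLS if c not in table.columns]
    if missing_cols:
        raise CohortFormatError(
            f"{path}: missing required .raw columns {missing_cols}"
        )
    snp_cols = [c for c in table.columns if c not in _PLINK_META_COLS]
    sample_ids = [str(s) for s in table["IID"]]
    pheno = table["PHENOTYPE"].to_numpy(float)
    observed = set(np.unique(pheno[~np.isnan(pheno)]))
    if observed <= {0.0, 1.0}:
        labels = pheno.astype(int)
    elif observed <= {1.0, 2.0}:
        labels = (pheno - 1).astype(int)
    else:
        raise CohortFormatError(
            f"{path}: PHENOTYPE values {sorted(observed)} are not a "
            "recognised case/control coding (expected 1/2 or 0/1)"
        )
    geno = table[snp_cols].astype(float)
    geno.index = pd.Index(sample_ids)
    _validate_genotype_frame(geno, str(path))
    return LabeledCohort(
        sample_ids=sample_ids,
        labels=labels,
        modalities={modality: geno},
        genotype_modalities={modality},
    )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["maf_range"] = list(d["maf_range"])
    return d
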