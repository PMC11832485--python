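# Methods

## The problem setting

The toolkit targets two-class (case/control) prediction from two
heterogeneous feature blocks measured on the same participants: an
additive-coded genotype matrix (entries 0/1/2 with missing calls) and a
continuous MRI-morphometry matrix (regional volumes and surface
measures). The defining difficulties are `p ≫ n` (thousands of features,
~167 samples), class imbalance (roughly 2:1 cases to controls), and the
need for *stable* feature selection: a locus or brain region is only a
credible marker if it is selected consistently across resampled
training sets, not just once.

## Synthetic cohort generator

`pdfuse.simulate` draws cohorts with the statistical shape of such a
study so every downstream stage can be tested against known truth.

- **Genotypes.** Per locus, an allele frequency `p_f` is drawn uniformly
  from `maf_range` (default 0.05–0.5) and genotypes are Binomial(2,
  p_f). At causal loci, cases use `p_f + snp_effect`; the shift directly
  controls per-locus discriminability while keeping the marginal MAF
  interpretable (a liability-threshold model would entangle the two).
  Configurations whose shifted frequencies leave (0, 1) are rejected.
- **Morphometry.** Features form blocks of `mri_block_size` (default 10)
  with compound-symmetry correlation `mri_block_rho` (default 0.3),
  emulating the within-ROI-family correlation of regional measures.
  Informative features get a mean shift of `mri_effect` SD units
  (Cohen's d) in cases.
- **Missingness.** Genotype calls are deleted completely at random at
  `missing_rate` (default 2%). MCAR suffices because the call-rate
  filter does not depend on informative missingness.
- **Defaults** are desk-scale study conditions: 113 cases / 54 controls,
  2,000 SNPs with 10 causal at shift 0.25, 300 morphometry features
  with 8 informative at d = 0.8. This preserves the `p ≫ n` regime
  while keeping a full repeated-split experiment in CPU-minutes; all
  sizes are configurable up to realistic chip scale.

What the generator does **not** emulate: linkage disequilibrium beyond
block correlation, relatedness/population structure, genotyping batch
effects, and site/scanner effects in morphometry. Passing tests
therefore demonstrate correctness of the machinery and calibration
under the stated generative model, not performance on real cohort data.

## Genotype quality control

Per-locus filters with the standard chip-protocol thresholds: minor
allele frequency < 1%, call rate < 95%, Hardy-Weinberg exact-test
p < 1e-6. Failure is strict (`<`), so a locus exactly at a threshold
passes. MAF and HWE use non-missing calls only. The HWE test is the
exact conditional test — all heterozygote counts compatible with the
observed allele counts are enumerated via a numerically stable
recurrence and the probabilities of configurations no more likely than
the observed one are summed — rather than the chi-square approximation,
both because the chip protocols this mirrors use the exact test and
because exactness admits an independent enumeration oracle in the test
suite. By default HWE is tested on all samples; a controls-only switch
is provided since disease association itself can distort HWE in cases.

Standardization (z-scoring) is always fitted on the training split and
reused on validation/test; training-mean imputation fills missing
genotype calls so penalized fits and distance-based oversampling are
defined. Zero-variance features map to 0.

## Stability selection cascade

Stage 1 — **Fisher filter.** The two-class Fisher criterion
`Σ_c n_c (μ_cf − μ_f)² / Σ_c n_c σ²_cf` ranks features; the top 5%
(configurable, count or fraction) survive. Ties break toward the
lexicographically smaller name, everywhere, for determinism.

Stage 2 — **Ensemble lasso.** M = R·K perturbation subsets are the
training complements of R repeated stratified K-fold partitions (at
K = 10, each subset holds 90% of samples). Each subset is optionally
balanced by SVM-SMOTE: an SVM identifies boundary (support-vector)
minority samples and synthetic points are convex combinations of a
minority support vector and one of its minority nearest neighbors;
originals are preserved verbatim and the output is deterministic given
the seed. An L1-regularized logistic model is fitted per subset with
its penalty chosen by the subset's own small internal CV over a
three-point grid. Weights are normalized within each subset by the
subset's maximum |coefficient| so that `FSw ∈ [0, 1]` is commensurate
with `FSq` in `IS = (FSq + FSw)/2`. The package default is R = 10
(M = 100); the shipped benchmark protocol uses R = 2 (M = 20), which we
found sufficient for stable rankings at these problem sizes while
keeping a ten-repeat experiment within minutes.

Stage 3 — **Forward search.** For each k in an ascending grid, a probe
classifier (L2 logistic regression) is trained on the top-k features by
IS and scored on the validation split; the smallest k attaining the
best validation balanced accuracy wins.

Stage 4 — **PLS.** Partial least squares (NIPALS, via scikit-learn)
projects the selected features onto components maximizing label
covariance; the component count is chosen by validation balanced
accuracy over 1..15 (capped by the selected-feature count). The fitted
projection is linear and reused unchanged on held-out data.

## Sparse group lasso

For feature-level fusion with modality structure, the subset-level
learner can be the sparse group lasso,
`½‖y − Xβ‖² + λ₁ Σ_l ‖β_l‖₂ + λ₂ ‖β‖₁`, with labels coded ±1 (the
squared loss needs a fixed coding; ±1 makes the null prediction 0).
The solver is block-coordinate proximal descent: per group, a screening
condition (`‖S(X_lᵀ r_l, λ₂)‖₂ ≤ λ₁`) decides whether the group is
exactly zero; otherwise accelerated proximal-gradient steps alternate
elementwise soft-thresholding (λ₂) with group soft-thresholding (λ₁).
Outer sweeps stop when the objective decreases by less than `tol`
(default 1e-8); non-convergence within `max_iter` returns the best
iterate with a warning flag. Default grouping is one group per
modality; any finer partition can be supplied.

## Adaptive stacking

Decision-level fusion trains a pool of candidate (classifier, modality)
base learners under stratified K-fold cross-validation (K = 10 in the
pipeline arm, matching the tenfold resampling used elsewhere in the
protocol), collects out-of-fold class probabilities and per-fold
balanced accuracies, keeps the learners whose mean fold Bacc strictly
exceeds the grand mean over the pool (single-best fallback when none
do), weights each selected learner by `λᵢ = −(1/M)/(1 − 1/μᵢ²)` with
`μᵢ` clipped into [1e-3, 1−1e-3] to avoid the singularity at perfect
folds, and fits a logistic-regression meta-learner on the weighted
out-of-fold probability columns. At test time each learner's K fold
models predict, their outputs are averaged with fold-Bacc-proportional
weights (a simple-mean switch exists), scaled by λᵢ, and passed to the
meta-learner.

Two design points deserve emphasis:

- **The per-modality front end is refit inside every stacking fold.**
  The selection cascade is supervised; fitting it once on the full
  training split and then cross-validating base learners on the reduced
  features leaks labels into the fold balanced accuracies. In our
  diagnostics this inflated the high-dimensional (SNP) modality's
  apparent fold accuracy to ~1.0 while its honest test accuracy was
  ~0.7, steering the selection rule toward the wrong modality. Treating
  the front end as part of each base learner — refit on the fold's
  training part, with the repeat's validation split (disjoint from all
  stacking training data) driving the forward search and component
  choice — keeps the selection statistic unbiased.
- **The meta-learner is class-balanced.** With a 2:1 class ratio,
  probability columns are shifted toward the majority class and a plain
  0.5 threshold sacrifices balanced accuracy even when the ranking is
  perfect (we observed repeats with AUC = 1.0 but Bacc = 0.8). Balanced
  class weights in the logistic meta-learner restore threshold
  calibration without any tuning.

An alternative literal reading of the weight definition (pooling fold
accuracies across learners, which makes all weights identical) is
available behind the `literal_mu` flag; the default per-learner reading
is the one consistent with weighting stronger learners more.

## Evaluation protocol

Repeated stratified 8:1:1 train/validation/test splits (nearest-integer
val/test sizes, remainder to train: 167 → 133/17/17), ten repeats by
default, all derived deterministically from one master seed via
`numpy` seed sequences. Hyperparameter tuning, where used, is an
exhaustive grid search by inner 5-fold CV balanced accuracy on training
data only, tie-broken by grid order. Metrics per repeat: sensitivity,
specificity, balanced accuracy, G-mean, F1 and rank-statistic AUC
(midranks on ties); aggregation is mean ± sample SD (ddof = 1). Model
comparison is the paired Wilcoxon signed-rank across shared splits
(exact null for n ≤ 25; all-zero differences give p = 1), with an
unpaired Mann-Whitney option. Feature stability averages per-repeat
importance scores (absent features count 0), ranks descending, and
reports per-modality top-k lists (defaults 10 morphometry / 30 loci)
and their pairwise/three-way intersections across methods.

## Numerical and degenerate-input choices

- All ranking ties break lexicographically by feature name; forward
  search ties break toward smaller k; grid-search ties toward earlier
  grid points.
- Constant features standardize to 0; all-missing genotype columns are
  rejected in MAF computation and counted as call-rate failures in QC.
- SVM-SMOTE with a minority class below two samples falls back to
  duplication with a logged warning; degenerate single-class
  perturbation subsets are redrawn with a warning.
- Monomorphic loci have HWE p = 1 (single attainable configuration).
- The Eq.-style ensemble weight is clipped at μ = 1−1e-3; fold-Bacc
  test weights fall back to a simple mean when all fold accuracies are
  zero.

## Benchmark problem sizes

The shipped benchmark routines (`pdfuse.benchmarks`, used by the test
suite and `scripts/acceptance.py`) run the exact default study
conditions — 2,000 SNPs / 10 causal at shift 0.25, 300 morphometry
features / 8 informative at d = 0.8, 113/54 samples — with the
desk-scale ensemble (R = 2, M = 20) and a four-classifier stacking pool
(LR, SVM, RF, XGBoost), sizes chosen so a complete run finishes in
CPU-minutes. Observed behavior at these sizes: ~95% of planted features
recovered in the per-modality top-50 importance ranking; null cohorts
score within binomial noise of Bacc 0.5; bimodal stacking exceeds the
best single-modality arm on shared splits.

## Known limitations

- The generator's independence assumptions (no LD, no relatedness, no
  batch effects) make recovery easier than on real chip/scanner data.
- PLS components are dense linear mixtures; interpretation runs through
  the stability ranking of the input features, not the components.
- The sparse group lasso solver targets the tens-to-hundreds-of-features
  regime after Fisher filtering; it has no screening rules for
  genome-scale direct fits.
- Sample-level genotype QC (sex checks, relatedness, population
  stratification) requires chip-level data and is out of scope; the
  locus filters assume it has already happened.
- Stacking is two layers only, and probability calibration beyond the
  class-balanced meta-learner is not attempted.
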