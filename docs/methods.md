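# Methods

## The heterogeneity score

MIRV treats each lesion at baseline as a point in radiomic feature space
and scores a patient by the spread of their lesions. After feature
reduction and cohort-wide z-scoring, all n(n−1)/2 unordered lesion pairs of
a patient contribute a Euclidean distance and a cosine dissimilarity
(1 − cosine similarity, range [0, 2]); the per-patient score aggregates
them with max (primary), mean, median or sample SD. The two families are
complementary: cosine dissimilarity responds to differences in feature
*composition* regardless of magnitude, Euclidean distance to overall
divergence. Self-pairs are excluded everywhere: they contribute 0 and can
never be the maximum, but they would bias the mean, median and SD.

Patients with fewer than two baseline lesions are excluded and reported —
a pairwise statistic is undefined for them. Scores are only comparable
within one cohort-and-feature-set: the z-scoring and the reduction are
cohort-level operations.

### z-scoring

z-scoring is cohort-wide (pooled over all patients' baseline lesions) with
sample SD (ddof = 1). Per-patient standardization is available
(`scope="per_patient"`) but degenerate for 2-lesion patients, which is why
it is not the default. A constant feature is a hard error: it cannot be
z-scored and should have been removed by the variance filter.

## Feature reduction

Three stages, strictly in this order, computed on the pooled baseline
lesion table with raw (un-normalized) feature values:

1. **Variance.** Features with sample variance strictly below the median
   variance of all input features are dropped; ties at the median are
   kept (the conservative reading of "below the median").
2. **Volume de-correlation.** Features with |Spearman ρ| > 0.1 against
   per-lesion voxel volume (mm³, pooled over patients) are dropped, so the
   final score cannot be a tumor-size surrogate. A constant volume vector
   is an error (degenerate ranks).
3. **Redundancy.** Greedy scan in variance-descending order (feature name
   ascending as tie-break): a feature is dropped when |Spearman ρ| > 0.7
   with any already-kept feature; the kept set therefore has all pairwise
   |ρ| ≤ 0.7. Which member of a redundant pair survives is a genuine
   convention choice; keeping the higher-variance member is the default
   and `redundancy_order="name_asc"` is available. The dropped partner and
   ρ are recorded.

All Spearman correlations use average ranks for ties. The
`ReductionReport` partitions the input feature set (kept + three dropped
lists, disjoint) and records every threshold used. An empty kept set after
any stage is an explicit stage-named error, which small or
heavily-confounded inputs can legitimately trigger.

One practical caveat: with clustered data (lesions nested in patients) the
null distribution of a pooled Spearman ρ is wider than 1/√(n−1), so the
|ρ| > 0.1 volume filter removes a non-trivial fraction of genuinely
volume-independent features in small cohorts. This mirrors its behavior on
real feature tables and is why reduction should run on the full cohort,
not a subset.

## Response metrics

Per lesion, ΔV = 100·(V_followup − V_baseline)/V_baseline (percent), with
lesions matched across timepoints by (patient, lesion) identifier —
unmatched baseline lesions are an itemized error, and the identifier-match
assumption is the package's lesion-tracking model. Per patient, the
volumetric response range is max ΔV − min ΔV (0 for a single lesion).

TSRC is the binary Complete-Tumor-Response label at a 33 % threshold. The
clinical wording is genuinely ambiguous between "all lesions shrank by
more than a third" and "no lesion changed by more than a third", so the
direction is an explicit enum rather than a silent guess:

* `reduction_all` (default): TSRC = 1 iff every ΔV ≤ −33 %;
* `no_growth_all`: TSRC = 1 iff every ΔV ≤ +33 %.

The boundary is inclusive on the response side in both conventions. ctDNA
positivity is consumed as given binary labels; the assay thresholding is
upstream of this package.

## Association analyses

**Correlation panels.** Spearman ρ with two-sided p-values between
patient-level variables, pairwise-complete deletion, and
Benjamini–Hochberg FDR applied once per panel (one family for the
volumetric-response panel, one for the ctDNA panel) — pairs with a
constant variable or < 3 complete observations are flagged undefined and
excluded from the family. Baseline volume controls (total, range, sample
SD of lesion volumes) are included so volume dependence of any score is
visible rather than hidden.

**Cross-validated logistic models.** Outer stratified 5-fold CV; within
each training fold a pipeline of standardization (training-fold statistics
only) and L2-regularized logistic regression (lbfgs, max_iter 1000) is
tuned over C ∈ 10⁻³…10³ by mean held-out AUC on an inner stratified 3-fold
split. Reported: per-fold AUC, mean ± sample SD, best C per fold, and the
mean ROC curve obtained by linearly interpolating each fold's TPR onto a
common 101-point FPR grid with endpoints pinned at (0,0) and (1,1).
Categorical covariates enter ordinally through an explicit mapping in the
config. Fold assignment is deterministic given the seed.

**AUC comparison.** Nested models on the same folds are compared with a
paired Z-statistic on per-fold AUC differences, z = d̄/(s_d/√k), two-sided
normal p. With k = 5 this is approximate and *anticonservative*: the
statistic is really t with 4 df, so the true size at nominal 0.05 is
≈ 0.12. This is acceptable for its role — a coarse check whether a nested
improvement is clearly beyond fold noise — and is verified by Monte Carlo
in the test suite. All-zero differences return z = 0, p = 1; a nonzero
constant difference (s_d = 0) is reported as p = 0 with a degeneracy flag.
DeLong-style variance estimation is deliberately out of scope.

## Survival analyses

Multivariable Cox proportional hazards (lifelines, Efron tie handling)
with the continuous heterogeneity score alongside age ≥ 65, performance
status, ordinal histology, RECIST category and total baseline volume;
score × histology interaction columns are indicator products against the
first (reference) level. Guards: no events, and parameters ≥ events, are
errors; non-convergence surfaces with diagnostics. Each MIRV metric is fit
in its own model by default.

Subgroup analysis splits each histology level at the within-subgroup
median of the score (configurable to a fixed cut), compares strata with a
two-sample log-rank test, and applies BH FDR across the subgroups actually
tested; a subgroup whose split leaves a stratum with < 2 members is
skipped with a logged reason. Kaplan–Meier curves with 95 % bands are
exported per stratum.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
real CT images:

* **Archetype mixture.** Each patient has a primary lesion archetype;
  every lesion after the first draws a non-primary archetype with
  probability `heterogeneity_mix`. Lesion vectors are centroid (coordinates
  ~ N(0, 3²)) plus isotropic N(0, noise_sd²) noise. True heterogeneity —
  the fraction of non-primary lesions — is recorded as ground truth. A
  mixture was chosen because MIRV is a pairwise-distance statistic:
  mixtures give directly controllable intertumor divergence.
* **Volumes** are log-normal (median ≈ 3 cm³, σ_log = 0.8) — positive and
  right-skewed like real tumor volumes. The first `n_volume_confounded`
  features add `volume_beta` × standardized log-volume, giving the volume
  filter true positives.
* **Response.** Per-lesion ΔV ~ N(μ_archetype, 10²) with archetype means
  (−50, +20, −10) %, so mixed-archetype patients show wider response
  ranges; follow-up volume is baseline scaled by 1 + ΔV/100 (floored at
  −99 %).
* **ctDNA** post-treatment positivity is Bernoulli with a logistic link on
  standardized true heterogeneity (slope 1.5) and log total volume
  (slope 0.8).
* **Survival** is exponential with hazard 0.35·exp(0.7·z(heterogeneity))
  per year, censored uniformly on [0, 6] years (≈ 58 % events).

Defaults (200 patients, 2–8 lesions, 40 features, 3 archetypes, mix 0.5)
are the shipped study conditions; `examples/synthetic_config.yaml` documents
every knob. All randomness flows from one seeded generator — same seed,
bit-identical cohort.

What the generator does **not** emulate: realistic radiomic covariance
structure (real feature sets are far more collinear and non-Gaussian),
scanner/protocol batch effects, lesion segmentation error, informative
censoring, or any image-level physics. Passing tests therefore demonstrate
correctness of the computations and sensible behavior under the assumed
structure, not clinical validity on real cohorts.

With three archetypes the generated feature table has an effective signal
rank of 3, so the redundancy filter typically keeps only a handful of
features; this is expected and mirrors how aggressively |ρ| ≤ 0.7 prunes
collinear radiomic panels.

## Numerical and design choices

* Cosine dissimilarities are clipped to [0, 2] to absorb floating-point
  overshoot; zero-norm lesion vectors are an identified error.
* Sample SD (ddof = 1) everywhere an SD is reported.
* Result CSVs are written with a fixed `%.10g` float format and `\n` line
  endings, making re-runs byte-identical under a fixed seed.
* Ordinal encodings (RECIST CR < PR < SD < PD; histology sorted
  alphabetically unless overridden) live in the run config and are echoed
  to the run log together with every threshold, the package version, the
  config hash and the seed.
* Problem sizes used by the test suite and acceptance script — 200
  oracle patients, 50 random reduction matrices, two groups of 100
  patients for discrimination, 50 permutation-null CV repeats at n = 200,
  100 Cox replicates at n = 400 — were chosen to give stable Monte-Carlo
  estimates at interactive runtimes.

## Known limitations

* Lesion matching across timepoints is by identifier only; no spatial
  matching is attempted.
* The paired AUC Z-test's anticonservatism at k = 5 (above).
* No imputation: missing feature cells are a hard, itemized load error.
* Proportional-hazards diagnostics are limited to lifelines'
  `check_assumptions` being reachable on the fitted model; no automated
  Schoenfeld screening is run by the pipeline.
* RECIST categories, ctDNA labels and performance status are consumed as
  given; the package computes none of them.
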