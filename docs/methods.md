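# Methods

This note documents the models and conventions behind `ihctyper`: what each
stage computes, the defaults and why, what the synthetic cohorts emulate,
and where the design was genuinely open.

## Data model

A cohort is a samples × markers matrix of IHC scores — the percentage of
tumor cells stained for one antibody, an integer in [0, 100] — with a
missing cell meaning the antibody was never applied to that sample. A score
of 0 (no stained cells) is valid data, distinct from missing. Each sample
carries a patient id (patients may contribute several samples, e.g. a
diagnostic biopsy and the later resection specimen), an anatomy-based
diagnosis, and a probe type. Intensity weighting (relevant only for p53,
where weak staining is conventionally not counted) is assumed to have been
applied upstream at scoring time; the pipeline treats all scores uniformly.

Positivity is `score > 10` (strictly), i.e. immunoreactivity in more than
10% of tumor cells; a missing score propagates as `unknown`.

## Pre-processing

Pruning runs in a fixed order: first markers whose missing fraction
(over all samples) is strictly above 0.40, then — on the reduced matrix —
samples whose missing fraction is strictly above 0.50. The order matters: a
sample is often rescued by the removal of antibodies that were never
ordered for it. The pass is deliberately not iterated; note that removing
samples can in principle push a retained marker back over its threshold, so
a second pass is not always a no-op (the tests exercise this edge).

kNN imputation operates over *samples*, not markers: with only a few dozen
antibodies, marker-space neighborhoods are unstable, while several hundred
tumors give each gap a meaningful donor pool. The distance between two
samples is the Euclidean distance over their co-observed markers divided by
the number of co-observed markers (without the normalization, samples
sharing few markers look systematically closer or farther). For a missing
cell the k = 10 nearest donors with that marker observed contribute an
inverse-distance-weighted mean, clipped to [0, 100]; a zero-distance donor
is copied exactly, and the marker's observed mean is the fallback when no
donor exists. k and the distance are exposed as parameters since neither is
canonical.

Confounder checks are PCA-based: the first two principal components of
either the score matrix (probe-type check) or the 0/1 analyzed-marker mask
(panel-choice check), summarized by the mean silhouette of the grouping;
silhouette < 0.1 is declared an admixture, i.e. no evidence of confounding.

## Clustering and type assignment

Samples are clustered with the Pearson distance d(i,j) = 1 − r(x_i, x_j)
(zero-variance vectors get r = 0, hence d = 1, with a logged warning) and
unweighted average linkage. The linkage is implemented directly — cluster
distance is the unweighted mean of all cross-pair distances, updated via
Lance–Williams, with ties broken by the smallest cluster-id pair — so that
its behavior is fully specified; the test suite verifies exact agreement
with both a brute-force O(n³) re-computation and SciPy's implementation.

Cutting the tree at k removes the k−1 highest merges. Selecting k and
naming clusters replaces what is, in practice, an expert's visual pruning
of the dendrogram with an explicit surrogate:

1. scan k = 2 … 12 and pick the smallest cut at which (a) at least 90% of
   the control-group samples (hepatocellular carcinoma, whose profile is
   well characterized) sit in clusters of ≥ 90% control purity **and**
   (b) the cut contains at least four clusters of ≥ 5 samples. Condition
   (b) was added because the control group frequently isolates already at
   k = 2, long before the remaining types have separated; without it the
   rule selects degenerate cuts.
2. name each cluster: size < 5 → `unclassified` (outliers); CK20 or MUC2
   positive fraction > 0.5 → INT (the intestinal type is not inferable
   from anatomy); otherwise by dominant diagnosis (hcc → HCC,
   intrahepatic_cc → ICC, the pancreatic/extrahepatic sites → EPB).

A manual-labels override mirrors expert review. All thresholds (k_max,
purity, capture, minimum size) are parameters.

## Discriminant-marker testing

Three permutation tests are computed per marker and type pair, sharing one
permutation engine: when the number of distinct group assignments C(n, n_A)
is at most 20 000 the null is enumerated exhaustively and p-values are
exact; otherwise assignments are sampled and the add-one estimate
(b+1)/(B+1) is reported.

* **Rank product.** For every cross-group sample pair, markers are ranked
  by the score *difference* (mid-ranks for ties) — differences, not
  ratios, because IHC percentages contain zeros. RP_up is the geometric
  mean of descending ranks over all pairs, RP_down of ascending ranks.
  The reported statistic is min(RP_up, RP_down), whose permutation p is
  two-sided by construction; one-sided p_up/p_down are also reported.
  Benjamini–Hochberg adjustment across markers.
* **SAM-style moderated difference.** d = (x̄_A − x̄_B)/(s + s₀) with s the
  pooled standard error and the stabilizer s₀ fixed at the median of the
  per-marker standard errors, computed once on the observed grouping and
  held fixed across permutations. (The original percentile search that
  minimizes the coefficient of variation of d is out of scope; the s₀
  argument is the hook.) Two-sided permutation p on |d|, BH adjustment.
* **maxT.** Welch t per marker with Westfall–Young step-down adjustment:
  markers ordered by decreasing |t|; the adjusted p of the j-th marker is
  the exceedance rate of the successive maximum of permuted |t| over
  markers ranked j and below, with monotonicity enforced. This controls
  the family-wise error rate, so no further adjustment applies.

A note on calibration: with 3-versus-3 groups the exhaustive null has 20
assignments that pair up under group swap, so any two-sided p is bounded
below by 0.10; exact 5%-level size can only be demonstrated on the
one-sided p-values (granularity 1/20), which is what the calibration tests
measure. Two-sided p-values are separately verified to be valid
(P(p ≤ α) ≤ α up to Monte-Carlo error).

The consensus rule declares a marker truly significant for a pair only when
all three methods reach p ≤ α = 0.05 on their own adjusted values *and*
agree in direction — a deliberate guard against false positives. The
pairwise comparisons run by default for the clinically most relevant
differential diagnoses: EPB vs INT, EPB vs ICC, ICC vs HCC.

## Consensus co-clustering network

Rather than trusting one completion of the missing data, each iteration
draws every missing cell fresh from the marker's empirical distribution of
observed scores (a uniform [0, 100] mode exists as an option), clusters the
completed matrix (Pearson + average linkage, cut at the main analysis's k),
and records which sample pairs co-cluster. The mean indicator over
iterations is the co-membership matrix; 200 iterations suffice for testing
while 15 000 is the documented production default (the estimate is stable
well before that — doubling from 2000 to 4000 iterations moves no entry by
more than 0.05 in the convergence test). Thresholding at 0.5 yields a
weighted undirected sample graph with type/diagnosis/probe/score attributes
per node, exported as GEXF, GraphML, or an edge list; layout is left to
external viewers.

With no missing data every iteration is identical, so the matrix is exactly
{0, 1} and equals a single deterministic run — a useful degeneration check.

## Diagnostic panel

The 8-marker × 4-type grid uses four expectation categories ordered by
positivity frequency: `+`, `+/-`, `-/+`, `-`. The printed grid defines no
numeric cutoffs; this package attaches left-closed bands on the positive
fraction — `+` at ≥ 0.75, `+/-` at [0.50, 0.75), `-/+` at [0.25, 0.50),
`-` below 0.25 — chosen so that verbal usages like "expressed in
approximately 70% of intestinal tumors" land in the intended category. The
`+/-` vs `-/+` distinction is read as mostly-positive vs
occasionally-positive. Panels can be derived from any cohort's positivity
profiles (cells without observed scores become `NA` with a warning) and are
serialized as JSON with their band edges and weights.

Single-sample classification sums match weights over observed panel
markers: ±1 for the confident categories, ±0.5 for the intermediate ones,
0 for missing; the label is the argmax type unless the margin over the
runner-up falls below 0.5 (then `indeterminate`). The weight scheme mirrors
the certainty ordering of the categories and is pluggable. Its accuracy is
intrinsically bounded: with only eight markers and overlapping archetypes,
even the Bayes-optimal rule on the same information misclassifies a
substantial minority of EPB/INT samples — the acceptance script reports the
achieved per-type accuracies rather than asserting an idealized figure.

## Internal validation

The pairwise tasks are re-learned under stratified 10-fold cross-validation
(every sample tested exactly once; pooled out-of-fold predictions yield the
metrics) by four ecosystem-neutral classifier families standing in for the
classic toolbox quartet: Gaussian naive Bayes, L2-regularized logistic
regression, a linear max-margin classifier, and a single
randomized-splitter decision tree. Metrics: TPR, FPR, precision, recall,
F-measure (macro-averaged over the two classes) and ROC area from pooled
decision scores. The full grid is 3 pairs × 4 families × 2 feature sets
(all markers vs the pair's consensus markers) = 24 rows; stability of ROC
area across the two feature sets is the stage's substantive claim.

## Survival analysis

Conventions, in one place: analysis is restricted to resected patients, one
record per patient (when a patient has several samples the resection
specimen's type label wins, else the earliest biopsy); `pTis` and `pNX`
records are excluded from model fits; pN1 and pN2 are merged; age is
dichotomized at the cohort median. Kaplan–Meier medians follow the
product-limit step convention — the first time with S(t) ≤ 0.5 — and groups
whose median is never reached report the restricted mean over follow-up,
flagged. Cox models use Efron tie handling, dummy coding against fixed
baselines (type EPB, anatomy ductal pancreatic, pT3, pN1/2), Wald 95%
intervals and p-values per level, and a likelihood-ratio global p; adjusted
models append pT + pN. Non-convergence raises in direct fits; inside the
prognostic table a failed block is reported as NaN with a warning rather
than aborting the whole report.

The proportional-hazards check is the scaled Schoenfeld-residual
correlation test with the rank time transform (ranks of the event times;
mid-ranks for ties): per covariate, χ² = (Σ z_k s*_kj)² / (d·V_jj·Σ z_k²),
and globally χ² = u'V⁻¹u / (d·Σ z_k²) on p degrees of freedom, where s* are
the scaled residuals, z the centered transform, V the coefficient
covariance and d the event count. For a single covariate the global and
per-covariate tests coincide; per-covariate values agree with the
established implementation to numerical precision on tie-free data.

## The synthetic cohorts

The generator's job is to produce data with the statistical structure the
analysis assumes, at the study's scale.

* **Archetypes.** Positivity probabilities for the 8 panel markers derive
  from the panel categories via the fixed map `+` → 0.90, `+/-` → 0.60,
  `-/+` → 0.30, `-` → 0.05 — separable yet overlapping, as real types are.
  Nineteen further discriminant markers bring the default set to 27, the
  number of analyzed antibodies; their per-type probabilities encode the
  archetypes' published qualitative profiles (e.g. CK7 in ~70% and CK17 in
  ~25% of intestinal tumors; vimentin/WT1 in ICC; a near-null epithelial
  profile in HCC).
* **Scores.** Per sample and marker, a Bernoulli draw at the profile
  probability selects the positive or negative component; scores are
  truncated-normal draws — positive (70, 20) on (10, 100], negative (2, 3)
  on [0, 10] — rounded to integers. The components are free parameters;
  the defaults give the characteristic bimodal IHC histogram.
* **Missingness.** `cell_mcar` masks cells independently; the default
  `marker_block` mechanism masks whole marker blocks per sample,
  emulating panel-driven missingness in a retrospective diagnostic series.
  Per-sample rates can be made heterogeneous (Beta-distributed) so that
  scant biopsies lose most of their panel. `raw_study_spec()` combines
  both with 11 rarely-ordered exclusion work-up antibodies (TTF1, napsin
  A, GATA3, PAX8, ER, PR, S100, synaptophysin, CK14, CK903, HepPar1 —
  each analyzed on ~18% of samples) into a 439 × 38 raw-dataset emulation:
  roughly 36% overall missingness of which the pruning rule removes the 11
  work-up markers and the scant samples, leaving ~15% before imputation.
* **Survival.** Exponential proportional-hazards times:
  log-hazard = baseline + type effect + pT effect + pN effect, with
  independent exponential censoring whose per-patient rate yields the
  requested censoring probability exactly. Defaults: type hazard ratios
  0.19 (INT), 0.61 (ICC), 0.50 (HCC, a free parameter — the control group
  has no reference value) against EPB; pT and pN effects at their reported
  crude magnitudes; baseline hazard log 2 / 15.7 per month, calibrated so
  the *marginal* EPB median (after mixing over the pT/pN distribution) is
  about 24 months. Because hazard ratios are non-collapsible, the planted
  type effect is recovered by the adjusted (type + pT + pN) model, not the
  crude one.

**What the generator does not emulate — and therefore what passing tests do
not show.** Marker scores are conditionally independent given the type:
real tumors co-regulate markers through differentiation state, which makes
real clusters tighter than synthetic ones. There is no pathologist
inter-observer noise, no spatial staining heterogeneity, no batch effects
across staining years, and anatomy is drawn from fixed per-type mixtures
rather than driving expression. Consequently, results on synthetic cohorts
bound what the *pipeline* does under known conditions; they do not certify
performance on real tissue data.

## Known limitations

* Under the default archetype overlap, unsupervised recovery of the
  EPB/INT boundary is intrinsically hard: an oracle-named cut of the
  average-linkage tree plateaus near ARI 0.7 on the 40-per-type cohort,
  and the shipped surrogate averages lower. Supervised classifiers
  separate the same pair substantially better — which is precisely why the
  typing is validated with supervised models rather than by clustering
  alone.
* The 8-marker panel classifier is information-limited (see above); use
  the extended marker set when scores are available.
* `derive_panel` is only as good as the positivity profiles' denominators;
  small types yield unstable categories near band edges.
* The network stage cuts every iteration at one global k; truly nested or
  overlapping structure is summarized only through the co-membership
  weights.
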