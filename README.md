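# ihctyper

Integrative immunohistochemical (IHC) typing of adenocarcinomas of the
pancreatobiliary system — a tested, reusable pipeline from raw marker-score
matrices with missing values to tumor-type assignments, discriminant-marker
panels, consensus co-clustering networks, diagnostic-panel classification,
internal validation, and survival stratification.

## The problem

Pancreatobiliary adenocarcinomas (ampullary, ductal pancreatic, distal bile
duct, gallbladder, perihilar and intrahepatic cholangiocarcinoma) are
classified by anatomical site, yet their marker-expression profiles cut
across anatomy. Clustering tumor samples by their IHC scores — the
percentage of stained tumor cells per antibody, 0–100 — reveals a small
number of *immunohistochemical tumor types* with distinct prognosis:

* **EPB** — extrahepatic pancreatobiliary (CK7/CK17/CK19, MUC1/MUC5AC,
  CA19-9, mCEA, CA125, maspin); poorest prognosis.
* **INT** — intestinal (CK20/MUC2/CDX2 with partial pancreatobiliary
  co-expression); markedly better prognosis.
* **ICC** — intrahepatic cholangiocarcinoma (generic adenocarcinoma markers
  plus vimentin and WT1).
* **HCC** — hepatocellular carcinoma, an internal control group with a
  well-known profile.

This package is aimed at biostatisticians and computational pathologists who
want to run, test, or extend that analysis. Because diagnostic IHC tables
are rarely shareable, a first-class synthetic-cohort generator emulates the
study conditions (four archetype profiles, discrete 0–100 scores,
panel-driven block missingness, type-dependent survival), so every stage is
testable without any download.

## Methods at a glance

* **Pre-processing** — markers with >40% missing values, then samples with
  >50%, are pruned; remaining gaps are filled by k-nearest-neighbor
  imputation over samples (normalized Euclidean distance on co-observed
  markers, inverse-distance-weighted donor mean). PCA checks that probe
  type (biopsy vs resection) and marker-panel choice are not confounders.
* **Clustering** — Pearson distance d(i,j) = 1 − r(x_i, x_j) with
  unweighted average linkage (UPGMA); the cut k is chosen by a
  control-group rule (the smallest cut isolating HCC into high-purity
  clusters) and clusters are named by dominant diagnosis plus a CK20/MUC2
  positivity rule; small clusters stay `unclassified`.
* **Discriminant markers** — three permutation tests per marker (rank
  product on score differences; SAM-style moderated difference
  d = Δx̄/(s+s₀); Westfall–Young step-down maxT on Welch t), with exact
  exhaustive enumeration whenever feasible; a marker is significant only
  when **all three** methods agree (p ≤ α after each method's own
  adjustment, same direction).
* **Consensus network** — missing scores are re-imputed with random draws
  from each marker's empirical distribution over thousands of iterations
  (15000 in the production profile); the fraction of iterations in which
  two samples co-cluster defines a weighted sample graph (GEXF/GraphML
  export).
* **Diagnostic panel** — the 8-marker × 4-type grid (CK19, CK20, MUC2,
  MUC5AC, CA19-9, mCEA, CA125, SMAD4 with categories +, +/−, −/+, −) is
  machine-readable, derivable from any cohort's positivity profiles, and
  applicable to single samples via a match-score classifier.
* **Validation** — stratified 10-fold CV of the three clinically relevant
  pairwise tasks (EPB vs INT, EPB vs ICC, ICC vs HCC) with four classifier
  families and two feature sets (all markers vs consensus markers).
* **Survival** — Kaplan–Meier with median OS (restricted mean when
  unreached), log-rank tests, and Cox proportional-hazards models (Efron
  ties) giving crude and pT+pN-adjusted hazard ratios; proportional
  hazards checked via scaled Schoenfeld residuals.

## Worked example

```python
from ihctyper import (CohortSpec, generate_cohort, prune_missing, knn_impute,
                      pearson_distance, agglomerative_average, assign_types,
                      run_pairwise, cox_model, PipelineConfig,
                      summarize_missingness)

spec = CohortSpec(n_per_type={"EPB": 40, "INT": 40, "ICC": 40, "HCC": 40},
                  missing_rate=0.18, probe_resection_prob=1.0, seed=7)
scores, truth, clinical = generate_cohort(spec)
print(f"cohort: {scores.n_samples} samples x {scores.n_markers} markers, "
      f"{summarize_missingness(scores).overall:.1%} missing")

pruned, report = prune_missing(scores, PipelineConfig())
complete = knn_impute(pruned, k=10)
dend = agglomerative_average(pearson_distance(complete),
                             sample_ids=complete.sample_ids)
assignment = assign_types(dend, complete)
print(f"cut at k={assignment.k}; type counts:")
print(assignment.labels.value_counts().to_string())

results = run_pairwise(complete, assignment.labels, pairs=[("ICC", "HCC")],
                       n_perm=1000, seed=1)
print("consensus markers ICC vs HCC:",
      results[("ICC", "HCC")].consensus_markers)

records = clinical.rename(columns={"true_type": "ihc_type"})
fit = cox_model(records[records["resected"]], ["ihc_type", "pT", "pN"])
hr = fit.summary.loc["ihc_type::INT"]
print(f"adjusted intestinal HR {hr['hr']:.2f} "
      f"(95% CI {hr['ci_lower']:.2f}-{hr['ci_upper']:.2f}, p={hr['p']:.3f})")
```

Output:

```
cohort: 160 samples x 27 markers, 18.0% missing
cut at k=9; type counts:
ihc_type
ICC             40
EPB             38
HCC             38
INT             33
unclassified    11
consensus markers ICC vs HCC: ['CK19', 'CA19-9', 'CK7', 'MUC1', 'maspin', 'BerEP4', 'EMA', 'CD10']
adjusted intestinal HR 0.32 (95% CI 0.17-0.61, p=0.001)
```

Reading the output: the 160-sample four-type cohort with 18% panel-block
missingness clusters into 9 groups; after naming, each generated type is
recovered as the dominant label (11 samples in small outlier clusters stay
unclassified). The ICC-vs-HCC comparison flags the epithelial/adeno markers
(CK19, CA19-9, CK7, MUC1, BerEP4, EMA …) that separate cholangiocarcinoma
from hepatocellular carcinoma by all three tests. The Cox model, adjusted
for pT and pN, estimates the protective intestinal-type effect (hazard
ratio well below 1); the generator's planted effect for INT is HR 0.19, and
at 40 resected patients per arm the estimate is correspondingly noisy.

## Command line

Every stage is also a subcommand of the `ihctyper` CLI:

```bash
ihctyper simulate --seed 1 --out data/
ihctyper prune data/scores.csv --out data/pruned.csv
ihctyper impute data/pruned.csv --method knn --k 10 --out data/complete.csv
ihctyper cluster data/complete.csv --out run/
ihctyper diffexp data/complete.csv run/labels.csv --out run/
ihctyper network data/pruned.csv --k 4 --iters 15000 --seed 1 --out run/
ihctyper validate data/complete.csv run/labels.csv --out run/validation.csv
ihctyper survival data/clinical.csv --out run/survival.csv
ihctyper run --seed 1 --out run/      # the whole pipeline on a simulated cohort
```

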