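# Methods

`survscan` implements a two-cohort survival-disparity analysis for bulk
transcriptomics: per-gene optimal-cutoff Kaplan–Meier scanning, simplified
negative-binomial differential expression, weight-matrix pathway-activity
scoring, cross-cohort concordance/discordance synthesis, and multivariable
Cox models with gene × cohort interactions. This note records the models,
the defaults and why, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Survival primitives

**Kaplan–Meier.** The product-limit estimate S(t_i) = Π_{j≤i}(1 − d_j/n_j)
over distinct observed times; censoring-only times leave S unchanged.
Events recorded at exactly t = 0 (real tables contain them) are shifted by
+1e-6 month so every event has a non-empty risk set; the shift is a module
constant (`ZERO_EVENT_SHIFT`).

**Log-rank with Yates' correction.** At each distinct event time the
observed group-1 events are compared with the conditional hypergeometric
expectation d·n₁/n and variance d·(n₁/n)(n₂/n)(n−d)/(n−1). With
U = O₁ − E₁ and V the summed variance, the statistic is
χ² = (max(0, |U| − 0.5))² / V, referred to χ²(1). The 0.5 continuity
correction (skipped when |U| ≤ 0.5) is the standard form used by the
community MATLAB log-rank implementations; it makes the test conservative,
which the permutation calibration test quantifies (null rejection ≈ 3%
at nominal 5%). A comparison with zero variance returns χ² = 0, p = 1.

**Cox proportional hazards.** Newton–Raphson maximisation of the partial
likelihood with Breslow tie handling by default and Efron selectable
(R's `coxph`, used for forest-plot-style analyses, defaults to Efron; the
MATLAB lineage of the scan defaults to Breslow — both are supported and the
choice is recorded in the fit object). Covariates are centred internally
for conditioning; the likelihood evaluation is vectorised over tied-time
blocks. Convergence: infinity-norm of the score < 1e-8, max 50 iterations,
step-halving when a step does not improve the likelihood. Monotone
likelihood (any |β| > 10) sets `converged=False` with a diagnostic rather
than returning a spuriously huge hazard ratio. Standard errors come from
the inverse observed information; confidence intervals are Wald at the
fixed 95% level; AIC = 2k − 2·loglik. The test suite cross-checks β and SE
against lifelines (Efron) to 1e-4 and against grid search of the Breslow
partial likelihood on tiny fixtures, and verifies that the score test at
β = 0 for a binary covariate equals the uncorrected log-rank χ².

## The optimal-cutoff (min-p) scan

For each feature, candidate cutoffs are the midpoints between consecutive
distinct sorted values whose induced low-group fraction lies in the scan
bounds (default 10–90%). Exhaustive distinct-value candidates are used
rather than an integer-percent grid: the scan is cheap at cohort sizes of a
few hundred (the log-rank O/E/V over all candidate prefixes is computed
with two cumulative-sum matrices) and dominates any coarser grid. Patients
with tied values are never split. The candidate minimising the
Yates-corrected p is reported; p ties break toward the most balanced split.
The hazard ratio (high vs low) is then fitted by Cox regression on the
winning binary indicator.

Min-p selection over many correlated splits is anti-conservative: under the
null roughly 20–30% of features reach p < 0.05 at realistic event counts.
This is a property of the procedure itself and is deliberately **not**
corrected (no maximally-selected-rank adjustment); it is documented and
measured by the calibration tests. Consequently, when Storey's FDR is
applied to the min-p values — as the procedure prescribes — the π0 estimate
collapses toward zero (almost no p-values exceed the λ grid) and q-values
fall *below* the raw p-values. The acceptance suite contains a deliberately
failing check recording that under a 500-gene null essentially every gene
receives q < 0.05; reported q-values from min-p scans must therefore be
read as descriptive companions of the raw p-values, not as calibrated false
discovery rates. The significance flag used throughout is raw p < α
(default 0.05), with q reported alongside.

**Storey q-values.** π0 is estimated on the λ grid 0.01…0.95 either by a
cubic polynomial smoother in λ evaluated at λ = 0.95 (default) or at the
fixed point λ = 0.5; both are clipped to (1/m, 1]. q_(i) = min_{j≥i}
π0·m·p_(j)/j over the sorted p-values. With π0 forced to 1 the q-values
equal Benjamini–Hochberg adjusted p-values exactly (tested against
statsmodels).

## Differential expression (simplified NB Wald)

A deliberately transparent stand-in for a full shrinkage-based NB pipeline:

1. median-of-ratios size factors s_j = median_g K_gj / geomean(K_g·) over
   genes with all-positive counts;
2. per-gene dispersion α by method of moments on normalised counts,
   computed within each cohort and pooled with weights n_c − 1, floored at
   1e-8 (Var = μ + αμ²);
3. per-gene NB GLM with log link, design intercept + cohort, log s_j as
   offset, fitted by Fisher scoring vectorised across all genes (2×2
   information solved in closed form); Wald test on the cohort coefficient;
4. BH adjustment; the DEG flag is p < 0.05 and |log2FC| > 0.1.

There is no dispersion-trend or fold-change shrinkage, no independent
filtering, no outlier handling; an externally produced table with the same
columns can be imported instead (`import_de_table`). The vectorised fit
makes label-swap antisymmetry exact to machine precision and a 2000-gene
null calibration run in well under a second; per-gene fits are cross-checked
against statsmodels' NB GLM in the tests. Null rejection at p < 0.05 is
5–6% (slightly above nominal because the moment dispersion estimate is
noisy); the planted log2FC = 1 recovery is unbiased to within ±0.2.

## Pathway activity

Scores are weighted sums of z-scored log expression over each pathway's
most responsive genes: counts → log2(count/s_j + 1) → per-gene z-score
(ddof = 1; constant genes become zero rows with a warning) → per pathway,
the top_k genes by responsiveness rank (or |weight| when no ranks are
supplied) present in the matrix, score_{p,j} = Σ_g z_{g,j}·w_{g,p}.
top_k defaults to 100, the cited scoring tool's convention. z-scoring is
per cohort by default (the pipeline analyses the cohorts independently);
pooled z-scoring is available and is used for the cohort mean-difference
table, since per-cohort standardisation forces cohort means to zero by
construction. Score–survival association reuses the optimal-cutoff scan.

## Cross-cohort synthesis

A gene's category depends only on the two significance flags and the sign
agreement of the log hazard ratios: both-concordant, both-discordant
(association flips direction), exclusive to either cohort, or neither.
All eight DEG × significant-A × significant-B Venn regions are reported
with their marginals. Summary percentages are pure integer arithmetic and
carry their numerator/denominator. Two conventions for "non-common" are
reported under distinct keys: the association-count convention
(n_A + n_B − overlap, counting a shared gene's two associations and
removing the overlap once) and the strictly set-theoretic symmetric
difference (n_A + n_B − 2·overlap).

## Multivariable Cox models

Designs are assembled from the clinical table: continuous terms as-is
(gene expression enters on the log2-normalised scale, not the dichotomised
scan groups — dichotomisation would conflate the scan's selection with the
model), categorical terms dummy-coded against a stated reference, and
interaction terms as elementwise products of declared columns. Missing
covariates are retained at load and handled by listwise deletion per model,
with the dropped count reported in the forest table. Stage can optionally
be collapsed to I–III vs IV. The forest table is a pure projection of the
fit (HR, 95% CI, Wald p, R-convention significance codes, n, events, AIC);
non-converged fits are emitted with a diagnostic flag.

## Synthetic-data generator

The generator emulates the structure of an unbalanced two-cohort TCGA-style
study, with every planted quantity recorded in a ground-truth sidecar.

* **Cohorts**: 61 and 272 patients by default, the preprocessed sizes of
  the study design the pipeline targets.
* **Counts**: per-gene baseline means log-uniform on [20, 2000] (a
  realistic mid-to-high expression range for genes retained in survival
  analyses), NB dispersion α = 0.4 (Var = μ + αμ²; typical bulk tumour
  heterogeneity), per-sample size factors log-normal with σ = 0.25.
  Genes in the DE table have cohort-B means scaled by 2^log2FC.
* **Survival**: each patient's hazard is h_j = h₀·exp(Σ_g β_{g,cohort(j)}
  z_{gj}) with z the per-gene standardised log-normalised expression, so a
  planted β is a per-SD log hazard ratio and may differ in sign between
  cohorts. Event times are drawn by exponential inversion (the per-sample
  hazard is constant, so the proportional-hazards assumption holds
  exactly). Censoring is independent exponential (rate 0.03/month) plus an
  administrative horizon at 120 months; with h₀ = 0.01/month this yields
  ≈25% events — about 80 events across 333 patients, the power regime the
  pipeline is designed for. The real study's censoring law is unknown
  beyond summary medians; this is a stand-in, not a calibration.
* **Gene sets**: nine named sets sized 117/26/134/338/26/253/119/84/46
  (1143 memberships over 893 unique genes) by default, generated with
  controlled overlap so the unique-gene reduction is exercised; arbitrary
  sizes are accepted.
* **Weight matrix**: five pathways (PI3K, MAPK, TGFB, WNT, p53 — "TGFB"
  is written in ASCII to keep TSV headers encoding-safe); each pathway has
  three disjoint driver genes carrying the largest |weight| (±2.5,
  recorded as ground truth) plus ~40 small background weights.

What the generator does **not** emulate: batch effects, stage/site biology,
gene–gene correlation beyond what shared survival effects induce, mutation
data, or non-exponential censoring. Passing recovery tests therefore shows
the estimators are correct under a well-specified proportional-hazards NB
world, not that the pipeline's findings on real tumour data are
biologically calibrated.

## Problem sizes used in tests and the acceptance script

Null calibrations use 2000 label permutations (n = 60), a 2000-gene NB
null (50 + 50 samples), a 500-gene scan null (50 + 50 patients) and 1000
uniform p-values. Recovery checks use 200 replicates of an n = 500 binary
Cox fit (HR = 2), 200 genes at log2FC = 1, one n = 600 interaction fit
(true coefficient −1.4, checked against the stratified-fit difference
within 2 joint SE), and 50 replicates of a planted five-pathway scoring
run (75 + 75 patients, 60 genes). The full study-shaped pipeline run uses
1000 genes across 333 patients. These sizes make the default test suite
and the acceptance script complete in a few minutes on one CPU while
keeping every binomial/Monte-Carlo standard error small relative to the
asserted bands.

## Known limitations

* The DE stage is intentionally simpler than shrinkage-based NB pipelines;
  exact parity with them is a non-goal.
* q-values attached to min-p scan results inherit the scan's
  anti-conservatism (see above) and are descriptive only.
* No proportional-hazards diagnostics, time-varying covariates or
  penalised fits.
* Pathway weight training is out of scope; weights are an input.
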