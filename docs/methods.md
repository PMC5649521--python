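# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have
to reverse-engineer.

## Preprocessing

Raw matrices may contain duplicate gene rows (multiple probes per
symbol). Duplicates are collapsed by the per-sample **median** by
default — robust to a single aberrant probe — with `mean` as an option.
Values are log2-transformed with offset 1.0 when raw (`already_log2`
skips this for pre-logged data; applying log2 twice would be silently
wrong, so the flag is explicit) and **median-normalized per gene**
(median subtracted across samples). Group differences, and therefore
log2 fold changes, are invariant to this centering.

Two further gene-wise scalings serve specific stages:

* **(0, 1) min-max scaling** for classifiers, learned on the training
  cohort only. Validation values outside the training range are clipped
  to [0, 1]; a constant training gene maps to 0.5. Clipping is the
  conservative choice for cohorts measured on different dynamic ranges.
* **Unit-variance standardization** for the clustering feature space
  (see below).

`top_variable_genes` keeps the `ceil(fraction · n_genes)` genes with the
largest unbiased sample variance (ties broken by input order). The
default fraction is 0.25 (the first quartile of most-variable genes, the
convention for this kind of cohort).

## Subgroup discovery

PCA is fitted on **disease samples only**, and all samples — controls
included — are projected onto the disease components; this keeps the
axes aligned with disease heterogeneity rather than the disease-control
contrast. Components are retained up to 90% explained variance
(configurable; the quantity clustered is a design choice, not something
the underlying study pins down).

Before PCA the top-variance submatrix is standardized per gene. This
matters: gene-wise noise variances are heavy-tailed (see the generator's
prior), and without standardization a handful of high-noise genes
dominate Euclidean distances and degrade cluster recovery badly
(adjusted Rand index ~0.87 vs ~1.0 on default synthetic cohorts).
Scaling to unit variance before PCA is standard practice in
transcriptomic clustering.

Disease scores are clustered by **Ward linkage on Euclidean distance**
(scipy's implementation; an exhaustive Ward-criterion agglomeration
oracle verifies it in the tests on all instances with ≤ 8 points).

**Cluster-count selection** operationalizes "the smallest number of
clusters that allows the maximal difference in average FEV1, FVC and
D_LCO": for each k in [2, 10] the clinical separation score is

    score(k) = mean over measures of
               (range of cluster means) / (pooled within-cluster SD)

with missing values dropped per measure, and the selected k is the
smallest whose score is ≥ (1 − tolerance) × the maximum over the range,
tolerance 0.05. The tolerance absorbs the mild upward drift of the score
with k (splitting a cluster lets extreme subset means inflate the range
by sampling noise); the drift scales with the within-cluster clinical SD
relative to the between-cluster spread, so selection is reliable
precisely when clinical separation is strong.

Clusters are renamed C1…Ck by **descending mean %D_LCO** (FVC, then FEV1
break ties): C1 mildest, Ck most severe. D_LCO leads because it is the
measure that tracks the severity gradient most directly in this disease.
The lung-function baseline grouping (mild-to-moderate iff FVC ≥ 55% or
D_LCO ≥ 40% on available measures; severe iff every available measure
fails; unknown if both are missing) is provided as a comparator.

## Differential expression

The engine is a from-scratch two-group empirical-Bayes moderated t, so
its statistical behavior is testable in isolation (a small-fixture
cross-check against R/limma's eBayes is in the test suite):

* per gene: mean difference (log2FC), pooled residual variance s²_g on
  d = n_A + n_B − 2 df, unscaled variance v = 1/n_A + 1/n_B;
* across genes: the scaled inverse-chi-square prior
  σ²_g ~ d₀s₀²/χ²_{d₀} is estimated by matching the mean and variance of
  log s²_g to a scaled F distribution (digamma/trigamma moment
  equations; the trigamma inverse is solved by Newton iteration). When
  the empirical log-variance spread does not exceed the sampling
  component trigamma(d/2), the prior df is infinite and s₀² is the
  geometric-mean-consistent constant
  exp(mean log s² + log(d/2) − digamma(d/2)) — the bias-corrected value,
  not the raw mean of s²;
* per gene again: posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d),
  t̃ = diff/√(s̃²v), two-sided p on d₀ + d df (normal limit at d₀ = ∞;
  d₀ = 0 recovers the ordinary two-sample t).

BH adjustment is applied **per contrast** (the analysis reports DEG
counts per cluster; a `global` option pools contrasts). DEG thresholds
are inclusive: q ≤ 0.05 and |log2FC| ≥ 1. Note the BH step-up map is not
idempotent — re-adjusting adjusted values re-inflates them — so adjusted
values are treated strictly as outputs.

Summary-level clinical comparisons use the pooled-variance two-sample t
(from printed mean/SD/n) and the 2×2 Pearson chi-square without
continuity correction, df = 1.

## Signatures

From the per-cluster DEG sets: `overlap_groups` counts cluster
membership per gene; the **core** set is the intersection across all
clusters (genes up in some clusters and down in others are flagged
discordant, recorded rather than resolved); **unique** sets contain
genes DEG in exactly one cluster, and the most severe cluster's unique
set is exported under the name **advanced**. Gene modules cluster the
DEG-union rows with distance 1 − Pearson correlation and complete
linkage, cut at 3 modules by default (configurable); constant gene rows
are assigned zero correlation with a warning.

## Classifier validation

Signature classifiers are L2-regularized logistic regressions
(strength 1.0 by default) on (0, 1)-scaled expression, positive class =
disease. Stratified 2-fold cross-validation refits the scaling and the
threshold inside each training fold. The decision threshold is
calibrated on training scores to **guarantee ≥ 90% sensitivity**:
among thresholds meeting the floor, specificity is maximized first and
sensitivity breaks ties; since any threshold inside a gap between
adjacent unique scores yields identical training confusion counts, the
returned threshold sits mid-gap, which maximizes the margin on both
sides and transfers far better to held-out cohorts than a threshold
placed exactly on an observed score. ROC curves sweep unique scores; the
AUC is the Mann-Whitney probability with ties counted ½.

## Candidate prioritization

Enrichment is a one-sided hypergeometric test per annotation term
(overlap at least observed, universe = all measured genes) with BH
within each annotation category. Functional similarity of a gene to the
known-disease training set is a deliberately simple, fully documented
surrogate for web-service gene prioritizers: the sum of −log10(q) over
training-set-enriched terms (q ≤ 0.05) that also annotate the gene. It
is pluggable — any scorer with the same signature can be substituted.
Candidates are ranked by similarity and by |log2FC| (the largest value
over the contrasts where the gene is a DEG), ranks aggregated by the
**rank product** (geometric mean; average-rank ties), known training
genes removed, and the top 10% reported.

## Biomarker panel search

Candidates are the secreted/BALF-annotated core genes, ordered by
|coefficient| of a logistic model on all candidates. For k = 1…50 a
classifier on the top-k candidates is fitted and its operating point
calibrated; the selected panel is the smallest k with specificity > 0.8
(strict) and sensitivity ≥ 0.9. When an evaluation cohort is supplied,
the threshold is calibrated **on the evaluation scores**: the question
asked is whether the k-gene classifier *admits* an operating point with
the required sensitivity and specificity there (an ROC-dominance check),
which measures panel information content rather than threshold
transfer. Without an evaluation cohort, metrics are training-cohort
predictions (with an `accuracy` calibration mode as an alternative).
The end-to-end pipeline falls back to searching the full secreted list
when fewer than five core genes carry the annotation, so the stage
remains meaningful on cohorts whose core set is sparsely annotated.

## Synthetic cohorts

The generator draws, per cohort:

* gene-wise variances σ²_g ~ d₀s₀²/χ²_{d₀} with d₀ = 4, s₀² = 0.25
  (typical microarray residual scale, σ ≈ 0.5 log2 units; d₀ = 4 is a
  realistic moderate prior strength and makes the variance distribution
  heavy-tailed, which is exactly what stresses variance-sensitive
  steps);
* per-gene baselines ~ Normal(8, 1.5²) log2 units;
* expression = baseline + subgroup effect + Normal(0, σ²_g), controls
  carrying zero effects — noise is gene-wise independent given the
  module structure;
* 12 controls + 96 disease samples split evenly into K = 6 latent
  severity subgroups (a `paper_scale()` preset emits 14,110 × 143).

Planted effect blocks (defaults, all ±1.5 log2 ≈ 3σ, "moderate" = 0.75):
a **core** block of 150 genes perturbed in every subgroup (⅓ down;
includes 6 high-effect candidates at 2.2), three severity-patterned
co-expression blocks of 150 genes mirroring the reported module
patterns, a **unique** block per subgroup (80 genes; 100 for the
second-most-severe), and an **advanced** block of 100 genes perturbed
only in the most severe subgroup (includes 6 candidates at 2.2). Every
subgroup pair therefore differs on a few hundred genes at ≥ 1.5 pooled
SD, the regime in which the clustering stage is designed to operate.

The **secreted biomarker block** (60 genes) is defined on the
standardized scale: each gene's log2 shift is SNR × σ_g, identical in
every subgroup, with 11 informative genes at SNR 0.82 and 49 marginal
fillers at SNR 0.30. This construction makes each informative gene
equally informative regardless of its noise level, so no single gene
suffices (single-gene specificity at 90% sensitivity ≈ 0.3) and roughly
ten are needed to clear the panel criterion — the planted analogue of a
~dozen-protein fluid-biomarker panel. These genes sit below the
fold-change DEG cut by design, so the truth core set excludes them even
though they are perturbed in every subgroup; the secreted annotation is
consequently its own block rather than a subset of the core set.

Clinical measures are drawn per subgroup: control means and SDs follow
the training cohort's demographics table (FEV1 94.33 ± 9.86,
FVC 91.75 ± 7.44, D_LCO 97.0 ± 21.3); disease subgroup means descend
linearly with severity (FEV1 90→55, FVC 85→48, D_LCO 75→35) with
within-subgroup SD 3 — strong clinical separation (≈ 2.7 SD between
adjacent subgroups), the condition under which clinically guided
cluster-count selection is meant to be assessed. D_LCO is missing in 5%
of disease samples to exercise the missing-data paths.

Paired cohorts ("same platform") are generated with `template=`, which
reuses the per-gene variances and baselines of an existing cohort —
residual variance is a property of the gene and assay, and without
sharing it classifier weights learned on one cohort are systematically
mismatched on the next.

`generate_annotation_db` emits six annotation categories; each carries
two planted disease terms built from ~80% of the known training genes
plus the planted candidate genes (so those terms come out enriched in
the training set and annotate the candidates) and 20 random background
terms.

**What the generator does not emulate** — and what passing tests
therefore do not establish about real cohorts: probe-level artifacts and
batch effects; gene-gene correlation beyond block structure (real
co-expression is pervasive, which weakens effective sample sizes);
realistic within-subgroup clinical spread (real clusters overlap far
more than SD 3, so clinical cluster-count selection on real data is
substantially noisier than here); uneven subgroup sizes; and annotation
databases with realistic term-size distributions and overlap.

## Numerical choices and degenerate inputs

* Variance = unbiased (n − 1) sample variance throughout.
* Ties: variable-gene selection and coefficient ranking break ties by
  input order (stable sorts); rank-based statistics use average ranks.
* `clinical_separation_score` returns ∞ when within-cluster spread is
  exactly zero but means differ (degenerate perfect separation), 0 when
  means are also identical.
* Constant genes: min-max scaling maps them to 0.5; standardization
  leaves them at 0; module clustering treats them as zero-correlated
  with a warning.
* Zero residual variances are dropped (with a warning) from the prior
  moment equations; an all-zero variance vector is an error.
* All randomness flows through explicit seeds (`numpy.random.Generator`
  or recorded sklearn seeds); every simulation-facing function is
  deterministic given its seed, and `run_all` reports are byte-identical
  across reruns of the same config and seed.

## Known limitations

* The moderated-t engine covers two-group contrasts only — no covariate
  adjustment, array weights or duplicate-correlation.
* The functional-similarity surrogate ignores term specificity weighting
  and gene-level evidence scores used by production prioritizers; ranks,
  not absolute scores, are the meaningful output.
* The cluster-count score inherits sampling drift with k (documented
  above); with weak clinical separation it can over-select clusters, and
  the selection trace should be inspected rather than trusted blindly.
* Panel-search metrics on a 12-control training cohort have 1/12
  specificity granularity; the evaluation-cohort mode exists precisely
  because such metrics are too coarse to rank panels.
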