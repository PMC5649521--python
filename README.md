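# fibrostrat

Severity stratification of idiopathic pulmonary fibrosis (IPF) lung
transcriptomes, as a tested, offline-reproducible pipeline.

IPF is a fatal fibrotic lung disease whose clinical course — tracked by
percent-predicted FEV1, FVC and D<sub>LCO</sub> — is highly variable, and whose
expression profiles are too heterogeneous for a single IPF-vs-control
contrast to capture. `fibrostrat` implements an unsupervised workflow for
bulk expression cohorts (microarray-style log2 intensities) that:

1. **Preprocesses** the matrix: duplicate-probe aggregation, log2,
   per-gene median normalization;
2. **Discovers patient subgroups**: PCA is fitted on disease samples only
   (controls are projected), and Ward/Euclidean hierarchical clustering of
   the disease scores is cut at the smallest number of clusters k whose
   clinical separation — the range of cluster means of each lung-function
   measure over its pooled within-cluster SD, averaged over measures — is
   within tolerance of the best over k ∈ [2, 10]; clusters are renamed
   C1…Ck from mildest to most severe by mean %D<sub>LCO</sub>;
3. **Tests differential expression** per cluster vs control with a
   self-contained empirical-Bayes moderated t: per-gene two-group models
   give the log2 fold change and residual variance s²_g on d degrees of
   freedom; a scaled inverse-chi-square prior (d₀, s₀²) is estimated
   across genes by log-variance moment matching, and the posterior
   variance s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) yields t̃ on d₀ + d df.
   DEGs satisfy BH-adjusted p ≤ 0.05 and |log2FC| ≥ 1;
4. **Builds signatures**: the *core* set (DEG in every cluster), per-cluster
   *unique* sets (the most severe cluster's unique set is exported as the
   *advanced* signature), and co-expression gene modules (1 − Pearson
   distance, complete linkage);
5. **Validates signatures** with L2-regularized logistic classifiers:
   per-gene (0, 1) scaling learned on the training cohort, stratified
   2-fold cross-validation, a decision threshold calibrated to ≥ 90%
   sensitivity (maximal specificity subject to that floor), and
   ROC/AUC/sensitivity/specificity/accuracy on held-out cohorts;
6. **Prioritizes novel candidates** by rank product: genes are ranked by
   functional similarity to a known-disease training set (sum of
   −log10 q over training-set-enriched annotation terms that also annotate
   the candidate; hypergeometric test, BH within category) and by
   |log2FC|, ranks are aggregated by their geometric mean, known genes are
   removed, and the top 10% reported;
7. **Searches for a minimal biomarker panel** among secreted/BALF-annotated
   core genes: candidates are ordered by |coefficient| of a full logistic
   model, nested top-k classifiers are fitted for k = 1…50, and the
   smallest panel admitting specificity > 0.8 at sensitivity ≥ 0.9 is
   selected.

Because the original cohorts live in GEO and the workflow is meant to be
testable offline, the package ships a first-class **synthetic-cohort
generator** (`fibrostrat.synthetic`) that emulates the study design —
12 controls + 96 disease samples in K = 6 latent severity subgroups,
module-structured effects, gene-wise variances drawn from the eBayes
prior, severity-correlated clinical measures, planted biomarkers and
annotation databases — with complete ground truth for recovery tests.

## Worked example

Run the whole workflow on a simulated cohort (2,000 genes × 108 samples):

```bash
fibrostrat run-all --out results/demo --seed 1
```

or from Python:

```python
from fibrostrat.pipeline import RunConfig, run_all
report = run_all(RunConfig(output_dir="results/demo", seed=1))
```

With seed 1 the run prints `report.json` containing (abridged):

```
cluster:    selected_k = 6, cluster sizes C1..C6 = 16 each,
            500 variable genes, 70 components
de:         DEGs per cluster C1..C6 = 530, 216, 662, 390, 555, 674
signatures: core = 134 genes, advanced (C6-unique) = 96 genes, 3 modules
classify:   validation sensitivity/specificity/accuracy/AUC = 1.0
recovery:   recovered_k = 6 (true 6), ARI = 1.0,
            core Jaccard = 0.88, advanced Jaccard = 0.94
```

Reading: the clinically guided selection recovered the six planted
severity subgroups exactly (adjusted Rand index 1.0 against the hidden
labels); the recovered core signature overlaps the planted
all-subgroup block at Jaccard 0.88; and a core-signature classifier
separates disease from control perfectly on an independently drawn
validation cohort. Stage artifacts (cluster labels, DE table, GMT
signatures, classifier reports, prioritized candidates, panel trace)
are written as plain TSV/CSV/GMT/JSON files under `results/demo/`.

Each stage is also an importable function
(`fibrostrat.diffexpr.de_table`, `fibrostrat.subtype_clustering.select_cluster_count`,
`fibrostrat.prioritization.prioritize_candidates`, …) and a CLI
subcommand (`simulate`, `preprocess`, `cluster`, `de`, `signatures`,
`classify`, `prioritize`, `biomarkers`).

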