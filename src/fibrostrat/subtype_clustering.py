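"""Patient subgroup discovery.

PCA is fitted on disease samples only and all samples (controls
included) are projected onto those components; Ward/Euclidean
hierarchical clustering of the disease-sample scores yields candidate
partitions, and the cluster count is chosen as the smallest k whose
clinical separation (difference in average FEV1 / FVC / D_LCO across
clusters) is within tolerance of the best over the candidate range.
Cluster labels are then renamed C1..Ck from mildest to most severe by
mean percent-predicted D_LCO.

Also provides the baseline lung-function severity grouping
(FVC >= 55% or D_LCO >= 40% -> mild-to-moderate, otherwise severe)
used as a comparator for the unsupervised subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from fibrostrat.io_formats import ClinicalTable, ExpressionMatrix

SEVERITY_MEASURES = ("fev1_pct", "fvc_pct", "dlco_pct")
#: severity ordering key: D_LCO first, FVC then FEV1 as tie-breaks
ORDERING_MEASURES = ("dlco_pct", "fvc_pct", "fev1_pct")


def severity_group(clinical: ClinicalTable) -> pd.Series:
    """Lung-function severity grouping of disease samples.

    mild_moderate if FVC >= 55 or D_LCO >= 40 (on available measures),
    severe if every available measure fails its cut-off, unknown when
    both measures are missing.
    """
    disease = clinical.disease_samples()
    fvc = clinical.measure("fvc_pct").loc[disease]
    dlco = clinical.measure("dlco_pct").loc[disease]
    mild = (fvc >= 55) | (dlco >= 40)
    unknown = fvc.isna() & dlco.isna()
    out = pd.Series("severe", index=pd.Index(disease, name="sample_id"))
    out[mild.fillna(False)] = "mild_moderate"
    out[unknown] = "unknown"
    return out


@dataclass
class PCAModel:
    """Principal components fitted on disease samples.

    ``loadings`` is genes x components (orthonormal columns);
    ``means`` are the per-gene centering means learned on the disease
    samples; projection of any cohort is ``(X - means) @ loadings``.
    """

    loadings: pd.DataFrame
    means: pd.Series
    explained_variance_ratio: np.ndarray

    def project(self, m: ExpressionMatrix) -> pd.DataFrame:
        sub = m.data.loc[self.loadings.index]
        centered = sub.sub(self.means, axis=0)
        scores = centered.T.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(scores, index=m.sample_ids, columns=self.loadings.columns)


def fit_pca_project(
    disease_m: ExpressionMatrix,
    all_m: ExpressionMatrix,
    n_components: int | None = None,
    explained_variance: float | None = None,
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit PCA on disease samples, project every sample onto it.

    Either a fixed ``n_components`` or an ``explained_variance``
    fraction (components retained until that much variance is
    explained) must be given.  Gene sets and order must agree between
    the two matrices.
    """
    if disease_m.gene_ids != all_m.gene_ids:
        raise ValueError("disease and full matrices must share genes in the same order")
    missing = [s for s in disease_m.sample_ids if s not in all_m.sample_ids]
    if missing:
        raise ValueError(f"disease samples absent from full matrix: {missing[:5]}")
    n_disease, n_genes = disease_m.shape[1], disease_m.shape[0]
    max_rank = min(n_disease, n_genes)
    if n_components is None and explained_variance is None:
        raise ValueError("give n_components or explained_variance")
    if n_components is not None and n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds matrix rank bound {max_rank}")

    X_disease = disease_m.values.T  # samples x genes
    pca = PCA(n_components=max_rank if n_components is None else n_components, svd_solver="full")
    pca.fit(X_disease)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, explained_variance) + 1)
        keep = min(keep, len(cum))
    else:
        keep = n_components
    cols = [f"PC{i + 1}" for i in range(keep)]
    loadings = pd.DataFrame(pca.components_[:keep].T, index=disease_m.gene_ids, columns=cols)
    model = PCAModel(
        loadings=loadings,
        means=pd.Series(pca.mean_, index=disease_m.gene_ids),
        explained_variance_ratio=pca.explained_variance_ratio_[:keep].copy(),
    )
    return model, model.project(all_m)


def ward_cluster(points: np.ndarray, k: int) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering cut at k clusters.

    Returns integer labels 1..k (dendrogram order, arbitrary before
    severity renaming).  Deterministic for fixed input.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} points")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(points, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def clinical_separation_score(
    labels: pd.Series,
    clinical: ClinicalTable,
    measures: tuple[str, ...] = SEVERITY_MEASURES,
) -> float:
    """Between-cluster clinical separation.

    For each lung-function measure: (range of cluster means) divided by
    the pooled within-cluster standard deviation; the score is the mean
    over measures with data.  Samples missing a measure are dropped for
    that measure; measures with no usable data are skipped.
    """
    labels = labels.dropna()
    if labels.nunique() < 2:
        raise ValueError("need at least two clusters")
    per_measure: list[float] = []
    for measure in measures:
        values = clinical.measure(measure).reindex(labels.index)
        ok = values.notna()
        if not ok.any():
            continue
        v, lab = values[ok], labels[ok]
        cluster_means = v.groupby(lab).mean()
        if len(cluster_means) < 2:
            continue
        rng = cluster_means.max() - cluster_means.min()
        # pooled within-cluster SD, (n_i - 1)-weighted
        ss, dof = 0.0, 0
        for _, grp in v.groupby(lab):
            if len(grp) >= 2:
                ss += (len(grp) - 1) * grp.var(ddof=1)
                dof += len(grp) - 1
        if dof == 0 or ss == 0:
            # degenerate: no within-cluster spread; separation is maximal
            per_measure.append(np.inf if rng > 0 else 0.0)
            continue
        per_measure.append(float(rng / np.sqrt(ss / dof)))
    if not per_measure:
        raise ValueError("no measure has usable data in >=2 clusters")
    return float(np.mean(per_measure))


def select_cluster_count(
    points: np.ndarray,
    sample_ids: list[str],
    clinical: ClinicalTable,
    k_min: int = 2,
    k_max: int = 10,
    tolerance: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by clinical separation.

    Scores each k in [k_min, k_max] and returns the smallest k whose
    score is >= (1 - tolerance) x the maximum over the range, together
    with the full trace.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    rows = []
    for k in range(k_min, min(k_max, len(sample_ids)) + 1):
        labels = pd.Series(ward_cluster(points, k), index=sample_ids)
        try:
            score = clinical_separation_score(labels, clinical)
        except ValueError:
            score = np.nan
        rows.append({"k": k, "score": score})
    trace = pd.DataFrame(rows)
    valid = trace.dropna(subset=["score"])
    if valid.empty:
        raise ValueError("no candidate cluster count could be scored")
    best = valid["score"].max()
    chosen = valid.loc[valid["score"] >= (1 - tolerance) * best, "k"].min()
    return int(chosen), trace


@dataclass
class ClusterAssignment:
    """Disease-sample cluster labels C1..Ck ordered mild -> severe."""

    labels: pd.Series  # sample_id -> "C1".."Ck"
    k: int
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)

    def samples_in(self, cluster: str) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()

    def cluster_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.k)]


def order_clusters_by_severity(
    labels: pd.Series,
    clinical: ClinicalTable,
    trace: pd.DataFrame | None = None,
) -> ClusterAssignment:
    """Rename raw cluster labels C1..Ck from mildest to most severe.

    Ordered by descending mean %predicted D_LCO (higher = milder),
    with mean FVC then mean FEV1 breaking ties, so C1 is the mildest
    cluster and Ck the most severe.
    """
    labels = labels.dropna()
    raw = labels.unique().tolist()
    keys = {}
    for lab in raw:
        members = labels.index[labels == lab]
        key = []
        for measure in ORDERING_MEASURES:
            vals = clinical.measure(measure).reindex(members).dropna()
            key.append(-vals.mean() if len(vals) else np.inf)
        keys[lab] = tuple(key)
    ordered = sorted(raw, key=lambda lab: keys[lab])
    mapping = {lab: f"C{i + 1}" for i, lab in enumerate(ordered)}
    renamed = labels.map(mapping)
    renamed.index.name = "sample_id"
    return ClusterAssignment(
        labels=renamed,
        k=len(raw),
        trace=trace if trace is not None else pd.DataFrame(),
    )
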