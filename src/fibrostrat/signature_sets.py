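"""Gene signatures derived from per-cluster DEG sets.

Given the DEG set (with direction) of each patient cluster versus
control, builds: overlap groups (in how many clusters each gene is a
DEG), the core set (DEG in every cluster), cluster-unique sets (DEG in
exactly one cluster; the most severe cluster's unique set is the
"advanced" signature), and co-expression gene modules obtained by
hierarchical clustering of genes with 1 - Pearson correlation distance
and complete linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from fibrostrat.io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DegSets = dict[str, dict[str, str]]  # cluster -> {gene: 'up'|'down'}


@dataclass
class GeneSignature:
    """A named gene set with per-cluster direction and provenance."""

    name: str
    genes: list[str]
    directions: pd.DataFrame = field(default_factory=pd.DataFrame)  # gene x cluster
    discordant: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def _directions_frame(deg_sets: DegSets, genes: list[str]) -> pd.DataFrame:
    clusters = list(deg_sets)
    frame = pd.DataFrame(index=genes, columns=clusters, dtype=object)
    for cluster, gene_dirs in deg_sets.items():
        for gene in genes:
            frame.loc[gene, cluster] = gene_dirs.get(gene)
    return frame


def overlap_groups(deg_sets: DegSets) -> dict[str, int]:
    """Number of clusters in which each DEG-union gene is a DEG."""
    if not deg_sets:
        raise ValueError("need at least one cluster DEG set")
    counts: dict[str, int] = {}
    for gene_dirs in deg_sets.values():
        for gene in gene_dirs:
            counts[gene] = counts.get(gene, 0) + 1
    return counts


def core_set(deg_sets: DegSets, name: str = "core") -> GeneSignature:
    """Genes differentially expressed in every cluster.

    Per-cluster direction is recorded; genes up in some clusters and
    down in others are flagged discordant (recorded, not resolved).
    """
    if not deg_sets:
        raise ValueError("need at least one cluster DEG set")
    clusters = list(deg_sets)
    counts = overlap_groups(deg_sets)
    genes = [g for g, c in counts.items() if c == len(clusters)]
    directions = _directions_frame(deg_sets, genes)
    discordant = {
        g for g in genes if len({d for d in directions.loc[g] if d is not None}) > 1
    }
    return GeneSignature(
        name=name,
        genes=genes,
        directions=directions,
        discordant=discordant,
        provenance={"kind": "core", "clusters": clusters},
    )


def unique_set(deg_sets: DegSets, cluster: str, name: str | None = None) -> GeneSignature:
    """Genes that are DEG in ``cluster`` and in no other cluster."""
    if cluster not in deg_sets:
        raise KeyError(f"unknown cluster {cluster!r}")
    counts = overlap_groups(deg_sets)
    genes = [g for g in deg_sets[cluster] if counts[g] == 1]
    directions = _directions_frame({cluster: deg_sets[cluster]}, genes)
    return GeneSignature(
        name=name or f"{cluster}_unique",
        genes=genes,
        directions=directions,
        provenance={"kind": "unique", "cluster": cluster},
    )


def advanced_set(deg_sets: DegSets, severity_ordered_clusters: list[str]) -> GeneSignature:
    """Unique set of the most severe cluster, exported as "advanced"."""
    most_severe = severity_ordered_clusters[-1]
    return unique_set(deg_sets, most_severe, name="advanced")


def gene_modules(m: ExpressionMatrix, n_modules: int = 3) -> pd.Series:
    """Co-expression modules of the DEG union.

    Hierarchical clustering of genes with distance 1 - Pearson
    correlation across samples and complete linkage, cut at
    ``n_modules``.  Constant gene rows (undefined correlation) are
    treated as zero-correlated with everything, with a warning.
    """
    n_genes = m.shape[0]
    if n_modules < 1 or n_modules > n_genes:
        raise ValueError(f"n_modules must be in [1, {n_genes}]")
    if n_modules == n_genes:
        return pd.Series(np.arange(1, n_genes + 1), index=m.gene_ids, name="module")
    values = m.values
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "gene_modules: %d constant genes assigned zero correlation", int(constant.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=n_modules, criterion="maxclust")
    return pd.Series(labels, index=m.gene_ids, name="module")


def signatures_to_collection(signatures: list[GeneSignature]) -> GeneSetCollection:
    """Export signatures as a GMT-ready collection."""
    coll = GeneSetCollection()
    for sig in signatures:
        coll.add(sig.name, sig.provenance.get("kind", ""), sig.genes)
    return coll


def directions_table(signatures: list[GeneSignature]) -> pd.DataFrame:
    """Long-format per-signature, per-cluster direction table."""
    rows = []
    for sig in signatures:
        for gene in sig.genes:
            if sig.directions.empty:
                continue
            for cluster in sig.directions.columns:
                direction = sig.directions.loc[gene, cluster]
                if direction is not None:
                    rows.append(
                        {
                            "signature": sig.name,
                            "gene": gene,
                            "cluster": cluster,
                            "direction": direction,
                        }
                    )
    return pd.DataFrame(rows, columns=["signature", "gene", "cluster", "direction"])
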