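"""Candidate gene prioritization by functional similarity and fold change.

Enrichment is a one-sided hypergeometric test per annotation term with
BH correction within each annotation category.  Functional similarity
of a candidate gene to the known-disease training set is a documented
local surrogate for web-service gene prioritizers: the sum, over
training-set-enriched terms (q <= 0.05) that also annotate the
candidate, of -log10(q).  Candidates are ranked separately by
similarity and by |log2 fold change|, the ranks are aggregated by the
rank product (geometric mean of ranks, average-rank ties), known genes
are removed, and the top fraction (default 10%) is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from fibrostrat.io_formats import GeneSetCollection, read_gmt

logger = logging.getLogger(__name__)

#: annotation feature categories mirrored from gene-prioritization practice
DEFAULT_CATEGORIES = (
    "GO_Biological_Process",
    "GO_Cellular_Component",
    "Human_Phenotype",
    "Mouse_Phenotype",
    "Pathway",
    "Disease",
)


@dataclass
class AnnotationDB:
    """Term -> gene-set annotations grouped into named categories."""

    categories: dict[str, GeneSetCollection] = field(default_factory=dict)

    @classmethod
    def from_gmt_dir(cls, directory: str | Path) -> "AnnotationDB":
        """One GMT per category; the file stem names the category."""
        db = cls()
        for path in sorted(Path(directory).glob("*.gmt")):
            db.categories[path.stem] = read_gmt(path)
        if not db.categories:
            raise FileNotFoundError(f"no .gmt files in {directory}")
        return db

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for coll in self.categories.values():
            out |= coll.all_genes()
        return out

    def terms_annotating(self, gene: str) -> set[tuple[str, str]]:
        out = set()
        for cat, coll in self.categories.items():
            for term, (_, genes) in coll.sets.items():
                if gene in genes:
                    out.add((cat, term))
        return out


def enrich_terms(
    query: set[str],
    universe: set[str],
    db: AnnotationDB,
    fdr_max: float = 0.05,
    per_category_bh: bool = True,
) -> pd.DataFrame:
    """Hypergeometrically enriched annotation terms of a query set.

    One-sided p = P(overlap >= observed) with the universe as the urn;
    BH within each category by default.  Returns terms with
    q <= fdr_max, columns category, term, overlap, term_size,
    query_size, p, q.
    """
    if not query:
        raise ValueError("empty query gene set")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    from fibrostrat.diffexpr import bh_adjust  # local import avoids a cycle

    M = len(universe)
    N = len(query)
    rows = []
    for cat, coll in db.categories.items():
        for term, (_, genes) in coll.sets.items():
            term_genes = set(genes) & universe
            K = len(term_genes)
            if K == 0:
                continue
            k = len(term_genes & query)
            p = float(hypergeom.sf(k - 1, M, K, N))
            rows.append(
                {
                    "category": cat,
                    "term": term,
                    "overlap": k,
                    "term_size": K,
                    "query_size": N,
                    "p": min(p, 1.0),
                }
            )
    table = pd.DataFrame(rows, columns=["category", "term", "overlap", "term_size", "query_size", "p"])
    if table.empty:
        return table.assign(q=pd.Series(dtype=float))
    if per_category_bh:
        table["q"] = table.groupby("category", sort=False)["p"].transform(
            lambda col: bh_adjust(col.to_numpy())
        )
    else:
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table[table["q"] <= fdr_max].reset_index(drop=True)


def _similarity_from_enrichment(
    gene: str, enriched: pd.DataFrame, db: AnnotationDB
) -> float:
    score = 0.0
    for row in enriched.itertuples():
        genes = db.categories[row.category].genes(row.term)
        if gene in genes:
            score += -math.log10(max(row.q, 1e-300))
    return score


def functional_similarity(
    gene: str,
    training: set[str],
    db: AnnotationDB,
    universe: set[str],
    enriched: pd.DataFrame | None = None,
) -> float:
    """Similarity of one gene to the training set (local surrogate
    score; see module docstring).  Pass ``enriched`` to reuse a
    precomputed training-set enrichment."""
    if not training:
        raise ValueError("training gene set is empty")
    if gene not in db.annotated_genes():
        logger.warning("gene %r absent from annotation DB; similarity 0", gene)
        return 0.0
    if enriched is None:
        enriched = enrich_terms(training & universe, universe, db)
    return _similarity_from_enrichment(gene, enriched, db)


def similarity_scores(
    genes: list[str],
    training: set[str],
    db: AnnotationDB,
    universe: set[str],
) -> pd.Series:
    """Vectorized similarity for many candidates (one enrichment pass)."""
    if not training:
        raise ValueError("training gene set is empty")
    enriched = enrich_terms(training & universe, universe, db)
    annotated = db.annotated_genes()
    scores = {}
    # membership lookup per enriched term, computed once
    term_members = [
        (set(db.categories[row.category].genes(row.term)), -math.log10(max(row.q, 1e-300)))
        for row in enriched.itertuples()
    ]
    for gene in genes:
        if gene not in annotated:
            scores[gene] = 0.0
            continue
        scores[gene] = sum(w for members, w in term_members if gene in members)
    return pd.Series(scores, name="similarity")


def rank_product(rank_lists: pd.DataFrame) -> pd.DataFrame:
    """Aggregate two or more rank vectors by their geometric mean.

    ``rank_lists``: genes x criteria, positive ranks.  Returns a frame
    with the rank product ``rp`` and the final rank (ascending rp,
    average-rank ties).
    """
    if rank_lists.shape[1] < 2:
        raise ValueError("need at least two rank criteria")
    values = rank_lists.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("rank lists must cover the same genes (no missing ranks)")
    if (values <= 0).any():
        raise ValueError("ranks must be positive")
    rp = np.exp(np.log(values).mean(axis=1))
    out = pd.DataFrame({"rp": rp}, index=rank_lists.index)
    out["final_rank"] = rankdata(rp)
    return out


def prioritize_candidates(
    signature_genes: list[str],
    de: pd.DataFrame,
    training: set[str],
    db: AnnotationDB,
    universe: set[str],
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Rank unknown signature genes by rank product of similarity and
    fold-change ranks; return the top fraction.

    Known genes (in the training set) are removed before ranking.  The
    fold change used is the largest |log2FC| over the contrasts in
    which the gene is a DEG (falling back to all contrasts for genes
    never flagged).  Output columns: gene, similarity,
    similarity_rank, abs_lfc, fc_rank, rp, final_rank, selected.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    unknown = [g for g in signature_genes if g not in training]
    if not unknown:
        raise ValueError("every signature gene is a known training gene")
    de_sig = de[de["gene"].isin(unknown)].copy()
    missing = set(unknown) - set(de_sig["gene"])
    if missing:
        raise ValueError(f"signature genes lack DE results: {sorted(missing)[:5]}")
    de_sig["abs_lfc"] = de_sig["lfc"].abs()
    deg_rows = de_sig[de_sig["deg"]]
    fc = deg_rows.groupby("gene")["abs_lfc"].max()
    fc = fc.reindex(unknown)
    fallback = de_sig.groupby("gene")["abs_lfc"].max().reindex(unknown)
    fc = fc.fillna(fallback)

    sim = similarity_scores(unknown, training, db, universe).reindex(unknown)
    records = pd.DataFrame({"gene": unknown, "similarity": sim.to_numpy(), "abs_lfc": fc.to_numpy()})
    # high similarity / high fold change -> small (good) rank; average ties
    records["similarity_rank"] = rankdata(-records["similarity"])
    records["fc_rank"] = rankdata(-records["abs_lfc"])
    agg = rank_product(records.set_index("gene")[["similarity_rank", "fc_rank"]])
    records["rp"] = agg["rp"].to_numpy()
    records["final_rank"] = agg["final_rank"].to_numpy()
    records["is_known"] = False
    n_top = math.ceil(top_fraction * len(records))
    records = records.sort_values(["final_rank", "gene"], kind="stable").reset_index(drop=True)
    records["selected"] = np.arange(len(records)) < n_top
    return records
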