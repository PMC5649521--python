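"""Expression preprocessing: duplicate aggregation, log2, median
centering, per-gene min-max scaling and variable-gene selection.

The analysis representation throughout the pipeline is log2 intensity,
median-centered per gene.  Classifiers additionally scale each gene to
(0, 1) with a reference learned on the training cohort; validation
values falling outside the training range are clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fibrostrat.io_formats import ExpressionMatrix


def aggregate_duplicate_genes(m: ExpressionMatrix, method: str = "median") -> ExpressionMatrix:
    """Collapse duplicate gene rows to one row per gene id.

    ``method`` is ``median`` (default; robust to one aberrant probe) or
    ``mean``.  Output gene order is first-occurrence order.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if not m.has_duplicate_genes:
        return m.copy()
    grouped = m.data.groupby(level=0, sort=False)
    agg = grouped.median() if method == "median" else grouped.mean()
    return ExpressionMatrix(agg)


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Element-wise ``log2(value + offset)``.

    Raises if any shifted value is nonpositive, naming offending genes.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    shifted = m.values + offset
    bad = (shifted <= 0).any(axis=1)
    if bad.any():
        genes = [g for g, b in zip(m.gene_ids, bad) if b]
        raise ValueError(
            f"log2 undefined: {bad.sum()} genes have values <= -offset, e.g. {genes[:5]}"
        )
    return ExpressionMatrix(pd.DataFrame(np.log2(shifted), index=m.data.index, columns=m.data.columns))


def median_center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples (median normalization)."""
    if m.shape[1] < 1:
        raise ValueError("need at least one sample")
    centered = m.data.sub(m.data.median(axis=1), axis=0)
    return ExpressionMatrix(centered)


def standardize_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene and scale it to unit variance across samples.

    Used for the clustering feature space so that a handful of
    high-noise genes cannot dominate Euclidean distances; constant
    genes are left at zero.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least two samples")
    sd = m.data.std(axis=1, ddof=1)
    centered = m.data.sub(m.data.mean(axis=1), axis=0)
    return ExpressionMatrix(centered.div(sd.where(sd > 0, 1.0), axis=0))


@dataclass
class ScalingReference:
    """Per-gene (min, max) learned on a training cohort, post median
    normalization, used to map expression to (0, 1)."""

    minima: pd.Series
    maxima: pd.Series

    def __post_init__(self) -> None:
        if not (self.maxima >= self.minima).all():
            raise ValueError("per-gene max must be >= min")

    @property
    def genes(self) -> list[str]:
        return self.minima.index.tolist()


def fit_minmax(m: ExpressionMatrix) -> ScalingReference:
    return ScalingReference(minima=m.data.min(axis=1), maxima=m.data.max(axis=1))


def apply_minmax(m: ExpressionMatrix, ref: ScalingReference) -> ExpressionMatrix:
    """Scale each gene to [0, 1] using the training reference.

    Out-of-range values (validation cohorts) are clipped; a constant
    training gene (max == min) maps to 0.5 everywhere.
    """
    missing = [g for g in ref.genes if g not in m.data.index]
    if missing:
        raise KeyError(f"matrix lacks reference genes: {missing[:5]}")
    sub = m.data.loc[ref.genes]
    span = ref.maxima - ref.minima
    constant = span == 0
    span_safe = span.where(~constant, 1.0)
    scaled = sub.sub(ref.minima, axis=0).div(span_safe, axis=0).clip(0.0, 1.0)
    if constant.any():
        scaled.loc[constant.index[constant]] = 0.5
    return ExpressionMatrix(scaled)


def top_variable_genes(m: ExpressionMatrix, fraction: float = 0.25) -> list[str]:
    """Gene ids with the largest sample variance (unbiased, n-1).

    Returns ``ceil(fraction * n_genes)`` genes; ties broken by input
    order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if m.shape[1] < 2:
        raise ValueError("need at least two samples to rank variance")
    n_keep = math.ceil(fraction * m.shape[0])
    variances = m.data.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-variances, kind="stable")[:n_keep]
    genes = m.gene_ids
    return [genes[i] for i in order]
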