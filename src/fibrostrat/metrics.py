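"""Small recovery metrics used by truth-based tests and reports."""

from __future__ import annotations

import pandas as pd
from sklearn.metrics import adjusted_rand_score


def adjusted_rand_index(truth: pd.Series, predicted: pd.Series) -> float:
    """Chance-corrected agreement between two partitions of the same
    samples (1 = identical up to relabeling, ~0 = random)."""
    truth, predicted = truth.align(predicted, join="inner")
    if truth.isna().any() or predicted.isna().any():
        raise ValueError("partitions must label every shared sample")
    return float(adjusted_rand_score(truth.astype(str), predicted.astype(str)))


def jaccard(a: set, b: set) -> float:
    """|A intersect B| / |A union B|; 1.0 for two empty sets."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)
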