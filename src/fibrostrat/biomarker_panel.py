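"""Minimal secreted-protein biomarker panel search.

Candidates are the secreted/BALF-annotated members of the core
signature, ordered by the magnitude of their coefficients in a full
logistic model.  A series of nested logistic classifiers on the top-k
candidates (k = 1..k_max), each with its decision threshold calibrated
to a sensitivity floor (or to maximal training accuracy), yields a
per-size metric trace; the selected panel is the smallest k whose
metrics satisfy specificity > 0.8 (strict) and sensitivity >= 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fibrostrat.classifier_eval import (
    DEFAULT_SEED,
    SignatureClassifier,
    build_signature_classifier,
    calibrate_threshold,
    evaluate,
)
from fibrostrat.io_formats import ExpressionMatrix
from fibrostrat.preprocess import apply_minmax, fit_minmax
from fibrostrat.signature_sets import GeneSignature

logger = logging.getLogger(__name__)


def filter_secreted(core: GeneSignature | list[str], secreted: set[str]) -> list[str]:
    """Core-signature genes annotated as secreted / BALF-detectable,
    core order preserved."""
    genes = core.genes if isinstance(core, GeneSignature) else list(core)
    keep = [g for g in genes if g in secreted]
    if not keep:
        raise ValueError(
            "no core gene carries a secreted/BALF annotation; check the annotation gene sets"
        )
    return keep


def rank_by_coefficient(clf: SignatureClassifier) -> list[str]:
    """Genes sorted by |coefficient| descending, input order on ties."""
    magnitudes = np.abs(clf.coefficients)
    order = np.argsort(-magnitudes, kind="stable")
    return [clf.genes[i] for i in order]


@dataclass
class PanelSearchResult:
    """Outcome of the nested panel search."""

    ordered_genes: list[str]
    trace: pd.DataFrame  # one row per k: sensitivity, specificity, accuracy, threshold
    selected_panel: list[str]
    criterion_met: bool
    params: dict = field(default_factory=dict)


def _accuracy_threshold(scores: pd.Series, labels: pd.Series) -> float:
    """Threshold maximizing training accuracy (highest on ties)."""
    from fibrostrat.classifier_eval import _binary

    y = _binary(labels, scores.index)
    s = scores.to_numpy(dtype=float)
    best_thr, best_acc = 1.0, -1.0
    for thr in np.unique(np.concatenate((s, [1.0])))[::-1]:
        acc = ((s >= thr) == (y == 1)).mean()
        if acc > best_acc:
            best_thr, best_acc = float(thr), float(acc)
    return min(max(best_thr, 0.0), 1.0)


def nested_panel_search(
    m: ExpressionMatrix,
    labels: pd.Series,
    ordered_genes: list[str],
    k_max: int = 50,
    min_specificity: float = 0.8,
    min_sensitivity: float = 0.9,
    seed: int = DEFAULT_SEED,
    l2_strength: float = 1.0,
    calibrate: str = "sensitivity",
    eval_m: ExpressionMatrix | None = None,
    eval_labels: pd.Series | None = None,
) -> PanelSearchResult:
    """Train nested top-k classifiers and pick the minimal adequate k.

    ``calibrate`` is ``sensitivity`` (threshold set for >=
    min_sensitivity, the default) or ``accuracy`` (threshold
    maximizing accuracy).  Metrics are computed on the training cohort
    unless an evaluation cohort is supplied, in which case the
    threshold is calibrated on the evaluation scores as well: a panel
    qualifies when its classifier *admits* an operating point with the
    required sensitivity and specificity on that cohort (an ROC
    dominance check), rather than when a training-derived threshold
    happens to transfer.  When no k satisfies the criterion the result
    carries an empty panel and ``criterion_met = False``.
    """
    if calibrate not in ("sensitivity", "accuracy"):
        raise ValueError("calibrate must be 'sensitivity' or 'accuracy'")
    if k_max > len(ordered_genes):
        logger.warning(
            "k_max %d exceeds %d candidates; truncated", k_max, len(ordered_genes)
        )
        k_max = len(ordered_genes)
    if k_max < 1:
        raise ValueError("need at least one candidate gene")
    rows = []
    selected: list[str] = []
    criterion_met = False
    for k in range(1, k_max + 1):
        panel = ordered_genes[:k]
        sub = m.subset_genes(panel)
        scaler = fit_minmax(sub)
        from fibrostrat.classifier_eval import train_logistic

        clf = train_logistic(
            apply_minmax(sub, scaler), labels, l2_strength=l2_strength, seed=seed,
            scaler=scaler,
        )
        target_m = eval_m.subset_genes(panel) if eval_m is not None else sub
        target_labels = eval_labels if eval_labels is not None else labels
        calib_scores = clf.decision_scores(target_m)
        if calibrate == "sensitivity":
            clf.threshold = calibrate_threshold(calib_scores, target_labels, min_sensitivity)
        else:
            clf.threshold = _accuracy_threshold(calib_scores, target_labels)
        report = evaluate(clf, target_m, target_labels, cohort=f"k={k}")
        rows.append(
            {
                "k": k,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "accuracy": report.accuracy,
                "threshold": clf.threshold,
            }
        )
        if (
            not criterion_met
            and report.specificity > min_specificity
            and report.sensitivity >= min_sensitivity
        ):
            criterion_met = True
            selected = panel
    trace = pd.DataFrame(rows)
    return PanelSearchResult(
        ordered_genes=list(ordered_genes[:k_max]),
        trace=trace,
        selected_panel=selected,
        criterion_met=criterion_met,
        params={
            "k_max": k_max,
            "min_specificity": min_specificity,
            "min_sensitivity": min_sensitivity,
            "seed": seed,
            "l2_strength": l2_strength,
            "calibrate": calibrate,
            "evaluated_on": "validation" if eval_m is not None else "training",
        },
    )


def panel_pipeline(
    m: ExpressionMatrix,
    labels: pd.Series,
    core: GeneSignature | list[str],
    secreted: set[str],
    k_max: int = 50,
    min_specificity: float = 0.8,
    min_sensitivity: float = 0.9,
    seed: int = DEFAULT_SEED,
    l2_strength: float = 1.0,
) -> PanelSearchResult:
    """Full panel stage: filter to secreted candidates, rank by full-model
    coefficients, then run the nested search."""
    candidates = filter_secreted(core, secreted)
    full_clf = build_signature_classifier(
        m, labels, candidates, l2_strength=l2_strength, seed=seed,
        min_sensitivity=min_sensitivity,
    )
    ordered = rank_by_coefficient(full_clf)
    return nested_panel_search(
        m,
        labels,
        ordered,
        k_max=k_max,
        min_specificity=min_specificity,
        min_sensitivity=min_sensitivity,
        seed=seed,
        l2_strength=l2_strength,
    )
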