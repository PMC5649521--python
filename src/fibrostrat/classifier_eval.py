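"""Logistic signature classifiers with sensitivity-floor calibration.

A signature classifier is an L2-regularized logistic regression over a
gene signature's (0, 1)-scaled expression.  Its decision threshold on
the predicted disease probability is calibrated to guarantee at least
a given sensitivity (default 90%) on training scores, choosing the
threshold that maximizes specificity subject to that floor.  Stratified
2-fold cross-validation (scaling refit within each training fold)
estimates generalization before the final classifier is trained on the
full training cohort and evaluated on held-out cohorts with ROC / AUC /
sensitivity / specificity / accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from fibrostrat.io_formats import ExpressionMatrix
from fibrostrat.preprocess import ScalingReference, apply_minmax, fit_minmax

POSITIVE = "disease"
NEGATIVE = "control"
DEFAULT_SEED = 17


def restrict_signature(
    signature: list[str], cohorts: list[ExpressionMatrix]
) -> list[str]:
    """Signature genes measured in every cohort, original order kept."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    keep = [g for g in signature if all(g in c.data.index for c in cohorts)]
    if not keep:
        raise ValueError("signature has no gene present in all cohorts")
    return keep


@dataclass
class SignatureClassifier:
    """Trained logistic signature classifier.

    ``scaler`` (per-gene min/max from the training cohort) is applied
    before scoring; ``threshold`` converts the predicted disease
    probability into a call.
    """

    genes: list[str]
    coefficients: np.ndarray
    intercept: float
    scaler: ScalingReference | None = None
    threshold: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.genes):
            raise ValueError("one coefficient per gene required")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def decision_scores(self, m: ExpressionMatrix) -> pd.Series:
        """Predicted disease probability per sample (scaling applied)."""
        missing = [g for g in self.genes if g not in m.data.index]
        if missing:
            raise KeyError(f"cohort lacks classifier genes: {missing[:5]}")
        if self.scaler is not None:
            m = apply_minmax(m, self.scaler)
        X = m.data.loc[self.genes].to_numpy().T
        z = X @ self.coefficients + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=m.sample_ids)

    def predict(self, m: ExpressionMatrix) -> pd.Series:
        scores = self.decision_scores(m)
        return pd.Series(
            np.where(scores >= self.threshold, POSITIVE, NEGATIVE), index=scores.index
        )


def train_logistic(
    m: ExpressionMatrix,
    labels: pd.Series,
    l2_strength: float = 1.0,
    seed: int = DEFAULT_SEED,
    scaler: ScalingReference | None = None,
) -> SignatureClassifier:
    """L2-regularized maximum-likelihood logistic fit.

    ``m`` must already be scaled (pass ``scaler`` so the classifier can
    reproduce the scaling at prediction time).  Deterministic given the
    data; the seed is recorded in the metadata.
    """
    y = (labels.reindex(m.sample_ids) == POSITIVE).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    # ridge-penalized logistic: C is the inverse penalty strength
    model = LogisticRegression(
        C=1.0 / l2_strength,
        solver="lbfgs",
        max_iter=5000,
        random_state=seed,
    )
    model.fit(m.values.T, y)
    return SignatureClassifier(
        genes=m.gene_ids,
        coefficients=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
        scaler=scaler,
        meta={"l2_strength": l2_strength, "seed": seed, "n_train": len(y)},
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Classifier performance on one cohort."""

    cohort: str
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    confusion: dict[str, int]
    roc: pd.DataFrame  # columns fpr, tpr, thr

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "threshold": self.threshold,
            "confusion": self.confusion,
            "roc": self.roc.to_dict(orient="records"),
        }


def _binary(labels: pd.Series, index) -> np.ndarray:
    y = (labels.reindex(index) == POSITIVE).astype(int).to_numpy()
    return y


def roc_curve(scores: pd.Series, labels: pd.Series) -> tuple[pd.DataFrame, float]:
    """ROC points over unique score thresholds and the Mann-Whitney AUC.

    The AUC is the probability that a random positive outscores a
    random negative, ties counting one half.
    """
    y = _binary(labels, scores.index)
    s = scores.to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes needed for a ROC curve")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    rows = []
    for thr in thresholds:
        pred = s >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        rows.append({"fpr": fp / n_neg, "tpr": tp / n_pos, "thr": thr})
    roc = pd.DataFrame(rows)
    ranks = rankdata(s)  # average ranks -> half-weight for ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return roc, float(auc)


def calibrate_threshold(
    scores: pd.Series, labels: pd.Series, min_sensitivity: float = 0.9
) -> float:
    """Threshold meeting the sensitivity floor with maximal specificity.

    Among thresholds whose sensitivity on the given scores is at least
    the floor, specificity is maximized first and sensitivity breaks
    specificity ties (so perfectly separated scores yield a threshold
    in the gap with sensitivity and specificity both 1); remaining ties
    go to the highest qualifying score gap, and the returned threshold
    sits mid-gap so the operating point transfers robustly to held-out
    cohorts.  A sample is called positive when its
    score is >= the threshold, so a threshold at the lowest positive
    score always achieves sensitivity 1 and the floor is always
    attainable.
    """
    if min_sensitivity > 1:
        raise ValueError("min_sensitivity cannot exceed 1")
    y = _binary(labels, scores.index)
    if y.sum() == 0:
        raise ValueError("no positive samples to calibrate against")
    s = scores.to_numpy(dtype=float)
    candidates = np.unique(np.concatenate((s, [1.0])))[::-1]
    best_thr, best_key, found = None, (-1.0, -1.0), False
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    for thr in candidates:  # descending: first hit at a (spec, sens) level is the highest thr
        pred = s >= thr
        sens = (pred & (y == 1)).sum() / n_pos
        spec = 1.0 if n_neg == 0 else (~pred & (y == 0)).sum() / n_neg
        if sens >= min_sensitivity and (spec, sens) > best_key:
            best_thr, best_key, found = float(thr), (float(spec), float(sens)), True
    if not found:  # unreachable: thr = min(scores) gives sensitivity 1
        raise RuntimeError("no threshold satisfies the sensitivity floor")
    # any threshold in (next lower score, best_thr] yields the same
    # confusion counts; the midpoint of that gap maximizes the margin on
    # both sides and so transfers best to unseen cohorts
    lower = s[s < best_thr]
    gap_low = float(lower.max()) if lower.size else 0.0
    return min(max((gap_low + best_thr) / 2.0, 0.0), 1.0)


def evaluate(
    clf: SignatureClassifier,
    m: ExpressionMatrix,
    labels: pd.Series,
    cohort: str = "cohort",
) -> EvalReport:
    """Apply the stored scaling and threshold; report confusion counts,
    accuracy, sensitivity, specificity, ROC and AUC."""
    scores = clf.decision_scores(m)
    y = _binary(labels, scores.index)
    pred = scores.to_numpy() >= clf.threshold
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    roc, auc = roc_curve(scores, labels)
    return EvalReport(
        cohort=cohort,
        auc=auc,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / len(y),
        threshold=clf.threshold,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        roc=roc,
    )


def cross_validate(
    m: ExpressionMatrix,
    labels: pd.Series,
    folds: int = 2,
    seed: int = DEFAULT_SEED,
    l2_strength: float = 1.0,
    min_sensitivity: float = 0.9,
) -> list[EvalReport]:
    """Stratified k-fold cross-validation of the signature classifier.

    The (0, 1) scaling reference and the decision threshold are fit
    within each training fold only, then applied to the held-out fold.
    """
    y = _binary(labels, m.sample_ids)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} samples for {folds}-fold CV")
    samples = np.array(m.sample_ids)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for i, (train_idx, test_idx) in enumerate(skf.split(samples, y)):
        train_m = m.subset_samples(samples[train_idx].tolist())
        test_m = m.subset_samples(samples[test_idx].tolist())
        scaler = fit_minmax(train_m)
        clf = train_logistic(
            apply_minmax(train_m, scaler), labels, l2_strength=l2_strength, seed=seed,
            scaler=scaler,
        )
        clf.threshold = calibrate_threshold(
            clf.decision_scores(train_m), labels, min_sensitivity
        )
        reports.append(evaluate(clf, test_m, labels, cohort=f"fold{i + 1}"))
    return reports


def build_signature_classifier(
    train_m: ExpressionMatrix,
    labels: pd.Series,
    signature: list[str],
    l2_strength: float = 1.0,
    seed: int = DEFAULT_SEED,
    min_sensitivity: float = 0.9,
) -> SignatureClassifier:
    """Restrict, scale, train on the full training cohort and calibrate
    the threshold to the sensitivity floor on training scores."""
    sig = restrict_signature(signature, [train_m])
    sub = train_m.subset_genes(sig)
    scaler = fit_minmax(sub)
    clf = train_logistic(
        apply_minmax(sub, scaler), labels, l2_strength=l2_strength, seed=seed, scaler=scaler
    )
    clf.threshold = calibrate_threshold(clf.decision_scores(sub), labels, min_sensitivity)
    return clf
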