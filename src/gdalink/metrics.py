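"""Link-classification metrics from first principles.

Implements precision/recall at a threshold, average precision as the
step-sum over recall increments, the ROC curve (one operating point per
distinct score, prediction rule ``score >= threshold``), trapezoidal AUC
(equal to the Mann–Whitney pair statistic with ties credited 1/2), and
Youden's J = sensitivity + specificity − 1 for best-threshold selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class ScoredLabels:
    """Paired score and binary-label vectors for threshold-based evaluation."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        y = np.asarray(self.labels)
        if s.shape != y.shape or s.ndim != 1 or s.size == 0:
            raise ValidationError("scores and labels must be equal-length 1-D, non-empty")
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("labels must be binary")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y.astype(np.int64))


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points at descending thresholds.

    ``thresholds[0]`` is +inf (nothing predicted positive, the (0, 0)
    corner); the last threshold is the minimum score, where everything is
    predicted positive, the (1, 1) corner.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def _as_scored(scored, labels=None) -> ScoredLabels:
    if labels is not None:
        return ScoredLabels(np.asarray(scored), np.asarray(labels))
    return scored


def precision_recall(scored: ScoredLabels, threshold: float) -> tuple[float, float]:
    """Precision and recall under the rule score >= threshold => positive.

    With zero predicted positives, precision is reported as 1 by the usual
    precision–recall-curve convention.
    """
    pred = scored.scores >= threshold
    tp = int(np.sum(pred & (scored.labels == 1)))
    fp = int(np.sum(pred & (scored.labels == 0)))
    fn = int(np.sum(~pred & (scored.labels == 1)))
    precision = 1.0 if (tp + fp) == 0 else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    return precision, recall


def average_precision(scored: ScoredLabels) -> float:
    """AP = sum_n (recall_n − recall_{n−1}) · precision_n over the ranked list.

    Operating points are taken at every distinct score (tied scores collapse
    to a single point), recall increasing as the threshold drops.
    """
    y = scored.labels
    p = int(y.sum())
    if p == 0:
        raise ValidationError("average precision needs at least one positive")

    order = np.argsort(-scored.scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scored.scores[order]
    tp = np.cumsum(y_sorted)
    n_pred = np.arange(1, y.size + 1)
    # keep only the last index of each tied block = the full >=threshold set
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp[last_of_block]
    n_pred = n_pred[last_of_block]
    recall = tp / p
    precision = tp / n_pred
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def roc_curve(scored: ScoredLabels) -> RocCurve:
    """ROC curve with one point per distinct score plus the (0, 0) corner."""
    y = scored.labels
    p = int(y.sum())
    n = y.size - p
    if p == 0 or n == 0:
        raise ValidationError("ROC needs at least one positive and one negative")

    order = np.argsort(-scored.scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scored.scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    thresholds = np.r_[np.inf, s_sorted[last_of_block]]
    tpr = np.r_[0.0, tp[last_of_block] / p]
    fpr = np.r_[0.0, fp[last_of_block] / n]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc(curve_or_scored, labels=None) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Accepts a RocCurve, a ScoredLabels, or raw (scores, labels).  Because
    tied scores collapse to one operating point, the trapezoid through a tie
    block credits exactly half, so this equals the Mann–Whitney statistic
    P(score_pos > score_neg) + 0.5 · P(tie).
    """
    if isinstance(curve_or_scored, RocCurve):
        curve = curve_or_scored
    else:
        curve = roc_curve(_as_scored(curve_or_scored, labels))
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_best_threshold(curve_or_scored, labels=None) -> tuple[float, float]:
    """Best classification threshold by Youden's index.

    J = sensitivity + specificity − 1 = TPR − FPR, maximised over the ROC
    operating points.  Ties in J are broken toward the higher threshold
    (the more conservative cut-off).  Returns (threshold, J).
    """
    if isinstance(curve_or_scored, RocCurve):
        curve = curve_or_scored
    else:
        curve = roc_curve(_as_scored(curve_or_scored, labels))
    j = curve.tpr - curve.fpr
    best = int(np.argmax(j))  # thresholds descend, argmax takes the first/highest
    return float(curve.thresholds[best]), float(j[best])


def evaluation_report(scores: np.ndarray, labels: np.ndarray) -> dict:
    """AUC, AP, and Youden best threshold as a JSON-ready dict."""
    scored = ScoredLabels(np.asarray(scores), np.asarray(labels))
    curve = roc_curve(scored)
    threshold, j = youden_best_threshold(curve)
    return {
        "auc": auc(curve),
        "ap": average_precision(scored),
        "best_threshold": threshold,
        "youden_j": j,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_roc_tsv(curve: RocCurve, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        for t, f, s in zip(curve.thresholds, curve.fpr, curve.tpr):
            fh.write(f"{t!r}\t{f!r}\t{s!r}\n")
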