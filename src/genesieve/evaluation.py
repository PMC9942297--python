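"""Classifier evaluation: confusion-matrix metrics (accuracy, precision,
recall, F1, G-mean), ROC/AUC and precision-recall/AUPR curves, and
averaging across replicate cycles.

Ratios with a zero denominator are reported as NaN, never coerced to 0, so
replicate averages can exclude them with an explicit count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

NAN = float("nan")


@dataclass
class MetricsReport:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    accuracy: float = NAN
    precision: float = NAN
    recall: float = NAN
    f1: float = NAN
    g_mean: float = NAN
    auc: float = NAN
    aupr: float = NAN
    roc: list[tuple[float, float]] = field(default_factory=list)
    pr: list[tuple[float, float]] = field(default_factory=list)

    SCALARS = ("accuracy", "auc", "precision", "recall", "f1", "g_mean", "aupr")

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in ("tp", "fp", "tn", "fn")}
        d.update({k: getattr(self, k) for k in self.SCALARS})
        return d


def _ratio(num: float, den: float) -> float:
    return num / den if den else NAN


def confusion_metrics(labels, predictions) -> MetricsReport:
    """Scalar metrics from binary labels and binary predictions.

    accuracy = (TP+TN)/n, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R), G-mean = sqrt(recall * TN/(TN+FP)).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("labels and predictions must be equal-length, non-empty")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    rep = MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)
    rep.accuracy = _ratio(tp + tn, tp + fp + tn + fn)
    rep.precision = _ratio(tp, tp + fp)
    rep.recall = _ratio(tp, tp + fn)
    if np.isnan(rep.precision) or np.isnan(rep.recall) or (rep.precision + rep.recall) == 0:
        rep.f1 = NAN
    else:
        rep.f1 = 2 * rep.recall * rep.precision / (rep.recall + rep.precision)
    specificity = _ratio(tn, tn + fp)
    rep.g_mean = NAN if np.isnan(rep.recall) or np.isnan(specificity) else float(
        np.sqrt(rep.recall * specificity)
    )
    return rep


def roc_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC curve (threshold sweep over the score values) and trapezoid AUC.
    Integer vote counts are valid scores."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        return [], NAN
    fpr, tpr, _ = roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def pr_aupr(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall curve and step-wise AUPR (average precision)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0:
        return [], NAN
    precision, recall, _ = precision_recall_curve(y, s)
    return list(zip(recall.tolist(), precision.tolist())), float(average_precision_score(y, s))


def full_report(labels, predictions, scores) -> MetricsReport:
    """Confusion metrics plus ROC/AUC and PR/AUPR in one report."""
    rep = confusion_metrics(labels, predictions)
    rep.roc, rep.auc = roc_auc(labels, scores)
    rep.pr, rep.aupr = pr_aupr(labels, scores)
    return rep


def replicate_summary(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Per-metric arithmetic mean over replicate cycles; NaN entries are
    excluded, with the contributing count reported alongside."""
    out: dict[str, dict[str, float]] = {}
    for name in MetricsReport.SCALARS:
        values = np.array([getattr(r, name) for r in reports], dtype=float)
        valid = values[~np.isnan(values)]
        out[name] = {
            "mean": float(valid.mean()) if valid.size else NAN,
            "n": int(valid.size),
        }
    return out
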