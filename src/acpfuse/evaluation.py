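"""Binary-classification evaluation: confusion counts, the five threshold
metrics (accuracy, F1, recall, precision, Matthews correlation coefficient),
and ROC / precision-recall curves with their areas.

Positive class is always ACP (label 1). Threshold metrics are computed from
the 2x2 confusion table with the standard formulas

    accuracy  = (TP+TN) / (TP+TN+FP+FN)
    F1        = 2*TP / (2*TP+FP+FN)
    recall    = TP / (TP+FN)
    precision = TP / (TP+FP)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Degenerate denominators (a zero factor under the MCC root, or an empty
predicted/actual positive set) yield 0 with a ``degenerate`` flag rather
than an error, so batch evaluation never dies on an edge case. AUC uses
trapezoidal integration of the ROC curve (equivalent to the Mann-Whitney
rank statistic, with tied scores rank-averaged); the PR area uses the
average-precision step convention, which differs slightly from a
trapezoidal PR integral.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .io import LabeledDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Threshold metrics as fractions in [0, 1] (format with
    :meth:`as_percent_dict` for table-style percentages), MCC in [-1, 1],
    optional curve areas, and the underlying counts."""

    accuracy: float
    f1: float
    recall: float
    precision: float
    mcc: float
    counts: ConfusionCounts
    auc: float | None = None
    prauc: float | None = None
    threshold: float = 0.5
    degenerate: bool = False

    def as_percent_dict(self, decimals: int = 1) -> dict[str, float]:
        """Accuracy/F1/recall/precision as percentages rounded to
        ``decimals`` places; MCC and areas unchanged (3 places)."""
        out = {
            "accuracy": round(100 * self.accuracy, decimals),
            "f1": round(100 * self.f1, decimals),
            "recall": round(100 * self.recall, decimals),
            "precision": round(100 * self.precision, decimals),
            "mcc": round(self.mcc, 3),
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, 3)
        if self.prauc is not None:
            out["prauc"] = round(self.prauc, 3)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2))


def confusion(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionCounts:
    """2x2 confusion table, positive class = ACP (label 1)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    for arr, name in ((t, "true"), (p, "predicted")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """The five threshold metrics from a confusion table."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    if n == 0:
        raise ValueError("empty confusion table")
    degenerate = False

    accuracy = (tp + tn) / n
    if 2 * tp + fp + fn > 0:
        f1 = 2 * tp / (2 * tp + fp + fn)
    else:
        f1, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc, degenerate = 0.0, True

    return MetricsReport(
        accuracy=accuracy,
        f1=f1,
        recall=recall,
        precision=precision,
        mcc=mcc,
        counts=counts,
        degenerate=degenerate,
    )


def roc_auc(
    scores: Sequence[float], true_labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (fpr, tpr arrays over all score thresholds) and its
    trapezoidal area."""
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def pr_auc(
    scores: Sequence[float], true_labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and its area by the average-precision
    step convention."""
    y = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    if (y == 1).sum() == 0:
        raise ValueError("PR curve needs at least one positive")
    precision, recall, _ = precision_recall_curve(y, s)
    return precision, recall, float(average_precision_score(y, s))


def evaluate_scores(
    scores: Sequence[float],
    true_labels: Sequence[int],
    threshold: float = 0.5,
) -> MetricsReport:
    """Full report from raw scores: threshold (strict >) to labels, count,
    derive metrics, and attach ROC/PR areas when both classes are present."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels)
    predicted = (s > threshold).astype(int)
    report = metrics_from_counts(confusion(y, predicted))
    auc_val = prauc_val = None
    if len(np.unique(y)) == 2:
        _, _, auc_val = roc_auc(s, y)
        _, _, prauc_val = pr_auc(s, y)
    return MetricsReport(
        accuracy=report.accuracy,
        f1=report.f1,
        recall=report.recall,
        precision=report.precision,
        mcc=report.mcc,
        counts=report.counts,
        auc=auc_val,
        prauc=prauc_val,
        threshold=threshold,
        degenerate=report.degenerate,
    )


def evaluate(model, dataset: LabeledDataset, threshold: float = 0.5) -> MetricsReport:
    """Score a labeled dataset with a trained model and report all metrics."""
    predictions = model.predict(dataset.peptides, threshold=threshold)
    scores = [p.score for p in predictions]
    truth = [p.label for p in dataset.peptides]
    return evaluate_scores(scores, truth, threshold=threshold)
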