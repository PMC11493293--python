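"""Confusion matrices and classification metrics.

Conventions follow the evaluation used for feeding-intensity discrimination:
per class, one-vs-rest counts TP/FP/FN/TN define precision, recall and F1;
accuracy is the fraction of correctly classified items. Accuracy, precision
and recall are reported in percent (×100); F1 is a unitless value in [0, 1].
Macro averaging (unweighted class mean) is the default; micro averaging is
available and, for single-label multiclass data, micro-precision =
micro-recall = accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataio import LABELS

__all__ = ["MetricsError", "MetricsReport", "confusion_matrix", "compute_metrics"]


class MetricsError(ValueError):
    """Raised for mismatched label vectors or degenerate confusion matrices."""


@dataclass
class MetricsReport:
    """Confusion matrix with derived metrics.

    ``accuracy``, per-class and averaged ``precision``/``recall`` are in
    percent; ``f1`` values are fractions in [0, 1]. ``per_class`` maps each
    label to a dict with keys precision, recall, f1, support, tp, fp, fn, tn.
    """

    confusion: np.ndarray
    labels: tuple[str, ...]
    accuracy: float
    per_class: dict
    averaging: str
    avg_precision: float
    avg_recall: float
    avg_f1: float

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "averaging": self.averaging,
            "avg_precision": self.avg_precision,
            "avg_recall": self.avg_recall,
            "avg_f1": self.avg_f1,
            "per_class": self.per_class,
        }


def confusion_matrix(
    true_labels: Sequence,
    predicted_labels: Sequence,
    labels: tuple[str, ...] = LABELS,
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    if len(true_labels) != len(predicted_labels):
        raise MetricsError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise MetricsError(f"unknown label in ({t!r}, {p!r}); expected one of {labels}")
        conf[index[t], index[p]] += 1
    return conf


def compute_metrics(
    confusion: np.ndarray,
    averaging: str = "macro",
    labels: Optional[tuple[str, ...]] = None,
) -> MetricsReport:
    """Derive accuracy, precision, recall and F1 from a confusion matrix.

    Per class c (one-vs-rest): TP is the diagonal entry, FN the rest of row
    c, FP the rest of column c, TN the remainder; precision = TP/(TP+FP),
    recall = TP/(TP+FN) (in percent), F1 the harmonic mean of the two (as a
    fraction). Classes with zero support are excluded from the macro
    average with a warning. Micro averaging pools counts over classes.
    """
    conf = np.asarray(confusion)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise MetricsError(f"confusion matrix must be square, got shape {conf.shape}")
    if (conf < 0).any() or not np.issubdtype(conf.dtype, np.integer):
        raise MetricsError("confusion matrix must contain non-negative integers")
    total = int(conf.sum())
    if total == 0:
        raise MetricsError("confusion matrix is all zero")
    if averaging not in ("macro", "micro"):
        raise MetricsError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    if labels is None:
        labels = LABELS if conf.shape[0] == len(LABELS) else tuple(
            f"class_{i}" for i in range(conf.shape[0])
        )
    if len(labels) != conf.shape[0]:
        raise MetricsError("labels length must match the confusion matrix size")

    accuracy = float(np.trace(conf)) / total * 100.0

    per_class: dict[str, dict] = {}
    for c, lab in enumerate(labels):
        tp = int(conf[c, c])
        fn = int(conf[c].sum()) - tp
        fp = int(conf[:, c].sum()) - tp
        tn = total - tp - fn - fp
        support = tp + fn
        precision = tp / (tp + fp) * 100.0 if tp + fp else 0.0
        recall = tp / (tp + fn) * 100.0 if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall) / 100.0
            if precision + recall
            else 0.0
        )
        per_class[lab] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
        }

    if averaging == "macro":
        supported = [lab for lab in labels if per_class[lab]["support"] > 0]
        dropped = [lab for lab in labels if per_class[lab]["support"] == 0]
        if dropped:
            warnings.warn(
                f"class(es) with zero support excluded from macro average: {dropped}",
                stacklevel=2,
            )
        avg_p = float(np.mean([per_class[l]["precision"] for l in supported]))
        avg_r = float(np.mean([per_class[l]["recall"] for l in supported]))
        avg_f = float(np.mean([per_class[l]["f1"] for l in supported]))
    else:
        tp = sum(per_class[l]["tp"] for l in labels)
        fp = sum(per_class[l]["fp"] for l in labels)
        fn = sum(per_class[l]["fn"] for l in labels)
        avg_p = tp / (tp + fp) * 100.0 if tp + fp else 0.0
        avg_r = tp / (tp + fn) * 100.0 if tp + fn else 0.0
        avg_f = 2 * avg_p * avg_r / (avg_p + avg_r) / 100.0 if avg_p + avg_r else 0.0

    return MetricsReport(
        confusion=conf,
        labels=tuple(labels),
        accuracy=accuracy,
        per_class=per_class,
        averaging=averaging,
        avg_precision=avg_p,
        avg_recall=avg_r,
        avg_f1=avg_f,
    )
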