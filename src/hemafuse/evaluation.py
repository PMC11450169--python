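"""Classification metrics: accuracy, per-class precision/recall/F1, confusion.

Thin layer over scikit-learn's metric functions that packages the numbers the
way the rest of the toolkit reports them: percentages, macro aggregates, and
an explicit flag for classes absent from the evaluation set (whose recall is
undefined and reported as 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

__all__ = ["EvalReport", "evaluate_predictions"]


@dataclass
class EvalReport:
    accuracy: float  # percent
    precision: np.ndarray  # per-class, percent
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # rows = true classes
    support: np.ndarray
    undefined_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
                "support": self.support.tolist(),
            },
            "confusion": self.confusion.tolist(),
            "undefined_classes": self.undefined_classes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_predictions(y_true, y_pred, n_classes: int | None = None) -> EvalReport:
    """Build an :class:`EvalReport` from true and predicted labels.

    Aggregate precision/recall/F1 are macro averages (unweighted mean over
    classes).  Classes with zero evaluation samples are flagged in
    ``undefined_classes``; their per-class values are reported as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be non-empty and same length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    labels = np.arange(n_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = 100.0 * np.trace(conf) / conf.sum()
    return EvalReport(
        accuracy=accuracy,
        precision=100.0 * prec,
        recall=100.0 * rec,
        f1=100.0 * f1,
        macro_precision=100.0 * prec.mean(),
        macro_recall=100.0 * rec.mean(),
        macro_f1=100.0 * f1.mean(),
        confusion=conf,
        support=support,
        undefined_classes=[int(c) for c in labels[support == 0]],
    )
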