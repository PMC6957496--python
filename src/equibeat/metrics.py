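"""Classification metrics for the 4-class beat classifier.

Per class (one-vs-rest collapsing of the 4x4 confusion matrix):

    recall = TP / (TP + FN)        PPV = TP / (TP + FP)
    F1 = 2 * recall * PPV / (recall + PPV)

Overall accuracy is trace/total (the multi-class reading of the binary
accuracy formula); macro averages are unweighted class means, with classes
that never occur excluded.  All metrics are reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import BEAT_CLASSES

__all__ = ["ConfusionMatrix", "EvalReport", "confusion", "compute_metrics",
           "average_reports"]


@dataclass
class ConfusionMatrix:
    """4x4 count matrix; rows = true class, columns = predicted class,
    class order (N, APC, VPC, A)."""

    counts: np.ndarray
    classes: tuple = BEAT_CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """Per-class and aggregate metrics, all in percent."""

    per_class: dict  # class -> {"recall": %, "ppv": %, "f1": %} (None if undefined)
    accuracy: float
    macro_recall: float
    macro_ppv: float
    macro_f1: float
    n_models_averaged: int = 1
    confusion: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_ppv": self.macro_ppv,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class,
            "n_models_averaged": self.n_models_averaged,
        }
        if self.confusion is not None:
            d["confusion"] = np.asarray(self.confusion).tolist()
        return d

    def format_table(self) -> str:
        lines = [f"{'Class':<6}{'Recall (%)':>12}{'PPV (%)':>10}{'F1 (%)':>9}"]
        for cls, m in self.per_class.items():
            vals = [f"{m[k]:.1f}" if m[k] is not None else "--"
                    for k in ("recall", "ppv", "f1")]
            lines.append(f"{cls:<6}{vals[0]:>12}{vals[1]:>10}{vals[2]:>9}")
        lines.append(f"Accuracy: {self.accuracy:.1f}%")
        return "\n".join(lines)


def confusion(true_labels, predicted_labels,
              classes: tuple = BEAT_CLASSES) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into a ConfusionMatrix."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def compute_metrics(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest per-class metrics + overall accuracy from a ConfusionMatrix.

    A class that never occurs as truth has undefined recall/F1 (reported as
    ``None`` and excluded from macro averages); likewise PPV for a class that
    is never predicted.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix is empty")
    per_class: dict[str, dict] = {}
    recalls, ppvs, f1s = [], [], []
    for i, cls in enumerate(cm.classes):
        tp = int(counts[i, i])
        fn = int(counts[i, :].sum()) - tp
        fp = int(counts[:, i].sum()) - tp
        recall = 100.0 * tp / (tp + fn) if (tp + fn) else None
        ppv = 100.0 * tp / (tp + fp) if (tp + fp) else None
        if recall is not None and ppv is not None and (recall + ppv) > 0:
            f1 = 2.0 * recall * ppv / (recall + ppv)
        elif recall is not None and ppv is not None:
            f1 = 0.0
        else:
            f1 = None
        per_class[cls] = {"recall": recall, "ppv": ppv, "f1": f1}
        if recall is not None:
            recalls.append(recall)
        if ppv is not None:
            ppvs.append(ppv)
        if f1 is not None:
            f1s.append(f1)
    return EvalReport(
        per_class=per_class,
        accuracy=100.0 * float(np.trace(counts)) / total,
        macro_recall=float(np.mean(recalls)) if recalls else 0.0,
        macro_ppv=float(np.mean(ppvs)) if ppvs else 0.0,
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
        confusion=counts,
    )


def average_reports(reports: list[EvalReport]) -> EvalReport:
    """Element-wise arithmetic mean over replicate-training reports."""
    if not reports:
        raise ValueError("need at least one report to average")
    classes = list(reports[0].per_class)
    per_class = {}
    for cls in classes:
        entry = {}
        for key in ("recall", "ppv", "f1"):
            vals = [r.per_class[cls][key] for r in reports
                    if r.per_class[cls][key] is not None]
            entry[key] = float(np.mean(vals)) if vals else None
        per_class[cls] = entry
    return EvalReport(
        per_class=per_class,
        accuracy=float(np.mean([r.accuracy for r in reports])),
        macro_recall=float(np.mean([r.macro_recall for r in reports])),
        macro_ppv=float(np.mean([r.macro_ppv for r in reports])),
        macro_f1=float(np.mean([r.macro_f1 for r in reports])),
        n_models_averaged=len(reports),
    )
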