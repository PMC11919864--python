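"""Classification metrics and the evaluation report.

Binary-count definitions: accuracy = (TP+TN)/(TP+FP+TN+FN),
precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2*precision*recall/(precision+recall). The 3-class task reduces to
these one-vs-rest, with macro (unweighted) averaging; undefined ratios are
reported as 0 and flagged. Confusion matrices are reported both as counts
and row-normalized probabilities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinaryMetrics",
    "EvaluationReport",
    "confusion_matrix",
    "metrics_from_counts",
    "multiclass_report",
]

logger = logging.getLogger(__name__)


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Count matrix with entry (i, j) = #{true class i, predicted class j}."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size and (min(t.min(), p.min()) < 0 or max(t.max(), p.max()) >= n_classes):
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


@dataclass
class BinaryMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: list[str] = field(default_factory=list)


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> BinaryMetrics:
    """Accuracy/precision/recall/F1 from binary confusion counts.

    Undefined ratios (zero denominator) are returned as 0 and named in
    ``undefined``.
    """
    for name, v in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all counts zero")
    undefined: list[str] = []
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        precision = 0.0
        undefined.append("precision")
        logger.warning("precision undefined (TP+FP=0); reported as 0")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        undefined.append("recall")
        logger.warning("recall undefined (TP+FN=0); reported as 0")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return BinaryMetrics(accuracy, precision, recall, f1, undefined)


@dataclass
class EvaluationReport:
    """Per-class and macro metrics plus confusion matrices for one dimension."""

    dimension: str | None
    n: int
    accuracy: float
    per_class: pd.DataFrame  # index: class, columns: precision/recall/f1/support
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion_counts: np.ndarray
    confusion_probabilities: np.ndarray

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_probabilities": self.confusion_probabilities.tolist(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def confusion_to_csv(self, path_counts, path_probs=None) -> None:
        k = self.confusion_counts.shape[0]
        names = [f"class{i}" for i in range(k)]
        pd.DataFrame(self.confusion_counts, index=names, columns=names).to_csv(path_counts)
        if path_probs is not None:
            pd.DataFrame(
                self.confusion_probabilities, index=names, columns=names
            ).to_csv(path_probs)

    def __str__(self) -> str:
        lines = [
            f"Evaluation report ({self.dimension or 'unnamed dimension'}), n={self.n}",
            f"  accuracy:        {self.accuracy:.4f}",
            f"  macro precision: {self.macro_precision:.4f}",
            f"  macro recall:    {self.macro_recall:.4f}",
            f"  macro F1:        {self.macro_f1:.4f}",
            "  per-class:",
        ]
        lines += [
            f"    class {i}: precision={r.precision:.4f} recall={r.recall:.4f} "
            f"f1={r.f1:.4f} support={int(r.support)}"
            for i, r in self.per_class.iterrows()
        ]
        lines.append("  confusion (rows = true, cols = predicted):")
        lines += [f"    {row}" for row in self.confusion_counts.tolist()]
        return "\n".join(lines)


def multiclass_report(
    true_labels, predicted_labels, n_classes: int = 3, dimension: str | None = None
) -> EvaluationReport:
    """One-vs-rest reduction of the binary metrics with macro averaging."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    cm = confusion_matrix(t, p, n_classes)
    n = int(cm.sum())
    accuracy = float(np.trace(cm) / n) if n else 0.0
    rows = []
    for c in range(n_classes):
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum() - tp)
        fn = int(cm[c, :].sum() - tp)
        tn = n - tp - fp - fn
        m = metrics_from_counts(tp, fp, tn, fn)
        rows.append(
            {"precision": m.precision, "recall": m.recall, "f1": m.f1,
             "support": int(cm[c, :].sum())}
        )
    per_class = pd.DataFrame(rows)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(row_sums > 0, cm / np.maximum(row_sums, 1), 0.0)
    return EvaluationReport(
        dimension=dimension,
        n=n,
        accuracy=accuracy,
        per_class=per_class,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        confusion_counts=cm,
        confusion_probabilities=probs,
    )
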