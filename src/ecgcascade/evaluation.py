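"""Confusion matrices and the accuracy/sensitivity/specificity metric suite.

Per-class metrics use the one-vs-rest reduction of the confusion matrix:
for class *c*, TP is the diagonal entry, FN the rest of its row, FP the rest
of its column, and TN everything else, giving

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

each reported in percent to three decimals. Overall values are macro
(unweighted) means across classes. A 0/0 ratio is reported as 0 with a
logged warning (e.g. a class never present in the truth).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity")


def _round3(x: float) -> float:
    """Round to three decimals, half away from zero."""
    return math.copysign(math.floor(abs(x) * 1000 + 0.5) / 1000, x)


@dataclass
class ConfusionMatrix:
    """Count matrix with rows = true label, columns = predicted label."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        header = "true\\pred," + ",".join(self.labels)
        rows = [
            f"{lab}," + ",".join(str(c) for c in row)
            for lab, row in zip(self.labels, self.counts)
        ]
        with open(path, "w") as fh:
            fh.write("\n".join([header, *rows]) + "\n")


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics, in percent."""

    labels: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    overall: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"labels": list(self.labels), "per_class": self.per_class,
                 "overall": self.overall},
                fh, indent=1,
            )

    def format_table(self, title: str = "") -> str:
        width = max(9, *(len(l) for l in self.labels)) + 2
        lines = []
        if title:
            lines.append(title)
        header = f"{'Metric (%)':<14}{'Overall':>10}" + "".join(
            f"{lab:>{width}}" for lab in self.labels
        )
        lines.append(header)
        for metric in METRIC_NAMES:
            row = f"{metric.capitalize():<14}{self.overall[metric]:>10.3f}"
            row += "".join(f"{self.per_class[lab][metric]:>{width}.3f}" for lab in self.labels)
            lines.append(row)
        return "\n".join(lines)


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_order: Sequence[str],
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    known = set(label_order)
    unknown = (set(true_labels) | set(predicted_labels)) - known
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in label order {list(label_order)}")
    counts = _sk_confusion_matrix(
        list(true_labels), list(predicted_labels), labels=list(label_order)
    )
    return ConfusionMatrix(labels=tuple(label_order), counts=counts)


def normalize_confusion(matrix: ConfusionMatrix) -> np.ndarray:
    """Row-normalize against each class's true count, rounded to 3 decimals."""
    out = np.zeros(matrix.counts.shape, dtype=float)
    for i, row in enumerate(matrix.counts):
        s = row.sum()
        if s > 0:
            out[i] = [_round3(c / s) for c in row]
    return out


def _safe_ratio(numerator: float, denominator: float, what: str) -> float:
    if denominator == 0:
        logger.warning("0/0 encountered computing %s; reporting 0", what)
        return 0.0
    return numerator / denominator


def per_class_metrics(matrix: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """One-vs-rest accuracy/sensitivity/specificity per class, in percent."""
    total = matrix.total
    out: dict[str, dict[str, float]] = {}
    for i, label in enumerate(matrix.labels):
        tp = int(matrix.counts[i, i])
        fn = int(matrix.counts[i].sum()) - tp
        fp = int(matrix.counts[:, i].sum()) - tp
        tn = total - tp - fn - fp
        out[label] = {
            "accuracy": _round3(100 * _safe_ratio(tp + tn, total, f"{label} accuracy")),
            "sensitivity": _round3(100 * _safe_ratio(tp, tp + fn, f"{label} sensitivity")),
            "specificity": _round3(100 * _safe_ratio(tn, tn + fp, f"{label} specificity")),
        }
    return out


def overall_metrics(per_class: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Macro (unweighted) mean of each metric across classes, to 3 decimals."""
    if not per_class:
        raise ValueError("per_class metrics are empty")
    return {
        metric: _round3(float(np.mean([pc[metric] for pc in per_class.values()])))
        for metric in METRIC_NAMES
    }


def evaluate(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_order: Sequence[str],
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix plus the full metrics report for one prediction run."""
    matrix = confusion_matrix(true_labels, predicted_labels, label_order)
    per_class = per_class_metrics(matrix)
    return matrix, MetricsReport(
        labels=tuple(label_order), per_class=per_class, overall=overall_metrics(per_class)
    )
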