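"""Confusion-matrix construction and the reported evaluation metrics.

Accuracy is the multiclass trace/total; precision and recall are the usual
one-vs-rest column/row ratios, macro precision their unweighted mean.  The
reduction ratio measures how much of the feature space a selected subset
discards, 100*(1 - SSize/TSize).  Repeated stochastic runs are summarised
as best / average / sample standard deviation of the per-run best costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "RunAggregate",
    "confusion_matrix",
    "accuracy",
    "per_class_precision",
    "per_class_recall",
    "macro_precision",
    "reduction_ratio",
    "aggregate_runs",
    "evaluate_mask",
    "truncate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts with rows = true class and columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        c = len(self.class_names)
        if counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="true\\pred")


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence, class_names: Sequence[str]
) -> ConfusionMatrix:
    """Tally counts[i][j] = samples of true class i predicted as class j.

    Labels may be class names or 0-based indices into ``class_names``.
    """
    names = tuple(str(c) for c in class_names)
    index = {c: i for i, c in enumerate(names)}

    def resolve(label) -> int:
        if isinstance(label, (int, np.integer)):
            i = int(label)
            if not 0 <= i < len(names):
                raise ValueError(f"label index {i} outside 0..{len(names) - 1}")
            return i
        try:
            return index[str(label)]
        except KeyError:
            raise ValueError(f"unknown class label {label!r}") from None

    t = [resolve(v) for v in true_labels]
    p = [resolve(v) for v in predicted_labels]
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, names)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall multiclass accuracy: correctly classified fraction (trace/total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def per_class_precision(cm: ConfusionMatrix, class_index: int) -> float:
    """TP / (TP + FP) over the class's column; 0.0 when never predicted."""
    col = cm.col_sums()[class_index]
    if col == 0:
        return 0.0
    return float(cm.counts[class_index, class_index] / col)


def per_class_recall(cm: ConfusionMatrix, class_index: int) -> float:
    """TP / (TP + FN) over the class's row; 0.0 when the class has no samples."""
    row = cm.row_sums()[class_index]
    if row == 0:
        return 0.0
    return float(cm.counts[class_index, class_index] / row)


def precision_undefined(cm: ConfusionMatrix) -> list[int]:
    """Classes whose precision denominator is zero (never predicted)."""
    return [int(i) for i in np.flatnonzero(cm.col_sums() == 0)]


def macro_precision(per_class: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-class precision values."""
    values = np.asarray(per_class, dtype=float)
    if values.size == 0:
        raise ValueError("macro precision of an empty vector is undefined")
    return float(values.mean())


def reduction_ratio(subset_size: int, t_size: int) -> float:
    """Percentage of features eliminated: 100 * (1 - subset_size / t_size)."""
    if subset_size <= 0:
        raise ValueError("subset_size must be positive")
    if subset_size > t_size:
        raise ValueError("subset_size cannot exceed the total feature count")
    return 100.0 * (1.0 - subset_size / t_size)


def truncate(value: float, decimals: int = 1) -> float:
    """Truncate (not round) toward zero at the given number of decimals.

    Human-readable reports use the display convention of truncated
    percentages; machine-readable output keeps full precision.
    """
    factor = 10.0 ** decimals
    return math.trunc(value * factor) / factor


@dataclass(frozen=True)
class EvaluationReport:
    """Full evaluation of one feature mask on a held-out partition."""

    accuracy: float
    per_class_precision: tuple[float, ...]
    per_class_recall: tuple[float, ...]
    macro_precision: float
    reduction_ratio: float
    subset_size: int
    t_size: int
    confusion: ConfusionMatrix
    undefined_precision_classes: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_precision": list(self.per_class_precision),
            "per_class_recall": list(self.per_class_recall),
            "macro_precision": self.macro_precision,
            "reduction_ratio": self.reduction_ratio,
            "subset_size": self.subset_size,
            "t_size": self.t_size,
            "class_names": list(self.confusion.class_names),
            "confusion": self.confusion.counts.tolist(),
            "undefined_precision_classes": list(self.undefined_precision_classes),
        }

    def summary(self) -> str:
        """One-line human-readable summary with display-truncated percentages."""
        return (
            f"accuracy {truncate(100 * self.accuracy, 2)}% | "
            f"macro precision {truncate(100 * self.macro_precision, 1)}% | "
            f"{self.subset_size}/{self.t_size} features "
            f"(reduction {truncate(self.reduction_ratio, 1)}%)"
        )


@dataclass(frozen=True)
class RunAggregate:
    """Best / average / sample-std of per-run best costs over repeated runs.

    The standard deviation uses the sample (n-1) convention, 0.0 for a
    single run.
    """

    best_cost: float
    avg_cost: float
    std_cost: float
    run_count: int
    mean_accuracy: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "best_cost": self.best_cost,
            "avg_cost": self.avg_cost,
            "std_cost": self.std_cost,
            "std_convention": "sample (n-1)",
            "run_count": self.run_count,
            "mean_accuracy": self.mean_accuracy,
        }


def aggregate_runs(
    costs: Sequence[float], accuracies: Sequence[float] | None = None
) -> RunAggregate:
    """Aggregate per-run best costs (and optionally accuracies)."""
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        raise ValueError("no runs to aggregate")
    if accuracies is not None:
        accuracies = np.asarray(accuracies, dtype=float)
        if accuracies.size != costs.size:
            raise ValueError("costs and accuracies differ in length")
        mean_acc = float(accuracies.mean())
    else:
        mean_acc = float("nan")
    std = float(costs.std(ddof=1)) if costs.size > 1 else 0.0
    return RunAggregate(
        best_cost=float(costs.min()),
        avg_cost=float(costs.mean()),
        std_cost=std,
        run_count=int(costs.size),
        mean_accuracy=mean_acc,
    )


def evaluate_mask(mask, dataset, classifier_spec=None) -> EvaluationReport:
    """Train the configured classifier on the mask's columns and report the
    full test-set evaluation (confusion matrix and all derived metrics)."""
    from .fitness import ClassifierSpec  # local import avoids a cycle

    spec = classifier_spec or ClassifierSpec()
    mask = np.asarray(mask, dtype=np.uint8)
    if mask.size != dataset.n_features:
        raise ValueError(
            f"mask length {mask.size} != feature count {dataset.n_features}"
        )
    cols = np.flatnonzero(mask)
    if cols.size == 0:
        raise ValueError("mask selects no features")
    clf = spec.make()
    clf.fit(dataset.train_x[:, cols], dataset.train_y)
    pred = clf.predict(dataset.test_x[:, cols])
    cm = confusion_matrix(dataset.test_y, pred, dataset.class_names)
    prec = tuple(per_class_precision(cm, i) for i in range(dataset.n_classes))
    rec = tuple(per_class_recall(cm, i) for i in range(dataset.n_classes))
    return EvaluationReport(
        accuracy=accuracy(cm),
        per_class_precision=prec,
        per_class_recall=rec,
        macro_precision=macro_precision(prec),
        reduction_ratio=reduction_ratio(int(cols.size), dataset.n_features),
        subset_size=int(cols.size),
        t_size=dataset.n_features,
        confusion=cm,
        undefined_precision_classes=tuple(precision_undefined(cm)),
    )
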