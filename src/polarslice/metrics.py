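"""Fold-level classification metrics and their cross-fold aggregation.

Per fold the panel is accuracy, precision (positive predictive value),
sensitivity (recall), F1 (harmonic mean of precision and sensitivity) and
AUC — the probability that a random positive sample outscores a random
negative one, with midrank handling of ties (equivalent to the trapezoidal
ROC area).  Across folds each metric is summarised as mean +/- standard
deviation (sample convention, n-1, configurable to population).

Degenerate folds are reported honestly: a zero denominator yields NaN plus
a warning, never a silent zero, and AUC on a single-class fold is an error.
Wall-clock training/scoring time is recorded alongside but is informational
only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "FoldMetrics",
    "confusion_counts",
    "compute_metrics",
    "aggregate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "f1", "auc")


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator was zero; the value is reported as NaN."""


@dataclass(frozen=True)
class FoldMetrics:
    """Metric panel of one model on one partition of one fold."""

    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    auc: float
    elapsed_seconds: float = float("nan")
    partition: str = "test"
    fold: int = 0
    model: str = ""

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], positive_label: int = 0
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with respect to the given positive label."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1 or len(yt) == 0:
        raise ValueError("y_true and y_pred must be equal-length 1-D, non-empty")
    tp = int(np.sum((yt == positive_label) & (yp == positive_label)))
    fp = int(np.sum((yt != positive_label) & (yp == positive_label)))
    fn = int(np.sum((yt == positive_label) & (yp != positive_label)))
    tn = int(np.sum((yt != positive_label) & (yp != positive_label)))
    return tp, fp, fn, tn


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(
            f"{name} is undefined (zero denominator); reporting NaN",
            UndefinedMetricWarning,
            stacklevel=3,
        )
        return float("nan")
    return num / den


def compute_metrics(
    y_true: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    positive_label: int = 0,
    *,
    elapsed_seconds: float = float("nan"),
    partition: str = "test",
    fold: int = 0,
    model: str = "",
) -> FoldMetrics:
    """Full metric panel from true labels and positive-class scores.

    Hard predictions use score >= threshold (ties go to the positive class).
    AUC requires both classes in ``y_true``.
    """
    yt = np.asarray(y_true)
    sc = np.asarray(scores, dtype=np.float64)
    if yt.shape != sc.shape or yt.ndim != 1 or len(yt) == 0:
        raise ValueError("y_true and scores must be equal-length 1-D, non-empty")
    pos = yt == positive_label
    if pos.all() or (~pos).all():
        raise ValueError("AUC is undefined when y_true contains a single class")

    yp = np.where(sc >= threshold, positive_label, 1 - positive_label)
    # keep prediction encoding consistent with arbitrary label values
    if positive_label not in (0, 1):
        raise ValueError("positive_label must be 0 or 1")
    tp, fp, fn, tn = confusion_counts(yt, yp, positive_label)
    n = tp + fp + fn + tn
    precision = _ratio(tp, tp + fp, "precision")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn(
            "F1 is undefined; reporting NaN", UndefinedMetricWarning, stacklevel=2
        )
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    auc = float(roc_auc_score(pos.astype(int), sc))
    return FoldMetrics(
        accuracy=(tp + tn) / n,
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        auc=auc,
        elapsed_seconds=elapsed_seconds,
        partition=partition,
        fold=fold,
        model=model,
    )


def aggregate(per_fold: Sequence[FoldMetrics], ddof: int = 1) -> pd.DataFrame:
    """Mean +/- standard deviation of each metric per (model, partition).

    ``ddof=1`` gives the sample standard deviation (default); ``ddof=0`` the
    population convention.  A group with a single fold reports sd 0.0 (with
    a warning) rather than NaN.
    """
    if not per_fold:
        raise ValueError("cannot aggregate zero fold records")
    df = pd.DataFrame([m.as_dict() for m in per_fold])
    cols = list(METRIC_NAMES) + ["elapsed_seconds"]
    rows = []
    for (model, partition), grp in df.groupby(["model", "partition"], sort=True):
        if len(grp) == 1:
            warnings.warn(
                f"aggregating a single fold for ({model}, {partition}); sd set to 0",
                UserWarning,
                stacklevel=2,
            )
        row: dict = {"model": model, "partition": partition, "n_folds": len(grp)}
        for c in cols:
            vals = grp[c].to_numpy(dtype=np.float64)
            finite = vals[~np.isnan(vals)]
            row[f"{c}_mean"] = float(finite.mean()) if finite.size else float("nan")
            if len(grp) == 1:
                row[f"{c}_sd"] = 0.0
            else:
                row[f"{c}_sd"] = (
                    float(finite.std(ddof=ddof)) if finite.size > ddof else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)


def format_table(summary: pd.DataFrame, partition: str, digits: int = 3) -> pd.DataFrame:
    """Render an aggregated summary as a model-by-metric 'mean +/- sd' table."""
    sub = summary[summary["partition"] == partition]
    pretty = {
        "accuracy": "Accuracy",
        "f1": "F1",
        "precision": "Precision",
        "sensitivity": "Sensitivity",
        "elapsed_seconds": "Time (s)",
        "auc": "AUC",
    }
    out = {}
    for _, row in sub.iterrows():
        out[row["model"]] = {
            label: f"{row[f'{key}_mean']:.{digits}f} +/- {row[f'{key}_sd']:.{digits}f}"
            for key, label in pretty.items()
        }
    return pd.DataFrame(out).T.rename_axis("Model")
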