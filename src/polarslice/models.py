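"""The four ensemble classifier families under one training/scoring contract.

Adaptive boosting, gradient boosting and extreme gradient boosting combine
sequences of weak tree learners; random forests bag deep trees grown on
bootstrap resamples.  All four are exposed through a single contract:
``train`` fits on an 11-column feature matrix, ``predict_scores`` returns
the estimated probability of a configurable positive class in [0, 1], and
``predict_labels`` thresholds those scores (score >= threshold is positive).

Implementations delegate to scikit-learn (AdaBoost, gradient boosting,
random forest) and xgboost; hyperparameters default to each library's
documented values except that forests use unrestricted depth, and every
effective value is recorded in the trained model for reporting.  Training is
deterministic given (seed, matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from xgboost import XGBClassifier

from .features import FEATURE_COLUMNS
from .synth import ConfigurationError

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "TrainedModel",
    "DegenerateTrainingError",
    "train",
    "predict_scores",
    "predict_labels",
]


class DegenerateTrainingError(ValueError):
    """Raised when a training matrix contains fewer than two classes."""


def _make_adaboost(seed: int, params: dict) -> AdaBoostClassifier:
    return AdaBoostClassifier(random_state=seed, **params)


def _make_gradient_boosting(seed: int, params: dict) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(random_state=seed, **params)


def _make_random_forest(seed: int, params: dict) -> RandomForestClassifier:
    # max_depth=None (unrestricted) is the library default; n_jobs stays 1
    # for reproducible single-CPU runs.
    return RandomForestClassifier(random_state=seed, **params)


def _make_xgboost(seed: int, params: dict) -> XGBClassifier:
    defaults: dict[str, Any] = dict(n_estimators=100, eval_metric="logloss", n_jobs=1)
    defaults.update(params)
    return XGBClassifier(random_state=seed, **defaults)


FAMILIES = {
    "adaptive_boosting": _make_adaboost,
    "gradient_boosting": _make_gradient_boosting,
    "random_forest": _make_random_forest,
    "extreme_gradient_boosting": _make_xgboost,
}


@dataclass(frozen=True)
class ModelSpec:
    """One ensemble family plus hyperparameter overrides and a seed."""

    family: str
    seed: int = 0
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown model family {self.family!r}; choose from {sorted(FAMILIES)}"
            )
        known = set(FAMILIES[self.family](0, {}).get_params())
        unknown = set(self.params) - known
        if unknown:
            raise ConfigurationError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}"
            )

    def build(self):
        return FAMILIES[self.family](self.seed, dict(self.params))


@dataclass
class TrainedModel:
    """A fitted ensemble plus the spec and effective parameters that built it."""

    estimator: Any
    spec: ModelSpec
    n_training_rows: int
    effective_params: dict[str, Any]


def _as_xy(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_COLUMNS + ["label"] if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns {missing}")
    X = matrix[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    y = matrix["label"].to_numpy(dtype=np.int64)
    return X, y


def train(spec: ModelSpec, matrix: pd.DataFrame) -> TrainedModel:
    """Fit one ensemble on an 11-column feature matrix.

    Deterministic given (spec.seed, matrix).  Raises
    :class:`DegenerateTrainingError` if the matrix holds a single class.
    """
    X, y = _as_xy(matrix)
    if len(y) < 2 or len(np.unique(y)) < 2:
        raise DegenerateTrainingError(
            "training requires at least two rows covering both classes"
        )
    est = spec.build()
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        spec=spec,
        n_training_rows=len(y),
        effective_params=est.get_params(),
    )


def _as_feature_array(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        X = features[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(
            f"expected {len(FEATURE_COLUMNS)} features per row, got {X.shape[1]}"
        )
    return X


def predict_scores(
    model: TrainedModel,
    features: pd.DataFrame | np.ndarray,
    positive_label: int = 0,
) -> np.ndarray:
    """Estimated probability of the positive class, one score in [0,1] per row.

    ``positive_label`` is the label value treated as positive (default 0,
    i.e. abnormal under the normal=1/abnormal=0 encoding).
    """
    X = _as_feature_array(features)
    classes = list(np.asarray(model.estimator.classes_))
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label} not among trained classes")
    proba = model.estimator.predict_proba(X)[:, classes.index(positive_label)]
    return np.clip(proba.astype(np.float64), 0.0, 1.0)


def predict_labels(
    model: TrainedModel,
    features: pd.DataFrame | np.ndarray,
    threshold: float = 0.5,
    positive_label: int = 0,
) -> np.ndarray:
    """Hard labels from thresholded scores; score >= threshold is positive."""
    scores = predict_scores(model, features, positive_label)
    positive = scores >= threshold
    return np.where(positive, positive_label, 1 - positive_label).astype(np.int64)
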