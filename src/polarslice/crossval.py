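"""Leakage-free stratified ten-fold cross-validation.

The central procedural guarantee of the pipeline: rotated (augmented) copies
of a map may only ever appear in the training partition of folds where the
source map itself is in training.  Concretely, per fold the pipeline is

    training maps  = all acquired maps not assigned to the fold
    augmented maps = rotated copies of the *training* normals only
    train matrix   = features of training + augmented maps
    test matrix    = features of the fold's acquired maps only

so no augmented copy of any test image can enter its own fold's training
set.  The run audits this property explicitly (by object identity of the
augmentation sources) and records the verdict in the report.

Folds are stratified on the class label with a fixed seed: at ~10% normal
prevalence, unstratified folds would risk single-class test partitions.
The positive class for precision/sensitivity defaults to *abnormal*
(label 0) — the clinically relevant detection target at ~89% abnormal
prevalence — and is configurable.
"""

from __future__ import annotations

import time
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .augment import AugmentationConfig, rotate_map
from .features import build_matrix
from .metrics import FoldMetrics, aggregate, compute_metrics, format_table
from .models import DegenerateTrainingError, ModelSpec, predict_scores, train
from .synth import NORMAL, PolarMapImage

__all__ = [
    "FoldPlan",
    "PipelineConfig",
    "CVReport",
    "make_folds",
    "run_fold",
    "run_cv",
    "run_cv_features",
]

_POSITIVE_LABEL = {"abnormal": 0, "normal": 1}


@dataclass(frozen=True)
class FoldPlan:
    """Stratified assignment of each original image (by position) to a fold."""

    k: int
    assignment: np.ndarray  # fold index per image, shape (n_images,)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a cross-validation run needs besides the images."""

    k: int = 10
    seed: int = 0
    model_specs: tuple[ModelSpec, ...] = ()
    augmentation: AugmentationConfig | None = field(default_factory=AugmentationConfig)
    positive_class: str = "abnormal"
    threshold: float = 0.5
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.positive_class not in _POSITIVE_LABEL:
            raise ValueError("positive_class must be 'abnormal' or 'normal'")

    @property
    def positive_label(self) -> int:
        return _POSITIVE_LABEL[self.positive_class]


@dataclass
class CVReport:
    """Per-fold metrics, their aggregation, and the run's audit trail."""

    fold_metrics: list[FoldMetrics]
    summary: pd.DataFrame
    fold_counts: pd.DataFrame
    leakage_free: bool
    config: dict

    def table(self, partition: str = "test") -> pd.DataFrame:
        return format_table(self.summary, partition)

    def to_json(self, path) -> None:
        import json

        payload = {
            "config": self.config,
            "leakage_free": bool(self.leakage_free),
            "fold_metrics": [m.as_dict() for m in self.fold_metrics],
            "summary": self.summary.to_dict(orient="records"),
            "fold_counts": self.fold_counts.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    def to_csv(self, path, partition: str = "test") -> None:
        self.table(partition).to_csv(path)


def make_folds(labels: Sequence[int], k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold assignment, deterministic for a fixed seed.

    Fold sizes differ by at most one and each fold's class proportions are
    within one image of the global proportions.
    """
    y = np.asarray(labels)
    if k > len(y):
        raise ValueError(f"cannot make {k} folds from {len(y)} samples")
    counts = Counter(y.tolist())
    if min(counts.values()) < k:
        warnings.warn(
            f"some class has fewer than k={k} members ({dict(counts)}); "
            "folds will not all contain every class",
            UserWarning,
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return FoldPlan(k=k, assignment=assignment)


def run_fold(
    images: Sequence[PolarMapImage],
    plan: FoldPlan,
    fold: int,
    spec: ModelSpec,
    config: PipelineConfig,
) -> tuple[FoldMetrics, FoldMetrics, dict]:
    """Train and evaluate one model on one fold.

    Returns (train metrics, test metrics, audit).  Train metrics are
    computed on the matrix the model was actually fitted to, i.e. including
    the augmented rows.  The audit dict records partition sizes and the
    leakage check: augmentation sources must be disjoint from the test set.
    """
    if not 0 <= fold < plan.k:
        raise ValueError(f"fold index {fold} out of range for k={plan.k}")
    train_idx = plan.train_indices(fold)
    test_idx = plan.test_indices(fold)
    train_imgs = [images[i] for i in train_idx]
    test_imgs = [images[i] for i in test_idx]

    augmented: list[PolarMapImage] = []
    aug_source_ids: set[int] = set()
    if config.augmentation is not None:
        for img in train_imgs:
            if img.label == NORMAL:
                for angle in config.augmentation.angles:
                    augmented.append(rotate_map(img, angle, config.augmentation))
                    aug_source_ids.add(id(img))
    leakage_free = aug_source_ids.isdisjoint(id(img) for img in test_imgs)

    train_matrix = build_matrix(train_imgs + augmented)
    test_matrix = build_matrix(test_imgs)
    if train_matrix["label"].nunique() < 2:
        raise DegenerateTrainingError(f"fold {fold}: training partition has one class")

    pos = config.positive_label
    t0 = time.perf_counter()
    model = train(spec, train_matrix)
    fit_seconds = time.perf_counter() - t0

    def _panel(matrix: pd.DataFrame, partition: str) -> FoldMetrics:
        scores = predict_scores(model, matrix, positive_label=pos)
        return compute_metrics(
            matrix["label"].to_numpy(),
            scores,
            threshold=config.threshold,
            positive_label=pos,
            elapsed_seconds=fit_seconds,
            partition=partition,
            fold=fold,
            model=spec.family,
        )

    audit = {
        "fold": fold,
        "model": spec.family,
        "n_train": len(train_imgs),
        "n_test": len(test_imgs),
        "n_augmented": len(augmented),
        "leakage_free": leakage_free,
    }
    return _panel(train_matrix, "train"), _panel(test_matrix, "test"), audit


def run_cv(images: Sequence[PolarMapImage], config: PipelineConfig) -> CVReport:
    """Full stratified k-fold run over every configured model family.

    Only acquired images are ever assigned to folds; augmented rows exist
    solely inside per-fold training matrices.  Every acquired image lands in
    exactly one test partition across the run.
    """
    images = list(images)
    if not config.model_specs:
        raise ValueError("config.model_specs must name at least one model")
    if any(img.provenance != "acquired" for img in images):
        raise ValueError("run_cv expects acquired images only; augmentation is per fold")
    labels = [img.label for img in images]
    plan = make_folds(labels, k=config.k, seed=config.seed)

    fold_metrics: list[FoldMetrics] = []
    audits: list[dict] = []
    for spec in config.model_specs:
        for fold in range(plan.k):
            tr, te, audit = run_fold(images, plan, fold, spec, config)
            fold_metrics.extend([tr, te])
            audits.append(audit)

    # coverage: the test partitions tile the dataset exactly
    covered = np.sort(np.concatenate([plan.test_indices(f) for f in range(plan.k)]))
    assert np.array_equal(covered, np.arange(len(images)))

    summary = aggregate(fold_metrics, ddof=config.sd_ddof)
    cfg_snapshot = {
        "k": config.k,
        "seed": config.seed,
        "positive_class": config.positive_class,
        "threshold": config.threshold,
        "sd_ddof": config.sd_ddof,
        "augmentation": None
        if config.augmentation is None
        else {
            "copies_per_image": config.augmentation.copies_per_image,
            "angles": list(config.augmentation.angles),
            "interpolation": config.augmentation.interpolation,
            "fill_value": config.augmentation.fill_value,
        },
        "models": [
            {"family": s.family, "seed": s.seed, "params": dict(s.params)}
            for s in config.model_specs
        ],
    }
    return CVReport(
        fold_metrics=fold_metrics,
        summary=summary,
        fold_counts=pd.DataFrame(audits),
        leakage_free=all(a["leakage_free"] for a in audits),
        config=cfg_snapshot,
    )


def run_cv_features(matrix: pd.DataFrame, config: PipelineConfig) -> CVReport:
    """Cross-validate directly on a precomputed feature matrix.

    Augmentation must be disabled: rotation acts on images, and band sums of
    rotated copies cannot be synthesised from the original feature rows.
    """
    if config.augmentation is not None:
        raise ValueError(
            "augmentation requires images; disable it to cross-validate a "
            "precomputed feature matrix"
        )
    if not config.model_specs:
        raise ValueError("config.model_specs must name at least one model")
    labels = matrix["label"].to_numpy()
    plan = make_folds(labels, k=config.k, seed=config.seed)
    pos = config.positive_label

    fold_metrics: list[FoldMetrics] = []
    audits: list[dict] = []
    for spec in config.model_specs:
        for fold in range(plan.k):
            tr_idx, te_idx = plan.train_indices(fold), plan.test_indices(fold)
            train_matrix = matrix.iloc[tr_idx].reset_index(drop=True)
            test_matrix = matrix.iloc[te_idx].reset_index(drop=True)
            t0 = time.perf_counter()
            model = train(spec, train_matrix)
            fit_seconds = time.perf_counter() - t0
            for part, m in (("train", train_matrix), ("test", test_matrix)):
                scores = predict_scores(model, m, positive_label=pos)
                fold_metrics.append(
                    compute_metrics(
                        m["label"].to_numpy(),
                        scores,
                        threshold=config.threshold,
                        positive_label=pos,
                        elapsed_seconds=fit_seconds,
                        partition=part,
                        fold=fold,
                        model=spec.family,
                    )
                )
            audits.append(
                {
                    "fold": fold,
                    "model": spec.family,
                    "n_train": len(tr_idx),
                    "n_test": len(te_idx),
                    "n_augmented": 0,
                    "leakage_free": True,
                }
            )
    summary = aggregate(fold_metrics, ddof=config.sd_ddof)
    cfg_snapshot = {
        "k": config.k,
        "seed": config.seed,
        "positive_class": config.positive_class,
        "threshold": config.threshold,
        "sd_ddof": config.sd_ddof,
        "augmentation": None,
        "models": [
            {"family": s.family, "seed": s.seed, "params": dict(s.params)}
            for s in config.model_specs
        ],
    }
    return CVReport(
        fold_metrics=fold_metrics,
        summary=summary,
        fold_counts=pd.DataFrame(audits),
        leakage_free=True,
        config=cfg_snapshot,
    )
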