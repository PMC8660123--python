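"""Fold construction, per-fold pipeline and leakage bookkeeping."""

import numpy as np
import pytest

import polarslice as ps


def test_balanced_20_samples_give_one_per_class_per_fold():
    labels = [1] * 10 + [0] * 10
    plan = ps.make_folds(labels, k=10, seed=0)
    for fold in range(10):
        idx = plan.test_indices(fold)
        assert len(idx) == 2
        assert sorted(np.asarray(labels)[idx]) == [0, 1]


def test_1007_samples_split_into_folds_of_100_or_101():
    labels = [1] * 108 + [0] * 899
    plan = ps.make_folds(labels, k=10, seed=1)
    sizes = sorted(len(plan.test_indices(f)) for f in range(10))
    assert set(sizes) <= {100, 101}
    assert sum(sizes) == 1007
    # stratification: each fold's normal count within 1 of 10.8
    for f in range(10):
        n_normal = int(np.sum(np.asarray(labels)[plan.test_indices(f)] == 1))
        assert n_normal in (10, 11)


def test_fold_plan_is_deterministic():
    labels = [1] * 30 + [0] * 70
    a = ps.make_folds(labels, k=10, seed=5)
    b = ps.make_folds(labels, k=10, seed=5)
    assert np.array_equal(a.assignment, b.assignment)


def test_more_folds_than_samples_is_an_error():
    with pytest.raises(ValueError):
        ps.make_folds([0, 1, 0], k=5)


def test_scarce_class_triggers_warning():
    with pytest.warns(UserWarning):
        ps.make_folds([1] * 3 + [0] * 50, k=10, seed=0)


def test_run_fold_partition_counts_without_augmentation(small_dataset):
    plan = ps.make_folds([i.label for i in small_dataset], k=4, seed=0)
    config = ps.PipelineConfig(
        k=4, seed=0, model_specs=(ps.ModelSpec("random_forest", seed=0),), augmentation=None
    )
    _, _, audit = ps.run_fold(small_dataset, plan, 0, config.model_specs[0], config)
    assert audit["n_train"] + audit["n_test"] == len(small_dataset)
    assert audit["n_augmented"] == 0


def test_run_fold_augments_training_normals_only(small_dataset):
    plan = ps.make_folds([i.label for i in small_dataset], k=4, seed=0)
    config = ps.PipelineConfig(
        k=4, seed=0, model_specs=(ps.ModelSpec("random_forest", seed=0),)
    )
    tr, te, audit = ps.run_fold(small_dataset, plan, 1, config.model_specs[0], config)
    n_train_normals = sum(
        small_dataset[i].label == 1 for i in plan.train_indices(1)
    )
    assert audit["n_augmented"] == 3 * n_train_normals
    assert audit["leakage_free"]
    assert tr.partition == "train" and te.partition == "test"


def test_degenerate_single_class_training_raises():
    images = ps.generate_dataset(0, 12, seed=0)
    plan = ps.make_folds([i.label for i in images], k=3, seed=0)
    config = ps.PipelineConfig(k=3, seed=0, model_specs=(ps.ModelSpec("random_forest"),))
    with pytest.raises(ps.DegenerateTrainingError):
        ps.run_fold(images, plan, 0, config.model_specs[0], config)


def test_run_cv_produces_one_record_per_fold_partition_and_model(small_dataset):
    config = ps.PipelineConfig(
        k=4,
        seed=0,
        model_specs=(
            ps.ModelSpec("random_forest", seed=0),
            ps.ModelSpec("adaptive_boosting", seed=0),
        ),
    )
    report = ps.run_cv(small_dataset, config)
    assert len(report.fold_metrics) == 4 * 2 * 2  # folds x partitions x models
    assert report.leakage_free
    assert set(report.summary["model"]) == {"random_forest", "adaptive_boosting"}


def test_run_cv_is_deterministic(small_dataset):
    config = ps.PipelineConfig(
        k=4, seed=3, model_specs=(ps.ModelSpec("random_forest", seed=3),)
    )
    r1 = ps.run_cv(small_dataset, config)
    r2 = ps.run_cv(small_dataset, config)
    for a, b in zip(r1.fold_metrics, r2.fold_metrics):
        for name in ("accuracy", "precision", "sensitivity", "f1", "auc"):
            assert getattr(a, name) == getattr(b, name)


def test_run_cv_rejects_augmented_inputs(small_dataset):
    tainted = list(small_dataset) + [
        ps.rotate_map(small_dataset[0], 90.0)
    ]
    config = ps.PipelineConfig(k=4, model_specs=(ps.ModelSpec("random_forest"),))
    with pytest.raises(ValueError):
        ps.run_cv(tainted, config)


def test_run_cv_features_requires_augmentation_disabled(small_dataset):
    matrix = ps.build_matrix(small_dataset)
    config = ps.PipelineConfig(k=4, model_specs=(ps.ModelSpec("random_forest"),))
    with pytest.raises(ValueError):
        ps.run_cv_features(matrix, config)
    ok = ps.PipelineConfig(
        k=4, model_specs=(ps.ModelSpec("random_forest"),), augmentation=None
    )
    report = ps.run_cv_features(matrix, ok)
    assert len(report.fold_metrics) == 8


def test_separable_synthetic_data_is_learned_by_all_families(small_dataset):
    """Discrimination sanity: severe defects at default noise are separable."""
    config = ps.PipelineConfig(
        k=4,
        seed=0,
        model_specs=tuple(ps.ModelSpec(f, seed=0) for f in sorted(ps.FAMILIES)),
    )
    report = ps.run_cv(small_dataset, config)
    test_rows = report.summary[report.summary["partition"] == "test"]
    assert (test_rows["auc_mean"] > 0.9).all()
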