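"""Metric panel: hand-counted oracles, AUC rank statistic, aggregation."""

import math

import numpy as np
import pytest

import polarslice as ps
from polarslice.metrics import FoldMetrics, UndefinedMetricWarning, aggregate


def brute_force_auc(y_pos, scores):
    """All-pairs comparison: P(random positive outscores random negative),
    ties counted half."""
    pos = [s for s, y in zip(scores, y_pos) if y]
    neg = [s for s, y in zip(scores, y_pos) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_confusion_counts_hand_example():
    y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    assert ps.confusion_counts(y_true, y_pred, positive_label=1) == (3, 1, 1, 5)


def test_all_correct_all_positive():
    assert ps.confusion_counts([1] * 4, [1] * 4, positive_label=1) == (4, 0, 0, 0)


def test_swapping_positive_class_swaps_quadrants():
    y_true = [1, 1, 0, 0, 1, 0]
    y_pred = [1, 0, 0, 1, 1, 0]
    tp, fp, fn, tn = ps.confusion_counts(y_true, y_pred, positive_label=1)
    tp2, fp2, fn2, tn2 = ps.confusion_counts(y_true, y_pred, positive_label=0)
    assert (tp2, fp2, fn2, tn2) == (tn, fn, fp, tp)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        ps.confusion_counts([1, 0], [1], positive_label=1)


def test_metric_panel_formula_oracle():
    """Counts (TP=3, FP=1, FN=1, TN=5) -> acc .8, prec .75, sens .75, F1 .75."""
    y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    scores = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1]
    m = ps.compute_metrics(y_true, scores, threshold=0.5, positive_label=1)
    assert m.accuracy == pytest.approx(0.8)
    assert m.precision == pytest.approx(0.75)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.f1 == pytest.approx(0.75)


def test_perfect_separation_gives_all_ones():
    m = ps.compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], positive_label=1)
    assert (m.accuracy, m.precision, m.sensitivity, m.f1, m.auc) == (1, 1, 1, 1, 1)


def test_fully_ordered_scores_give_auc_one():
    m = ps.compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.2], positive_label=1)
    assert m.auc == 1.0


def test_auc_matches_all_pairs_statistic_with_ties(rng):
    for _ in range(10):
        n = int(rng.integers(10, 120))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        scores = rng.integers(0, 8, size=n) / 8.0  # coarse grid forces ties
        m = ps.compute_metrics(y, scores, positive_label=1)
        assert m.auc == pytest.approx(brute_force_auc(y == 1, scores), abs=1e-12)


def test_metrics_invariant_to_row_order(rng):
    y = np.array([1, 1, 1, 0, 0, 0, 1, 0])
    s = np.array([0.9, 0.4, 0.8, 0.3, 0.6, 0.1, 0.7, 0.2])
    perm = rng.permutation(len(y))
    a = ps.compute_metrics(y, s, positive_label=1)
    b = ps.compute_metrics(y[perm], s[perm], positive_label=1)
    assert a.as_dict() == b.as_dict()


def test_zero_denominator_reports_nan_with_warning():
    # no predicted positives at this threshold -> precision undefined
    with pytest.warns(UndefinedMetricWarning):
        m = ps.compute_metrics([1, 0, 0], [0.1, 0.2, 0.3], threshold=0.9, positive_label=1)
    assert math.isnan(m.precision)
    assert not math.isnan(m.accuracy)


def test_single_class_auc_is_an_error():
    with pytest.raises(ValueError):
        ps.compute_metrics([1, 1, 1], [0.5, 0.6, 0.7], positive_label=1)


def test_f1_identity_holds(rng):
    for _ in range(20):
        n = int(rng.integers(8, 60))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.random(n)
        m = ps.compute_metrics(y, s, positive_label=1)
        if not (math.isnan(m.precision) or math.isnan(m.sensitivity)):
            if m.precision + m.sensitivity > 0:
                expected = 2 * m.precision * m.sensitivity / (m.precision + m.sensitivity)
                assert m.f1 == pytest.approx(expected, abs=1e-15)


def _fold(acc, fold, partition="test", model="random_forest"):
    return FoldMetrics(
        accuracy=acc,
        precision=acc,
        sensitivity=acc,
        f1=acc,
        auc=acc,
        fold=fold,
        partition=partition,
        model=model,
    )


def test_aggregate_identical_folds():
    summary = aggregate([_fold(0.9, i) for i in range(10)])
    row = summary.iloc[0]
    assert row["accuracy_mean"] == pytest.approx(0.9)
    assert row["accuracy_sd"] == pytest.approx(0.0)
    assert row["n_folds"] == 10


def test_aggregate_two_folds_closed_form():
    """Folds [0.8, 1.0]: mean 0.9, sample sd sqrt(0.02)."""
    summary = aggregate([_fold(0.8, 0), _fold(1.0, 1)])
    row = summary.iloc[0]
    assert row["accuracy_mean"] == pytest.approx(0.9)
    assert row["accuracy_sd"] == pytest.approx(math.sqrt(0.02))
    # population convention on request
    pop = aggregate([_fold(0.8, 0), _fold(1.0, 1)], ddof=0).iloc[0]
    assert pop["accuracy_sd"] == pytest.approx(0.1)


def test_aggregate_single_fold_warns_and_reports_zero_sd():
    with pytest.warns(UserWarning):
        summary = aggregate([_fold(0.7, 0)])
    assert summary.iloc[0]["accuracy_sd"] == 0.0


def test_aggregate_empty_is_rejected():
    with pytest.raises(ValueError):
        aggregate([])
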