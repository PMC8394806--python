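"""Metric suite: localization, AP/AR, A/N error, diagnostics, ROC/AUC."""

import numpy as np
import pytest

from adenoceph.evaluation import (UndefinedMetricError, an_ratio_error,
                                  diagnostic_metrics, keypoint_ap_ar,
                                  localization_errors, roc_auc)
from adenoceph.geometry import LandmarkSet, classify_ah
from conftest import random_landmarks


def _coords(*rows):
    return np.asarray(rows, dtype=float)


GT = _coords([10, 20], [30, 40], [25, 10], [5, 15])


def test_localization_zero_for_perfect_predictions():
    table = localization_errors([GT, GT], [GT, GT])
    assert all(v == 0.0 for v in table.per_keypoint.values())
    assert table.average == 0.0


def test_localization_single_displacement():
    pred = GT.copy()
    pred[0] += [3.0, 4.0]  # Ba off by a 3-4-5 triangle
    table = localization_errors([pred], [GT])
    assert table.per_keypoint["Ba"] == pytest.approx(5.0)
    assert table.average == pytest.approx(5.0 / 4)


def test_localization_permutation_invariant(rng):
    preds = [GT + rng.normal(0, 2, (4, 2)) for _ in range(6)]
    gts = [GT] * 6
    t1 = localization_errors(preds, gts)
    order = rng.permutation(6)
    t2 = localization_errors([preds[i] for i in order], [gts[i] for i in order])
    assert t1.average == pytest.approx(t2.average)
    assert t1.per_keypoint == pytest.approx(t2.per_keypoint)


def test_ap_ar_extremes():
    assert keypoint_ap_ar([GT], [GT]) == (1.0, 1.0)
    far = GT + 100.0
    assert keypoint_ap_ar([far], [GT]) == (0.0, 0.0)
    with pytest.raises(ValueError):
        keypoint_ap_ar([GT], [GT], thresholds=[])


def _enumerate_pck(errors, thresholds):
    """Independent enumeration oracle for threshold-averaged precision."""
    fracs = []
    for t in thresholds:
        fracs.append(sum(e <= t for e in errors) / len(errors))
    return sum(fracs) / len(fracs)


def test_ap_ar_worked_example():
    errors = [0.5, 2.5, 5.5, 20.0]
    pred = GT.copy()
    for i, e in enumerate(errors):
        pred[i, 0] += e
    expected = _enumerate_pck(errors, range(1, 11))
    ap, ar = keypoint_ap_ar([pred], [GT])
    assert expected == pytest.approx(0.575)  # fractions 1,1,2,2,2,3,3,3,3,3 / 4
    assert ap == pytest.approx(expected)
    assert ar == pytest.approx(expected)


def test_ap_improves_when_prediction_moves_closer(rng):
    pred = GT + rng.normal(0, 5, (4, 2))
    ap_before, _ = keypoint_ap_ar([pred], [GT])
    closer = GT + 0.5 * (pred - GT)
    ap_after, _ = keypoint_ap_ar([closer], [GT])
    assert ap_after >= ap_before


def test_an_ratio_error_basic(rng):
    lms = [random_landmarks(rng) for _ in range(5)]
    res = an_ratio_error(lms, lms)
    assert res.mae == 0.0 and res.n_used == 5 and res.n_excluded == 0


def test_an_ratio_error_mean():
    gt = LandmarkSet.from_array(_coords([0, 0], [0, 100], [30, 50], [100, 50]))
    # scale A' offset to hit exact ratio errors of 0.02 and 0.04
    p1 = LandmarkSet.from_array(_coords([0, 0], [0, 100], [32, 50], [100, 50]))
    p2 = LandmarkSet.from_array(_coords([0, 0], [0, 100], [34, 50], [100, 50]))
    res = an_ratio_error([p1, p2], [gt, gt])
    assert res.mae == pytest.approx(0.03, abs=1e-12)


def test_an_ratio_error_excludes_degenerate_samples():
    gt = LandmarkSet.from_array(_coords([0, 0], [0, 100], [30, 50], [100, 50]))
    degenerate = _coords([1, 1], [1, 1], [2, 2], [3, 3])  # Ba == Ar
    with pytest.warns(UserWarning):
        res = an_ratio_error([gt.as_array(), degenerate], [gt, gt])
    assert res.n_used == 1 and res.n_excluded == 1


def test_an_ratio_error_rigid_invariance(rng):
    """Jointly transforming pred and gt landmark sets leaves the MAE fixed."""
    import math
    for _ in range(100):
        gt = random_landmarks(rng)
        pred = LandmarkSet.from_array(gt.as_array() + rng.normal(0, 1, (4, 2)))
        base = an_ratio_error([pred], [gt]).mae
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        t = rng.uniform(-100, 100, 2)
        moved = an_ratio_error([pred.transformed(lambda a: a @ R.T + t)],
                               [gt.transformed(lambda a: a @ R.T + t)]).mae
        assert moved == pytest.approx(base, abs=1e-9)


def test_diagnostic_metrics_worked_confusion_matrix():
    """TP=29, FN=3, TN=120, FP=8 -> the cohort-style marginal rates."""
    gt = [True] * 32 + [False] * 128
    pred = [True] * 29 + [False] * 3 + [False] * 120 + [True] * 8
    rep = diagnostic_metrics(pred, gt)
    assert (rep.tp, rep.fn, rep.tn, rep.fp) == (29, 3, 120, 8)
    assert rep.sensitivity == pytest.approx(0.90625)
    assert rep.specificity == pytest.approx(0.9375)
    assert rep.accuracy == pytest.approx(0.93125)
    assert rep.f1 == pytest.approx(2 * rep.precision * rep.recall
                                   / (rep.precision + rep.recall))
    assert rep.lr_positive == pytest.approx(rep.sensitivity / (1 - rep.specificity))
    assert rep.lr_negative == pytest.approx((1 - rep.sensitivity) / rep.specificity)


def test_diagnostic_metrics_perfect_and_degenerate():
    gt = [True] * 3 + [False] * 5
    rep = diagnostic_metrics(gt, gt)
    assert rep.sensitivity == rep.specificity == rep.accuracy == rep.f1 == 1.0
    assert rep.lr_negative == 0.0
    all_neg = diagnostic_metrics([False] * 8, gt)
    assert all_neg.sensitivity == 0.0 and all_neg.specificity == 1.0
    with pytest.raises(UndefinedMetricError):
        diagnostic_metrics([True, False], [True, True])


def test_wilson_ci_contains_estimate_and_shrinks():
    gt = [True] * 32 + [False] * 128
    pred = [True] * 29 + [False] * 3 + [False] * 120 + [True] * 8
    rep = diagnostic_metrics(pred, gt)
    for key, value in (("sensitivity", rep.sensitivity),
                       ("specificity", rep.specificity),
                       ("accuracy", rep.accuracy)):
        lo, hi = rep.ci[key]
        assert lo <= value <= hi
    big = diagnostic_metrics(pred * 10, gt * 10)
    for key in ("sensitivity", "specificity", "accuracy"):
        assert (big.ci[key][1] - big.ci[key][0]) < (rep.ci[key][1] - rep.ci[key][0])


def test_roc_auc_extremes():
    labels = [True, True, False, False]
    perfect = roc_auc([0.9, 0.8, 0.2, 0.1], labels, n_boot=50)
    assert perfect.auc == 1.0
    ties = roc_auc([0.5, 0.5, 0.5, 0.5], labels, n_boot=50)
    assert ties.auc == 0.5
    with pytest.raises(UndefinedMetricError):
        roc_auc([0.5, 0.6], [True, True], n_boot=10)


def test_roc_auc_worked_example():
    res = roc_auc([0.7, 0.65, 0.5, 0.4], [True, False, True, False], n_boot=50)
    assert res.auc == pytest.approx(0.75)  # 3 wins of 4 positive-negative pairs


def _mann_whitney(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_equals_all_pairs_mann_whitney(rng):
    for _ in range(100):
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        res = roc_auc(scores, labels, n_boot=2)
        assert res.auc == pytest.approx(_mann_whitney(scores, labels), abs=1e-9)


def test_roc_curve_monotone_and_ci_brackets_auc(rng):
    scores = rng.random(60)
    labels = scores + rng.normal(0, 0.3, 60) > 0.5
    if labels.all() or not labels.any():
        labels[0], labels[-1] = False, True
    res = roc_auc(scores, labels, n_boot=200, seed=0)
    assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
    assert 0.0 <= res.auc_ci[0] <= res.auc_ci[1] <= 1.0
    res2 = roc_auc(scores, labels, n_boot=200, seed=0)
    assert res2.auc_ci == res.auc_ci  # bootstrap is seeded


def test_threshold_consistency_with_classifier(rng):
    """Thresholding true ratios at 0.6 reproduces classify_ah labels exactly."""
    ratios = rng.uniform(0.2, 0.95, 200)
    labels_a = [r > 0.6 for r in ratios]
    labels_b = [classify_ah(r) == "hypertrophic" for r in ratios]
    rep = diagnostic_metrics(labels_a, labels_b)
    assert rep.accuracy == 1.0
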