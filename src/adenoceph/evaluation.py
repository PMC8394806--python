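"""Evaluation metrics: localization error, AP/AR, A/N error, diagnostics, ROC.

Keypoint AP/AR use a PCK-style rule: with exactly one prediction per
ground-truth keypoint, a prediction is correct at threshold ``t`` iff its
Euclidean error is at most ``t`` pixels; precision equals recall at each
threshold and AP/AR are their means over thresholds 1..10 px by default.

Confidence intervals: Wilson score (statsmodels) for proportions, stratified
bootstrap over samples for the AUC. The ROC treats the predicted A/N ratio
as a continuous diagnostic score with "hypertrophic" as the positive class.

A note on likelihood ratios: the standard formulas LR+ = sens/(1-spec) and
LR- = (1-sens)/spec are used. For sens 0.906 / spec 0.938 they give 14.6 and
0.100; published values of 10 and 0.067 for the same operating point arise
only if sensitivity and specificity exchange roles in those formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .geometry import KEYPOINT_NAMES, LandmarkSet, compute_an

__all__ = [
    "LocalizationTable",
    "ANRatioErrorResult",
    "DiagnosticReport",
    "ROCResult",
    "UndefinedMetricError",
    "localization_errors",
    "keypoint_ap_ar",
    "an_ratio_error",
    "diagnostic_metrics",
    "roc_auc",
]

POSITIVE_LABEL = "hypertrophic"


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given labels (e.g. single-class truth)."""


def _as_coord_stack(items) -> np.ndarray:
    arrs = [x.as_array() if isinstance(x, LandmarkSet) else np.asarray(x, float)
            for x in items]
    out = np.stack(arrs) if arrs else np.zeros((0, 4, 2))
    if out.shape[1:] != (4, 2):
        raise ValueError(f"expected (n, 4, 2) landmarks, got {out.shape}")
    return out


@dataclass(frozen=True)
class LocalizationTable:
    """Mean Euclidean error per keypoint plus the across-keypoint average."""

    per_keypoint: Dict[str, float]
    average: float

    def as_dict(self) -> Dict[str, float]:
        return {**self.per_keypoint, "average": self.average}


def localization_errors(preds: Sequence, gts: Sequence) -> LocalizationTable:
    """Per-keypoint mean Euclidean distance between predictions and truth."""
    p, g = _as_coord_stack(preds), _as_coord_stack(gts)
    if p.shape != g.shape:
        raise ValueError(f"prediction/truth mismatch: {p.shape} vs {g.shape}")
    if len(p) == 0:
        raise ValueError("empty evaluation set")
    dists = np.linalg.norm(p - g, axis=2)          # (n, 4)
    per_kp = {name: float(dists[:, i].mean())
              for i, name in enumerate(KEYPOINT_NAMES)}
    return LocalizationTable(per_keypoint=per_kp, average=float(dists.mean()))


def keypoint_ap_ar(preds: Sequence, gts: Sequence,
                   thresholds: Sequence[float] = tuple(range(1, 11)),
                   ) -> Tuple[float, float]:
    """PCK-style average precision and recall over distance thresholds.

    A keypoint counts as correctly detected at threshold ``t`` iff its error
    is <= t pixels; with one prediction per keypoint precision and recall
    coincide at each threshold, and AP/AR are their means over thresholds.
    """
    if len(thresholds) == 0:
        raise ValueError("empty threshold list")
    p, g = _as_coord_stack(preds), _as_coord_stack(gts)
    if p.shape != g.shape:
        raise ValueError(f"prediction/truth mismatch: {p.shape} vs {g.shape}")
    dists = np.linalg.norm(p - g, axis=2).ravel()
    fracs = [float((dists <= t).mean()) for t in thresholds]
    ap = float(np.mean(fracs))
    return ap, ap


@dataclass(frozen=True)
class ANRatioErrorResult:
    """Mean absolute A/N ratio error; degenerate samples are excluded."""

    mae: float
    n_used: int
    n_excluded: int


def an_ratio_error(preds: Sequence, gts: Sequence) -> ANRatioErrorResult:
    """Mean |predicted ratio - true ratio| over evaluable samples."""
    if len(preds) != len(gts):
        raise ValueError("prediction/truth length mismatch")
    errors: List[float] = []
    n_excluded = 0
    for i, (p, g) in enumerate(zip(preds, gts)):
        try:
            pl = p if isinstance(p, LandmarkSet) else LandmarkSet.from_array(p)
            gl = g if isinstance(g, LandmarkSet) else LandmarkSet.from_array(g)
            errors.append(abs(compute_an(pl).ratio - compute_an(gl).ratio))
        except (ValueError, ZeroDivisionError) as exc:
            n_excluded += 1
            warnings.warn(f"sample {i} excluded from A/N error: {exc}")
    if not errors:
        raise UndefinedMetricError("no evaluable samples for A/N ratio error")
    return ANRatioErrorResult(mae=float(np.mean(errors)),
                              n_used=len(errors), n_excluded=n_excluded)


def _to_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    return arr == POSITIVE_LABEL


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion-matrix diagnostics with Wilson 95% CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    lr_positive: float
    lr_negative: float
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("tp", "fp", "tn", "fn", "sensitivity", "specificity", "accuracy",
              "precision", "recall", "f1", "lr_positive", "lr_negative")}
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def _wilson(count: int, nobs: int) -> Tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def diagnostic_metrics(pred_labels, gt_labels) -> DiagnosticReport:
    """Binary diagnostics with the hypertrophic class as positive.

    Sensitivity/specificity/accuracy/precision carry Wilson score 95% CIs.
    Likelihood ratios use the standard definitions (may be ``inf`` when the
    denominator is zero).
    """
    pred = _to_binary(pred_labels)
    gt = _to_binary(gt_labels)
    if pred.shape != gt.shape or pred.ndim != 1:
        raise ValueError("labels must be aligned 1-D sequences")
    if gt.all() or not gt.any():
        raise UndefinedMetricError(
            "sensitivity and specificity undefined: ground truth has a single class")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    tn = int((~pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(gt)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    lr_pos = sens / (1 - spec) if spec < 1 else float("inf")
    lr_neg = (1 - sens) / spec if spec > 0 else float("inf")
    ci = {
        "sensitivity": _wilson(tp, tp + fn),
        "specificity": _wilson(tn, tn + fp),
        "accuracy": _wilson(tp + tn, len(gt)),
    }
    if tp + fp:
        ci["precision"] = _wilson(tp, tp + fp)
    return DiagnosticReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                            specificity=spec, accuracy=acc, precision=prec,
                            recall=sens, f1=f1, lr_positive=lr_pos,
                            lr_negative=lr_neg, ci=ci)


@dataclass(frozen=True)
class ROCResult:
    """ROC curve points, AUC and its bootstrap 95% CI."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: Tuple[float, float]
    n_boot: int


def roc_auc(scores, gt_labels, n_boot: int = 2000,
            seed: int = 0) -> ROCResult:
    """ROC and AUC of a continuous score (the predicted A/N ratio).

    The AUC equals the Mann–Whitney statistic (ties counted 1/2); the 95% CI
    is a percentile bootstrap stratified by class so every resample contains
    both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = _to_binary(gt_labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D sequences")
    if y.all() or not y.any():
        raise UndefinedMetricError("ROC undefined: single-class ground truth")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    pos, neg = s[y], s[~y]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        bs = np.concatenate([bp, bn])
        by = np.concatenate([np.ones(len(bp), bool), np.zeros(len(bn), bool)])
        boots[b] = roc_auc_score(by, bs)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                     auc_ci=(float(lo), float(hi)), n_boot=n_boot)
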