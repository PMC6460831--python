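"""Confusion-matrix metrics, Q9, ROC/PR curves and cross-validation folds.

Sensitivity, specificity and Matthews correlation follow the usual
definitions. Q9 is a class-skew-invariant global accuracy: with both
classes present, q9 = 1 - sqrt(2) * sqrt((FN/(TP+FN))^2 + (FP/(TN+FP))^2)
and Q9 = (1+q9)/2, so Q9 = 1 exactly when there are no errors; when one
class is absent q9 degrades to the other class's signed accuracy.

PR curves use the Davis-Goadrich construction: precision cannot be
interpolated linearly between operating points, so intermediate points
are generated by stepping the true-positive count one unit at a time with
false positives accruing at the local skew, and the area is taken on the
densified curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_metrics",
    "q9",
    "roc_pr",
    "kfold_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_predictions(cls, labels: Sequence[bool], predicted: Sequence[bool]) -> "ConfusionCounts":
        lab = np.asarray(labels, bool)
        pred = np.asarray(predicted, bool)
        return cls(
            int((lab & pred).sum()),
            int((~lab & pred).sum()),
            int((~lab & ~pred).sum()),
            int((lab & ~pred).sum()),
        )


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity and MCC; undefined values reported as NaN/0.

    MCC with a zero marginal is reported as 0.0 with ``mcc_defined=False``
    (the usual convention for a degenerate denominator).
    """
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    denom = (
        (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom > 0:
        mcc = (c.tp * c.tn - c.fn * c.fp) / math.sqrt(denom)
        defined = True
    else:
        mcc, defined = 0.0, False
    return {"SN": sn, "SP": sp, "MCC": mcc, "mcc_defined": defined}


def q9(c: ConfusionCounts) -> float:
    """Global accuracy Q9 = (1+q9)/2, invariant to class skew."""
    if c.tp + c.fn + c.tn + c.fp == 0:
        raise ValueError("empty confusion matrix")
    if c.tp + c.fn == 0:
        q = (c.tn - c.fp) / (c.tn + c.fp)
    elif c.tn + c.fp == 0:
        q = (c.tp - c.fn) / (c.tp + c.fn)
    else:
        q = 1.0 - math.sqrt(2.0) * math.sqrt(
            (c.fn / (c.tp + c.fn)) ** 2 + (c.fp / (c.tn + c.fp)) ** 2
        )
    return (1.0 + q) / 2.0


def _threshold_counts(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) after each distinct score threshold, descending.

    Equal scores are grouped into a single step, so ties never create
    artificial operating points.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    boundary = np.nonzero(np.diff(s))[0]
    last = np.concatenate([boundary, [len(s) - 1]])
    tp = np.cumsum(lab)[last].astype(float)
    fp = np.cumsum(~lab)[last].astype(float)
    return tp, fp


def roc_pr(scores: Sequence[float], labels: Sequence[bool]) -> dict:
    """ROC and PR curves with their areas.

    Returns a dict with ``roc`` (list of (FPR, TPR)), ``pr`` (list of
    (recall, precision) on the Davis-Goadrich densified curve),
    ``auc_roc`` (trapezoidal) and ``auc_pr`` (trapezoid on the densified
    curve).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must be parallel")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("curve construction needs both classes")

    tp, fp = _threshold_counts(scores, labels)
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc_roc = float(np.trapezoid(tpr, fpr))

    # Davis-Goadrich densification: between achievable points, step TP by
    # one unit with FP growing at the local skew; precision follows.
    pts = [(0.0, 0.0)]  # (TP, FP), virtual origin
    pts += list(zip(tp, fp))
    recall = [0.0]
    # precision at recall 0 taken as precision of the first achievable point
    first_prec = tp[0] / (tp[0] + fp[0]) if (tp[0] + fp[0]) > 0 else 1.0
    precision = [first_prec]
    for (tp_a, fp_a), (tp_b, fp_b) in zip(pts[:-1], pts[1:]):
        d_tp = tp_b - tp_a
        if d_tp <= 0:
            # vertical in FP only: recall unchanged, precision drops
            if tp_b + fp_b > 0:
                recall.append(tp_b / n_pos)
                precision.append(tp_b / (tp_b + fp_b))
            continue
        skew = (fp_b - fp_a) / d_tp
        steps = int(round(d_tp)) if abs(d_tp - round(d_tp)) < 1e-9 else 0
        xs = np.arange(1, steps + 1, dtype=float) if steps else np.array([d_tp])
        for x in xs:
            t = tp_a + x
            f = fp_a + skew * x
            recall.append(t / n_pos)
            precision.append(t / (t + f) if (t + f) > 0 else 1.0)
    rec = np.asarray(recall)
    prec = np.asarray(precision)
    auc_pr = float(np.trapezoid(prec, rec))

    return {
        "roc": list(zip(fpr.tolist(), tpr.tolist())),
        "pr": list(zip(rec.tolist(), prec.tolist())),
        "auc_roc": auc_roc,
        "auc_pr": auc_pr,
    }


def kfold_split(
    n: int,
    k: int,
    seed: int,
    labels: Sequence[bool] | None = None,
) -> list[np.ndarray]:
    """Random k folds of 0..n-1 with sizes differing by at most one.

    With ``labels`` given, folds are stratified: each class is shuffled
    and dealt separately so every fold preserves the class ratio as
    closely as integer counts allow.
    """
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= n")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if labels is None:
        perm = rng.permutation(n)
        for i, idx in enumerate(perm):
            folds[i % k].append(int(idx))
    else:
        lab = np.asarray(labels, bool)
        if len(lab) != n:
            raise ValueError("labels length must equal n")
        cursor = 0
        for cls in (True, False):
            members = rng.permutation(np.nonzero(lab == cls)[0])
            for idx in members:
                folds[cursor % k].append(int(idx))
                cursor += 1
    return [np.array(sorted(f), dtype=np.int64) for f in folds]
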