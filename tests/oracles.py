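"""Independent reference implementations used only to cross-check results.

These deliberately avoid the package's own code paths: chi-square values
come from scipy.stats.chi2_contingency, merge search is a plain recursive
routine over dicts/lists, and curve areas are computed by dense numeric
integration between achievable operating points.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import chi2, chi2_contingency


def _safe_chi2(table: np.ndarray) -> float:
    """Pearson statistic via scipy, dropping all-zero columns first."""
    keep = table.sum(axis=0) > 0
    t = table[:, keep]
    if t.shape[1] < 2 or t.sum(axis=1).min() == 0:
        return 0.0
    return float(chi2_contingency(t, correction=False)[0])


def compress_reference(counts: np.ndarray, ordinal: bool, alpha: float) -> list[tuple]:
    """Greedy merge search re-implemented from scratch; returns final groups."""
    cols = [counts[:, j].astype(float).copy() for j in range(counts.shape[1])]
    groups = [(j,) for j in range(counts.shape[1])]
    while len(cols) > 1:
        if ordinal:
            pairs = [(j, j + 1) for j in range(len(cols) - 1)]
        else:
            pairs = [(i, j) for i in range(len(cols)) for j in range(i + 1, len(cols))]
        best, best_stat = None, -1.0
        for i, j in pairs:
            merged = [c for k, c in enumerate(cols) if k != j]
            merged[i] = cols[i] + cols[j]
            stat = _safe_chi2(np.column_stack(merged)) if len(merged) > 1 else 0.0
            if stat > best_stat:
                best, best_stat = (i, j), stat
        i, j = best
        if cols[i].sum() == 0 or cols[j].sum() == 0:
            p = 1.0
        else:
            local = np.column_stack([cols[i], cols[j]])
            stat = _safe_chi2(local)
            p = float(chi2.sf(stat, 1))
        if p < alpha:
            break
        cols[i] = cols[i] + cols[j]
        groups[i] = groups[i] + groups[j]
        del cols[j], groups[j]
    return groups


def pr_auc_reference(scores, labels) -> float:
    """AUC-PR by brute-force threshold enumeration with interpolated points.

    Between consecutive achievable (TP, FP) operating points, intermediate
    points are created for every integer TP with FP accruing at the local
    skew; the area is the trapezoid sum over the densified recall axis.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    pts = [(0, 0.0)]
    for thresh in sorted(set(scores), reverse=True):
        sel = scores >= thresh
        pts.append((int((labels & sel).sum()), float((~labels & sel).sum())))
    first = next(p for p in pts[1:] if p[0] + p[1] > 0)
    rec = [0.0]
    prec = [first[0] / (first[0] + first[1]) if first[0] > 0 else 0.0]
    for (tp_a, fp_a), (tp_b, fp_b) in zip(pts[:-1], pts[1:]):
        if tp_b == tp_a:
            if tp_b + fp_b > 0:
                rec.append(tp_b / n_pos)
                prec.append(tp_b / (tp_b + fp_b))
            continue
        skew = (fp_b - fp_a) / (tp_b - tp_a)
        for t in range(tp_a + 1, tp_b + 1):
            f = fp_a + skew * (t - tp_a)
            rec.append(t / n_pos)
            prec.append(t / (t + f))
    area = 0.0
    for k in range(1, len(rec)):
        area += (rec[k] - rec[k - 1]) * (prec[k] + prec[k - 1]) / 2
    return area


def entropy_reference(pos: float, neg: float) -> float:
    total = pos + neg
    h = 0.0
    for c in (pos, neg):
        if c:
            h -= (c / total) * math.log2(c / total)
    return h


def gain_reference(parent: list[tuple[float, float]], refined: list[tuple[float, float]]) -> float:
    n = sum(p + q for p, q in parent)
    hp = sum((p + q) / n * entropy_reference(p, q) for p, q in parent if p + q)
    hr = sum((p + q) / n * entropy_reference(p, q) for p, q in refined if p + q)
    return hp - hr


def iv_reference(sizes) -> float:
    n = sum(sizes)
    return -sum(s / n * math.log2(s / n) for s in sizes if s)
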