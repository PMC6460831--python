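"""Decision-table classifier with gain-ratio feature introduction.

The model partitions feature space into conjunctive rules by introducing
features one at a time. Each round, every remaining feature's 2xr
contingency table is compressed *within every current cell* of the
partition; a feature whose table collapses to a single column everywhere
carries no residual class signal and is not a candidate. Among candidates
whose information gain is at least the candidates' mean gain, the one
with the highest gain ratio is introduced, splitting each cell by that
feature's cell-specific status groups (cells where it collapsed stay
whole, which is why rules have variable length). Introduction stops when
no candidate remains.

The fitted rules' positive/negative sample counts form a 2xK decision
table. Under class imbalance each rule's negative count is multiplied by
theta = N+/N-, equalising the two rows' totals. A test sample matching
rule k is classified by a +/-1 perturbation: add 1 to the rule's positive
count and compute the whole-table chi-square, then instead add 1 to its
(weighted) negative count and recompute; the hypothesis that disturbs the
table more is the predicted class, with ties going to negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .contingency import ContingencyTable, DegenerateTableError, chi2_stat, compress
from .features import FeatureSpec, LabeledWindow, default_feature_specs, encode_batch

__all__ = [
    "entropy",
    "information_gain",
    "gain_ratio",
    "PartitionCell",
    "introduce_features",
    "DecisionTable",
    "build_decision_table",
    "Prediction",
    "classify",
    "DonorSiteModel",
    "fit",
    "predict_batch",
]


def entropy(pos_count: float, neg_count: float) -> float:
    """Binary Shannon entropy of a class-count pair, in bits."""
    if pos_count < 0 or neg_count < 0:
        raise ValueError("counts must be nonnegative")
    total = pos_count + neg_count
    if total == 0:
        raise DegenerateTableError("entropy of an empty set is undefined")
    h = 0.0
    for c in (pos_count, neg_count):
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def _weighted_entropy(cells: Sequence[tuple[float, float]], total: float) -> float:
    h = 0.0
    for pos, neg in cells:
        size = pos + neg
        if size > 0:
            h += (size / total) * entropy(pos, neg)
    return h


def information_gain(
    parent_cells: Sequence[tuple[float, float]],
    refined_cells: Sequence[tuple[float, float]],
) -> float:
    """Reduction in weighted class entropy from refining a partition.

    ``parent_cells`` and ``refined_cells`` are (positive, negative) count
    pairs; the refined cells must redistribute exactly the parents' mass.
    """
    parent_total = sum(p + n for p, n in parent_cells)
    refined_total = sum(p + n for p, n in refined_cells)
    if parent_total <= 0:
        raise DegenerateTableError("empty parent partition")
    if not math.isclose(parent_total, refined_total, rel_tol=1e-9):
        raise ValueError("refined cells do not partition the parent cells")
    return _weighted_entropy(parent_cells, parent_total) - _weighted_entropy(
        refined_cells, parent_total
    )


def gain_ratio(gain: float, subcell_sizes: Sequence[float]) -> float:
    """Gain divided by the intrinsic value of the split.

    The intrinsic value IV = -sum (|D^j|/|D|) log2(|D^j|/|D|) over nonempty
    sub-cells penalises many-way splits. A single nonempty sub-cell gives
    IV = 0, in which case the feature is not a valid candidate and a
    ValueError is raised rather than dividing by zero.
    """
    sizes = [s for s in subcell_sizes if s > 0]
    total = sum(sizes)
    if total <= 0:
        raise ValueError("no nonempty sub-cells")
    iv = -sum((s / total) * math.log2(s / total) for s in sizes)
    if iv == 0.0:
        raise ValueError("single sub-cell: intrinsic value is zero")
    return gain / iv


def intrinsic_value(subcell_sizes: Sequence[float]) -> float:
    """IV of a split: entropy of the sub-cell size distribution, in bits."""
    sizes = [s for s in subcell_sizes if s > 0]
    total = sum(sizes)
    if total <= 0:
        raise ValueError("no nonempty sub-cells")
    return -sum((s / total) * math.log2(s / total) for s in sizes)


@dataclass
class PartitionCell:
    """One conjunctive rule: conditions plus its training-sample indices."""

    conditions: list[tuple[str, tuple]]  # (feature id, status group)
    indices: np.ndarray
    pos_count: float = 0.0
    neg_count: float = 0.0


def _cell_table(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, fcol: int, spec: FeatureSpec
) -> ContingencyTable:
    """2xr table of feature ``fcol`` over the samples in ``idx``."""
    r = len(spec.domain)
    vals = X[idx, fcol]
    lab = y[idx]
    pos = np.bincount(vals[lab], minlength=r).astype(float)
    neg = np.bincount(vals[~lab], minlength=r).astype(float)
    return ContingencyTable(
        np.vstack([pos, neg]), [(s,) for s in spec.domain], ordinal=spec.ordinal
    )


def introduce_features(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[FeatureSpec],
    alpha: float = 0.01,
    min_cell_size: int = 0,
) -> tuple[list[str], list[PartitionCell]]:
    """Iteratively introduce features, refining the rule partition.

    ``X`` holds status indices (samples x features), ``y`` is True for
    positives. Returns the introduced feature ids in order and the final
    cells; with a one-class training set no feature is introduced and the
    single root cell is returned. ``min_cell_size`` optionally stops a
    cell from being split below that many samples (0 disables the guard).
    """
    n = len(y)
    cells = [PartitionCell([], np.arange(n), float(y.sum()), float((~y).sum()))]
    if cells[0].pos_count == 0 or cells[0].neg_count == 0:
        return [], cells

    spec_by_id = {s.id: k for k, s in enumerate(specs)}
    remaining = [s.id for s in specs]
    introduced: list[str] = []
    total = float(n)

    while remaining:
        # Per remaining feature: compress its table inside every cell and
        # record the resulting split; candidates keep >=2 groups somewhere.
        candidates: dict[str, dict] = {}
        for fid in remaining:
            fcol = spec_by_id[fid]
            spec = specs[fcol]
            splits = []  # per cell: list of (group, sub_idx) or None if unsplit
            any_split = False
            for cell in cells:
                if min_cell_size and len(cell.indices) < min_cell_size:
                    splits.append(None)
                    continue
                table = _cell_table(X, y, cell.indices, fcol, spec)
                compressed, _ = compress(table, alpha)
                if compressed.r < 2:
                    splits.append(None)
                    continue
                any_split = True
                vals = X[cell.indices, fcol]
                groups = compressed.column_groups
                member = {s: gi for gi, g in enumerate(groups) for s in g}
                assign = np.array([member[spec.domain[v]] for v in vals])
                splits.append(
                    [(groups[gi], cell.indices[assign == gi]) for gi in range(len(groups))]
                )
            if not any_split:
                continue
            refined = []
            for cell, split in zip(cells, splits):
                if split is None:
                    refined.append((cell.pos_count, cell.neg_count))
                else:
                    for _, sub in split:
                        refined.append((float(y[sub].sum()), float(len(sub) - y[sub].sum())))
            parent = [(c.pos_count, c.neg_count) for c in cells]
            gain = information_gain(parent, refined)
            sizes = [p + q for p, q in refined if p + q > 0]
            if len(sizes) < 2:
                continue
            candidates[fid] = {
                "gain": gain,
                "ratio": gain / intrinsic_value(sizes),
                "splits": splits,
            }

        if not candidates:
            break
        mean_gain = sum(c["gain"] for c in candidates.values()) / len(candidates)
        eligible = [fid for fid, c in candidates.items() if c["gain"] >= mean_gain - 1e-12]
        # max gain ratio; ties resolved by canonical spec order (list order)
        best = max(eligible, key=lambda fid: candidates[fid]["ratio"])

        new_cells: list[PartitionCell] = []
        for cell, split in zip(cells, candidates[best]["splits"]):
            if split is None:
                new_cells.append(cell)
                continue
            for group, sub in split:
                pos = float(y[sub].sum())
                new_cells.append(
                    PartitionCell(
                        cell.conditions + [(best, tuple(group))],
                        sub,
                        pos,
                        float(len(sub)) - pos,
                    )
                )
        cells = new_cells
        introduced.append(best)
        remaining.remove(best)

    return introduced, cells


@dataclass
class DecisionTable:
    """2xK rule table with optional class rebalancing.

    ``neg_weighted[k] = neg_raw[k] * theta``; with theta = N+/N- the two
    rows carry equal total mass, so the +/-1 chi-square decision is not
    swamped by the majority class. Weighted counts are kept unrounded.
    """

    rules: list[list[tuple[str, tuple]]]
    pos_counts: np.ndarray
    neg_raw: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.pos_counts = np.asarray(self.pos_counts, float)
        self.neg_raw = np.asarray(self.neg_raw, float)

    @property
    def neg_weighted(self) -> np.ndarray:
        return self.neg_raw * self.theta

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def display_rows(self) -> list[tuple[str, float, float]]:
        """(rule text, positives, 1-dp weighted negatives) for reporting."""
        out = []
        for rule, a, b in zip(self.rules, self.pos_counts, self.neg_weighted):
            text = " AND ".join(f"{fid} in {{{','.join(map(str, g))}}}" for fid, g in rule) or "(all)"
            out.append((text, float(a), round(float(b), 1)))
        return out


def build_decision_table(
    partition: Sequence[PartitionCell],
    balanced: bool = True,
    theta_override: float | None = None,
) -> DecisionTable:
    """Tally rule counts and set the negative-row weight theta."""
    pos = np.array([c.pos_count for c in partition], float)
    neg = np.array([c.neg_count for c in partition], float)
    if theta_override is not None:
        theta = float(theta_override)
    elif balanced:
        n_neg = neg.sum()
        if n_neg == 0:
            raise ValueError("cannot balance a table with no negative samples")
        theta = pos.sum() / n_neg
    else:
        theta = 1.0
    return DecisionTable([list(c.conditions) for c in partition], pos, neg, theta)


@dataclass(frozen=True)
class Prediction:
    """Classification of one sample with its two hypothesis chi-squares."""

    label: bool
    chi2_pos: float
    chi2_neg: float
    rule_index: int

    @property
    def score(self) -> float:
        return self.chi2_pos - self.chi2_neg


def classify_rule(table: DecisionTable, rule_index: int) -> Prediction:
    """Apply the +/-1 chi-square decision for a sample matching ``rule_index``.

    Hypothesis 'positive' adds 1 to the rule's positive count; hypothesis
    'negative' adds 1 to its weighted negative count. The larger resulting
    whole-table chi-square wins; a tie is called negative.
    """
    a = table.pos_counts.copy()
    b = table.neg_weighted.copy()
    if table.n_rules == 1:
        return Prediction(False, 0.0, 0.0, rule_index)
    a_plus = a.copy()
    a_plus[rule_index] += 1.0
    chi2_pos = chi2_stat(np.vstack([a_plus, b]))
    b_plus = b.copy()
    b_plus[rule_index] += 1.0
    chi2_neg = chi2_stat(np.vstack([a, b_plus]))
    return Prediction(chi2_pos > chi2_neg, chi2_pos, chi2_neg, rule_index)


def match_rule(table: DecisionTable, specs: Sequence[FeatureSpec], values: np.ndarray) -> int:
    """Index of the unique rule whose conditions the encoded sample satisfies."""
    spec_by_id = {s.id: k for k, s in enumerate(specs)}
    for k, rule in enumerate(table.rules):
        ok = True
        for fid, group in rule:
            spec = specs[spec_by_id[fid]]
            if spec.domain[values[spec_by_id[fid]]] not in group:
                ok = False
                break
        if ok:
            return k
    raise RuntimeError("sample matched no rule; partition is not exhaustive")


def classify(
    values: np.ndarray, table: DecisionTable, specs: Sequence[FeatureSpec]
) -> Prediction:
    """Match an encoded sample to its rule and apply the +/-1 decision."""
    return classify_rule(table, match_rule(table, specs, values))


@dataclass
class DonorSiteModel:
    """Fitted decision-table model plus the config needed to apply it."""

    specs: list[FeatureSpec]
    introduced: list[str]
    table: DecisionTable
    alpha: float
    upstream: int
    downstream: int
    compositional: bool = True

    def reweighted(self, theta: float) -> "DonorSiteModel":
        """Same rules and raw counts under a different negative-row weight."""
        table = DecisionTable(
            [list(r) for r in self.table.rules],
            self.table.pos_counts.copy(),
            self.table.neg_raw.copy(),
            float(theta),
        )
        return DonorSiteModel(list(self.specs), list(self.introduced), table,
                              self.alpha, self.upstream, self.downstream,
                              self.compositional)

    # -- persistence: structured JSON, bit-exact round trip ----------------
    def to_dict(self) -> dict:
        return {
            "format": "chidt-model",
            "version": __version__,
            "alpha": self.alpha,
            "upstream": self.upstream,
            "downstream": self.downstream,
            "compositional": self.compositional,
            "introduced": self.introduced,
            "theta": self.table.theta,
            "rules": [
                {
                    "conditions": [[fid, list(g)] for fid, g in rule],
                    "positive": a,
                    "negative_raw": b,
                }
                for rule, a, b in zip(
                    self.table.rules,
                    self.table.pos_counts.tolist(),
                    self.table.neg_raw.tolist(),
                )
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "DonorSiteModel":
        if d.get("format") != "chidt-model":
            raise ValueError("not a chidt model file")
        specs = default_feature_specs(d["upstream"], d["downstream"],
                                      d.get("compositional", True))
        rules = [
            [(fid, tuple(g)) for fid, g in rule["conditions"]] for rule in d["rules"]
        ]
        table = DecisionTable(
            rules,
            np.array([r["positive"] for r in d["rules"]], float),
            np.array([r["negative_raw"] for r in d["rules"]], float),
            float(d["theta"]),
        )
        return cls(list(specs), list(d["introduced"]), table, d["alpha"],
                   d["upstream"], d["downstream"], d.get("compositional", True))

    @classmethod
    def from_json(cls, text: str) -> "DonorSiteModel":
        return cls.from_dict(json.loads(text))

    # -- vectorised matching ----------------------------------------------
    def match_batch(self, X: np.ndarray) -> np.ndarray:
        """Rule index for each row of an encoded sample matrix."""
        spec_by_id = {s.id: k for k, s in enumerate(self.specs)}
        out = np.full(len(X), -1, dtype=np.int64)
        unmatched = np.ones(len(X), dtype=bool)
        for k, rule in enumerate(self.table.rules):
            mask = unmatched.copy()
            for fid, group in rule:
                col = spec_by_id[fid]
                spec = self.specs[col]
                member = np.array([s in group for s in spec.domain])
                mask &= member[X[:, col]]
            out[mask] = k
            unmatched &= ~mask
        if unmatched.any():
            raise RuntimeError("some samples matched no rule; partition not exhaustive")
        return out

    def predict(self, windows: Sequence[LabeledWindow]) -> list[Prediction]:
        X, _ = encode_batch(windows, self.specs)
        idx = self.match_batch(X)
        cache: dict[int, Prediction] = {}
        preds = []
        for k in idx:
            k = int(k)
            if k not in cache:
                cache[k] = classify_rule(self.table, k)
            preds.append(cache[k])
        return preds


def fit(
    windows: Sequence[LabeledWindow],
    upstream: int = 3,
    downstream: int = 8,
    alpha: float = 0.01,
    balanced: bool = True,
    theta_override: float | None = None,
    min_cell_size: int = 0,
    compositional: bool = True,
) -> DonorSiteModel:
    """Train a decision-table model on labelled windows."""
    if not windows:
        raise ValueError("empty training set")
    specs = default_feature_specs(upstream, downstream, compositional)
    X, y = encode_batch(windows, specs)
    if not (y.any() and (~y).any()):
        raise ValueError("training set must contain both classes")
    introduced, cells = introduce_features(X, y, specs, alpha, min_cell_size)
    table = build_decision_table(cells, balanced=balanced, theta_override=theta_override)
    return DonorSiteModel(list(specs), introduced, table, alpha, upstream, downstream,
                          compositional)


def predict_batch(model: DonorSiteModel, windows: Sequence[LabeledWindow]) -> list[Prediction]:
    """Order-preserving predictions for a batch of windows."""
    return model.predict(windows)
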