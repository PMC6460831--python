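"""Chi-square statistics on 2xr contingency tables and greedy column compression.

A feature's class association is summarised by a 2xr contingency table:
row 0 counts positive samples, row 1 counts negative samples, and each of
the r columns corresponds to a *status group* — one original status value
of the feature, or several merged together. Compression greedily merges
the pair of columns whose merged table keeps the chi-square statistic
maximal, accepting a merge only when a local 2x2 test finds the two
columns class-indistinguishable (p >= alpha). Merging stops at the first
rejected merge, so the surviving columns are exactly the status groups
that carry class information.

Counts may be real-valued: reweighted decision tables scale the negative
row by a positive constant and the Pearson statistic applies unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "ContingencyTable",
    "MergeDecision",
    "DegenerateTableError",
    "chi2_stat",
    "chi2_pvalue",
    "chi2_log10_inv_pvalue",
    "local_merge_test",
    "compress",
    "grid_mutual_information",
]

DEFAULT_ALPHA = 0.01


class DegenerateTableError(ValueError):
    """Raised when a table has no mass to test (all counts zero)."""


@dataclass(frozen=True)
class MergeDecision:
    """Record of one attempted column merge during compression."""

    pair: tuple[int, int]
    local_p: float
    accepted: bool


@dataclass
class ContingencyTable:
    """A 2xr table of class-by-status counts.

    ``column_groups[j]`` lists the original status symbols pooled into
    column j.  For ordinal features the groups must be contiguous runs of
    the ordered status domain and only adjacent columns may merge.
    """

    counts: np.ndarray
    column_groups: list[tuple] = field(default_factory=list)
    ordinal: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("counts must be a 2xr matrix")
        if self.counts.shape[1] < 1:
            raise ValueError("need at least one column")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.column_groups:
            self.column_groups = [(j,) for j in range(self.counts.shape[1])]
        if len(self.column_groups) != self.counts.shape[1]:
            raise ValueError("one status group per column required")
        self.column_groups = [tuple(g) for g in self.column_groups]

    @property
    def r(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self) -> str:
        """Render as group / positive / negative TSV (round-trips via from_tsv)."""
        lines = ["group\tpositive\tnegative"]
        for g, (a, b) in zip(self.column_groups, self.counts.T):
            lines.append(f"{','.join(str(s) for s in g)}\t{float(a)!r}\t{float(b)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, ordinal: bool = False) -> "ContingencyTable":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        groups = [tuple(r[0].split(",")) for r in rows]
        counts = np.array([[float(r[1]) for r in rows], [float(r[2]) for r in rows]])
        return cls(counts, groups, ordinal=ordinal)


def chi2_stat(table: ContingencyTable | np.ndarray | Sequence) -> float:
    """Pearson chi-square statistic of a 2xr table, no continuity correction.

    Cells whose expected value is zero (an all-zero row or column)
    contribute nothing.  Raises :class:`DegenerateTableError` on an
    all-zero table.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, float)
    return _chi2_stat_raw(counts)


def _chi2_stat_raw(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        raise DegenerateTableError("all-zero contingency table")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / total
    mask = expected > 0
    diff = counts[mask] - expected[mask]
    return float(np.sum(diff * diff / expected[mask]))


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail p-value of the chi-square distribution."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if stat < 0:
        raise ValueError("statistic must be nonnegative")
    return float(_chi2_dist.sf(stat, df))


def chi2_log10_inv_pvalue(stat: float, df: int) -> float:
    """log10(1/p) computed in log space; finite even when p underflows."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(-_chi2_dist.logsf(stat, df) / math.log(10))


def local_merge_test(col_a: Sequence[float], col_b: Sequence[float]) -> float:
    """p-value of the local 2x2 test on two columns proposed for merging.

    A column with zero total carries no evidence against merging and the
    test returns 1, so status values unseen in training are always
    absorbed into some group (this is what makes downstream decision
    rules exhaustive).
    """
    a = np.asarray(col_a, float)
    b = np.asarray(col_b, float)
    if a.sum() == 0 or b.sum() == 0:
        return 1.0
    local = np.column_stack([a, b])
    stat = _chi2_stat_raw(local)
    return chi2_pvalue(stat, 1)


def _candidate_pairs(r: int, ordinal: bool) -> list[tuple[int, int]]:
    if ordinal:
        return [(j, j + 1) for j in range(r - 1)]
    return [(i, j) for i in range(r) for j in range(i + 1, r)]


def _merge_columns(counts: np.ndarray, i: int, j: int) -> np.ndarray:
    merged = np.delete(counts, j, axis=1)
    merged[:, i] = counts[:, i] + counts[:, j]
    return merged


def compress(
    table: ContingencyTable, alpha: float = DEFAULT_ALPHA
) -> tuple[ContingencyTable, list[MergeDecision]]:
    """Greedily merge columns until a local 2x2 test rejects the merge.

    Each round considers every admissible column pair (all pairs for
    categorical tables, adjacent pairs for ordinal ones), merges the pair
    whose resulting 2x(r-1) table has maximal chi-square statistic, and
    keeps the merge only if the local 2x2 test of the two columns gives
    p >= alpha; the first rejection backtracks and stops. A table may
    compress all the way to a single column, meaning the feature carries
    no class signal in this context.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    counts = table.counts.copy()
    groups = list(table.column_groups)
    decisions: list[MergeDecision] = []

    while counts.shape[1] > 1:
        pairs = _candidate_pairs(counts.shape[1], table.ordinal)
        best_pair = None
        best_stat = -np.inf
        for i, j in pairs:
            merged = _merge_columns(counts, i, j)
            try:
                stat = _chi2_stat_raw(merged) if merged.shape[1] > 1 else 0.0
            except DegenerateTableError:
                stat = 0.0
            # ties go to the smaller leftmost index: pairs are generated in
            # that order, so strict > keeps the first maximiser
            if stat > best_stat:
                best_stat = stat
                best_pair = (i, j)
        i, j = best_pair
        p_local = local_merge_test(counts[:, i], counts[:, j])
        if p_local >= alpha:
            decisions.append(MergeDecision((i, j), p_local, True))
            counts = _merge_columns(counts, i, j)
            groups[i] = tuple(groups[i]) + tuple(groups[j])
            del groups[j]
        else:
            decisions.append(MergeDecision((i, j), p_local, False))
            break

    return ContingencyTable(counts, groups, ordinal=table.ordinal), decisions


def grid_mutual_information(table: ContingencyTable | np.ndarray | Sequence) -> tuple[float, float]:
    """Mutual information (bits) of a count grid and its normalised value.

    Normalisation divides by log2(min(#rows, #cols)), the maximum MI a
    grid of that shape can attain, yielding a value in [0, 1].
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, float)
    total = counts.sum()
    if total <= 0:
        raise DegenerateTableError("empty grid")
    p = counts / total
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pi * pj))
    mi = float(np.nansum(terms))
    mi = max(mi, 0.0)  # clip tiny negative rounding
    denom = math.log2(min(counts.shape))
    normalized = mi / denom if denom > 0 else 0.0
    return mi, min(normalized, 1.0)
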