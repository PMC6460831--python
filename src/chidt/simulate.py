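"""Synthetic donor-site sequence generation and indel mutation.

True donor sites show strong base preferences at a handful of offsets
around the invariant GT (the classic consensus MAG|GTRAGT: C/A at -3, A
at -2, G at -1, then A/G, A, G, T immediately downstream). The generator
emulates exactly the structure the classifier exploits: positives draw
their window bases from a position-weight model around a forced GT while
negatives are background sequence with a decoy GT forced at the same
anchor, so the two classes share composition and differ only in
positional structure.

Datasets mimic the benchmark layout: full sequences of 140 nt with the GT
at 1-based positions 71-72, at configurable positive:negative imbalance.
A separate mutator introduces random single-base insertions and deletions
at a fixed per-position rate, emulating sequencing frameshift errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BASES

__all__ = [
    "DonorPWM",
    "SimConfig",
    "IMBALANCE_PRESETS",
    "generate_dataset",
    "mutate_indels",
    "make_worked_fixtures",
]

# Base-preference directions of the canonical donor consensus for window
# offsets -3..+8 (GT excluded). Each row is the preferred-base profile at
# full sharpness; the working PWM mixes these with the background.
_CONSENSUS = {
    "-3": (0.35, 0.35, 0.15, 0.15),  # M = A/C
    "-2": (0.60, 0.10, 0.15, 0.15),  # A
    "-1": (0.10, 0.05, 0.80, 0.05),  # G
    "+1": (0.50, 0.02, 0.45, 0.03),  # R = A/G
    "+2": (0.70, 0.08, 0.12, 0.10),  # A
    "+3": (0.07, 0.05, 0.83, 0.05),  # G
    "+4": (0.15, 0.15, 0.17, 0.53),  # T
    "+5": (0.25, 0.20, 0.35, 0.20),
    "+6": (0.25, 0.25, 0.25, 0.25),
    "+7": (0.25, 0.25, 0.25, 0.25),
    "+8": (0.25, 0.25, 0.25, 0.25),
}
_BACKGROUND = (0.27, 0.23, 0.23, 0.27)


@dataclass
class DonorPWM:
    """Per-offset base probabilities for the donor window plus background.

    ``sharpness`` controls how conserved the positive windows are:
    1 reproduces the consensus frequencies, values in [0,1) mix the
    columns linearly toward the background (0 = indistinguishable from
    background), and values above 1 concentrate each column on its
    preferred bases (p_b proportional to p_b^sharpness), emulating a
    site with stronger conservation than the average consensus.
    """

    columns: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    background: tuple[float, float, float, float] = _BACKGROUND
    sharpness: float = 1.0

    def __post_init__(self) -> None:
        if self.sharpness < 0:
            raise ValueError("sharpness must be nonnegative")
        if not self.columns:
            self.columns = dict(_CONSENSUS)
        bg = np.asarray(self.background, float)
        mixed = {}
        for lab, col in self.columns.items():
            col = np.asarray(col, float)
            if np.any(col < 0):
                raise ValueError("probabilities must be nonnegative")
            if self.sharpness <= 1:
                c = self.sharpness * col + (1 - self.sharpness) * bg
            else:
                c = col**self.sharpness
            c = c / c.sum()
            mixed[lab] = tuple(c)
        self.columns = mixed
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")


@dataclass
class SimConfig:
    """Dataset shape: counts, sequence geometry, indel rate and seed."""

    n_pos: int
    n_neg: int
    seq_length: int = 140
    gt_position: int = 71  # 1-based position of the G
    upstream: int = 3
    downstream: int = 8
    seed: int = 0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be nonnegative")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel rate must lie in [0,1)")
        if self.gt_position - self.upstream < 1 or self.gt_position + 1 + self.downstream > self.seq_length:
            raise ValueError("window does not fit inside the sequence")


#: positive:negative ratio presets at the benchmark's training-set scale
IMBALANCE_PRESETS = {
    "1:1": (2000, 2000),
    "1:10": (2000, 20000),
    "1:20": (2000, 40000),
    "1:50": (2000, 100000),
    "1:135": (2000, 271132),
}


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of one global seed (reproducible pipelines)."""
    return np.random.default_rng([seed, int.from_bytes(name.encode(), "little") % (2**31)])


def _draw_column(rng: np.random.Generator, probs, n: int) -> np.ndarray:
    """n draws from a 4-way base distribution (inverse-CDF, vectorised)."""
    cdf = np.cumsum(np.asarray(probs, float))
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.int8)


def generate_dataset(cfg: SimConfig, pwm: DonorPWM | None = None) -> list[tuple[str, str, bool]]:
    """Generate (record id, sequence, label) triples.

    Positives carry PWM-drawn bases at the window offsets and background
    elsewhere; negatives are pure background. Both have GT forced at the
    anchor, so every record is a valid GT candidate and discrimination
    must come from the flanking structure.
    """
    pwm = pwm or DonorPWM()
    base_arr = np.array(list("ACGT"))
    g0 = cfg.gt_position - 1
    labels_up = [str(-k) for k in range(cfg.upstream, 0, -1)]
    labels_down = [f"+{k}" for k in range(1, cfg.downstream + 1)]
    records: list[tuple[str, str, bool]] = []

    rng_pos = _substream(cfg.seed, "positives")
    rng_neg = _substream(cfg.seed, "negatives")
    rng_mut = _substream(cfg.seed, "indels")

    if cfg.n_pos:
        mat = _draw_column(rng_pos, pwm.background, cfg.n_pos * cfg.seq_length).reshape(
            cfg.n_pos, cfg.seq_length
        )
        for j, lab in enumerate(labels_up):
            mat[:, g0 - cfg.upstream + j] = _draw_column(rng_pos, pwm.columns[lab], cfg.n_pos)
        for j, lab in enumerate(labels_down):
            mat[:, g0 + 2 + j] = _draw_column(rng_pos, pwm.columns[lab], cfg.n_pos)
        mat[:, g0], mat[:, g0 + 1] = 2, 3  # G, T
        for i, row in enumerate(mat):
            records.append((f"pos_{i}", "".join(base_arr[row]), True))

    if cfg.n_neg:
        mat = _draw_column(rng_neg, pwm.background, cfg.n_neg * cfg.seq_length).reshape(
            cfg.n_neg, cfg.seq_length
        )
        mat[:, g0], mat[:, g0 + 1] = 2, 3
        for i, row in enumerate(mat):
            records.append((f"neg_{i}", "".join(base_arr[row]), False))

    if cfg.indel_rate > 0:
        records = [
            (rid, mutate_indels(seq, cfg.indel_rate, rng=rng_mut), lab)
            for rid, seq, lab in records
        ]
    return records


def mutate_indels(
    sequence: str,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Hit each position independently with probability ``rate``.

    A hit deletes the base or inserts one uniform random base before it,
    each with probability 1/2, so the expected length is unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0,1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rate == 0:
        return sequence
    out = []
    hits = rng.random(len(sequence)) < rate
    kinds = rng.random(len(sequence)) < 0.5  # True = deletion
    for c, hit, is_del in zip(sequence, hits, kinds):
        if not hit:
            out.append(c)
        elif is_del:
            continue
        else:
            out.append(BASES[rng.integers(4)])
            out.append(c)
    return "".join(out)


def make_worked_fixtures() -> dict:
    """Small printed-table fixtures used by the worked examples and tests.

    Keys: ``table14`` (imbalanced 2x4 rule counts, 87/1687 samples),
    ``table15_negatives`` (the 1-dp balanced negative row), ``theta14``
    and ``theta_main`` (reweighting factors), ``table2_negatives`` (raw
    first/last rule negative counts), and ``mi_grid`` (2x3 count grid).
    """
    return {
        "table14": np.array([[38, 12, 26, 11], [184, 1026, 289, 188]], float),
        "table15_negatives": np.array([9.5, 52.9, 14.9, 9.7]),
        "theta14": 87.0 / 1687.0,
        "theta_main": 2000.0 / 271132.0,
        "table2_negatives": np.array([47512.0, 368.0]),
        "mi_grid": np.array([[0, 4, 6], [2, 0, 8]], float),
    }
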