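"""Window extraction around GT anchors and feature encoding.

Donor splice sites sit at exon-intron boundaries whose intron side almost
always begins with the dinucleotide GT. Prediction therefore reduces to
discriminating true donor GTs from the vastly more numerous decoy GTs,
using a short window of flanking sequence: by default the 3 bases
immediately upstream and the 8 bases immediately downstream of the GT
(offsets -3..-1 and +1..+8), the GT itself excluded.

Each window is described by 27 features: 11 positional features (the base
at each labelled offset, categorical over {A,C,G,T}) and 16 compositional
features (the count of each dinucleotide among the window's overlapping
pairs, ordinal over 0..L-1 for a window of length L).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .contingency import (
    ContingencyTable,
    chi2_log10_inv_pvalue,
    chi2_stat,
    compress,
)

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(BASES, repeat=2))

DEFAULT_UPSTREAM = 3
DEFAULT_DOWNSTREAM = 8


class AnchorError(ValueError):
    """The claimed GT anchor position does not hold a GT."""


class WindowBoundsError(ValueError):
    """The requested window extends past the sequence ends."""


class AlphabetError(ValueError):
    """A window contains a base outside {A,C,G,T}."""


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed-length ACGT window with its class label.

    ``origin`` optionally records (source record id, 1-based GT position).
    """

    sequence: str
    label: bool
    origin: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if any(c not in BASE_INDEX for c in self.sequence):
            raise AlphabetError(f"non-ACGT base in window {self.sequence!r}")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: a positional base identity or a dinucleotide count."""

    id: str
    kind: str  # "categorical" | "ordinal"
    domain: tuple = ()

    @property
    def ordinal(self) -> bool:
        return self.kind == "ordinal"


def position_labels(upstream: int, downstream: int) -> list[str]:
    """Offset labels -u..-1, +1..+d with the GT anchor implicit at 00."""
    return [str(-k) for k in range(upstream, 0, -1)] + [f"+{k}" for k in range(1, downstream + 1)]


def default_feature_specs(
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    compositional: bool = True,
) -> list[FeatureSpec]:
    """Positional specs for every window offset plus the 16 dinucleotide counts.

    ``compositional=False`` drops the dinucleotide-count features, leaving
    the purely positional encoding (useful for ablation: composition is
    what buys tolerance to frameshift errors).
    """
    window_len = upstream + downstream
    specs = [FeatureSpec(lab, "categorical", BASES) for lab in position_labels(upstream, downstream)]
    if compositional:
        count_domain = tuple(range(window_len))
        specs += [FeatureSpec(d, "ordinal", count_domain) for d in DINUCLEOTIDES]
    return specs


def extract_window(
    sequence: str,
    gt_position: int,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    label: bool = False,
    origin_id: str | None = None,
) -> LabeledWindow:
    """Cut the window flanking a GT whose G sits at 1-based ``gt_position``.

    The window concatenates ``upstream`` bases 5' of the G and
    ``downstream`` bases 3' of the T; the GT itself is excluded.
    """
    seq = sequence.upper()
    g0 = gt_position - 1  # 0-based index of the G
    if g0 < 0 or g0 + 1 >= len(seq) or seq[g0 : g0 + 2] != "GT":
        raise AnchorError(f"no GT at 1-based position {gt_position}")
    if g0 - upstream < 0 or g0 + 2 + downstream > len(seq):
        raise WindowBoundsError("window exceeds sequence bounds")
    window = seq[g0 - upstream : g0] + seq[g0 + 2 : g0 + 2 + downstream]
    origin = (origin_id, gt_position) if origin_id is not None else None
    return LabeledWindow(window, label, origin)


def encode(window: LabeledWindow | str, specs: Sequence[FeatureSpec]) -> np.ndarray:
    """Encode a window as one status index per feature spec.

    Positional features map the base at the spec's offset to its index in
    {A,C,G,T}; compositional features count the named dinucleotide among
    the window's overlapping pairs.
    """
    seq = window.sequence if isinstance(window, LabeledWindow) else window
    values = np.empty(len(specs), dtype=np.int64)
    pos_cursor = 0
    for k, spec in enumerate(specs):
        if spec.kind == "categorical":
            values[k] = BASE_INDEX[seq[pos_cursor]]
            pos_cursor += 1
        else:
            values[k] = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == spec.id)
    return values


def encode_batch(windows: Iterable[LabeledWindow], specs: Sequence[FeatureSpec]) -> tuple[np.ndarray, np.ndarray]:
    """Encode windows into an (n, n_features) status matrix plus label vector."""
    rows, labels = [], []
    for w in windows:
        rows.append(encode(w, specs))
        labels.append(w.label)
    if not rows:
        return np.empty((0, len(specs)), dtype=np.int64), np.empty(0, dtype=bool)
    return np.vstack(rows), np.asarray(labels, dtype=bool)


@dataclass
class ImportanceRecord:
    """Per-position class-association summary after table compression."""

    position: str
    compressed_r: int
    chi2: float
    log10_inv_p: float


def position_importance(
    sequences: Sequence[str],
    labels: Sequence[bool],
    position: int,
    alpha: float = 0.01,
    label_text: str | None = None,
) -> ImportanceRecord:
    """Chi-square importance of one 1-based position across full sequences.

    Builds the position's 2x4 base table, compresses it, then scores the
    compressed table: chi-square statistic and log10(1/p) with r-1 degrees
    of freedom. p-values are handled in log space, so positions with
    overwhelming signal still get finite scores.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be represented")
    counts = np.zeros((2, 4))
    for seq, lab in zip(sequences, labels):
        if position < 1 or position > len(seq):
            raise WindowBoundsError(f"position {position} outside sequence")
        base = seq[position - 1].upper()
        if base in BASE_INDEX:
            counts[0 if lab else 1, BASE_INDEX[base]] += 1
    table = ContingencyTable(counts, [(b,) for b in BASES])
    compressed, _ = compress(table, alpha)
    if compressed.r == 1:
        return ImportanceRecord(label_text or str(position), 1, 0.0, 0.0)
    stat = chi2_stat(compressed)
    return ImportanceRecord(
        label_text or str(position),
        compressed.r,
        stat,
        chi2_log10_inv_pvalue(stat, compressed.r - 1),
    )


def importance_profile(
    sequences: Sequence[str],
    labels: Sequence[bool],
    anchor: int,
    span: int = 15,
    alpha: float = 0.01,
) -> list[ImportanceRecord]:
    """Importance of every offset -span..+span around the GT anchor at 1-based ``anchor``."""
    records = []
    for off in range(-span, span + 1):
        if off == 0:
            continue
        pos = anchor + off if off < 0 else anchor + 1 + off
        lab = str(off) if off < 0 else f"+{off}"
        records.append(position_importance(sequences, labels, pos, alpha, label_text=lab))
    return records


def select_window(
    profile: Sequence[ImportanceRecord],
    data_driven: bool = False,
    reference_position: str = "-2",
    default: tuple[int, int] = (DEFAULT_UPSTREAM, DEFAULT_DOWNSTREAM),
) -> tuple[int, int]:
    """Choose (upstream, downstream) flank lengths from an importance profile.

    The default rule returns the fixed (3, 8) window. The data-driven rule
    takes the maximal contiguous run of offsets around the anchor whose
    log10(1/p) exceeds the reference position's value; a degenerate run
    falls back to the default.
    """
    if not data_driven:
        return default
    by_label = {r.position: r for r in profile}
    ref = by_label.get(reference_position)
    if ref is None:
        return default
    threshold = ref.log10_inv_p

    def important(off: int) -> bool:
        lab = str(off) if off < 0 else f"+{off}"
        rec = by_label.get(lab)
        return rec is not None and rec.log10_inv_p > threshold

    up = 0
    while important(-(up + 1)):
        up += 1
    down = 0
    while important(down + 1):
        down += 1
    if up == 0 and down == 0:
        return default
    return up, down


@dataclass
class CandidateSite:
    """A GT occurrence with full flanks; coordinates 1-based at the G."""

    record_id: str
    gt_position: int
    window: str


def enumerate_candidate_sites(
    sequence: str,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    record_id: str = "",
) -> tuple[list[CandidateSite], int]:
    """Scan a sequence for GT-anchored candidate windows.

    Returns one candidate per GT occurrence whose flanks fit inside the
    sequence, plus the count of candidates skipped because their window
    contained a non-ACGT character.
    """
    seq = sequence.upper()
    sites: list[CandidateSite] = []
    skipped = 0
    start = upstream  # 0-based index of the earliest admissible G
    stop = len(seq) - downstream - 2
    idx = seq.find("GT", start)
    while 0 <= idx <= stop:
        window = seq[idx - upstream : idx] + seq[idx + 2 : idx + 2 + downstream]
        if all(c in BASE_INDEX for c in window):
            sites.append(CandidateSite(record_id, idx + 1, window))
        else:
            skipped += 1
        idx = seq.find("GT", idx + 1)
    return sites, skipped
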