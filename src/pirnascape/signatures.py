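"""piRNA biogenesis signatures.

Two sequence-level signatures distinguish the piRNA biogenesis routes:
primary piRNAs carry a 5' uridine (1U), while ping-pong amplified secondary
piRNAs carry an adenine at position 10 (10A) and sit antisense to their
initiating partner with the two 5' ends overlapping by exactly 10 nt.  This
module computes positional base-composition matrices, per-position base
enrichment, first-base preference by read length, and the ping-pong
5'-overlap profile with a z-score for the 10-nt bin.

Coordinates follow the BED convention: 0-based, half-open, with the 5' end
of a minus-strand alignment at ``end - 1``.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .sequences import as_rna_base, normalize_dna

RNA_BASES = ("U", "A", "G", "C")

#: 5'-5' overlap bins tallied by the ping-pong profile.
OVERLAP_RANGE = range(1, 21)

#: Overlap length diagnostic of ping-pong amplification.
PING_PONG_OVERLAP = 10


@dataclass(frozen=True)
class AlignmentRecord:
    """A genome alignment of a collapsed read (BED-style coordinates)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    count: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.read_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (highest coordinate on minus)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PositionalBaseMatrix:
    """Count-weighted base fractions at 1-based positions 1..k (5'->3')."""

    freq: dict[int, dict[str, float]]

    def fraction(self, position: int, base: str) -> float:
        return self.freq.get(position, {}).get(as_rna_base(base), 0.0)


@dataclass
class FirstBaseByLength:
    freq: dict[int, dict[str, float]]

    def fraction(self, length: int, base: str) -> float:
        return self.freq.get(length, {}).get(as_rna_base(base), 0.0)


@dataclass
class PingPongProfile:
    """Counts of opposite-strand 5'-5' overlaps and the bin-10 z-score.

    ``z10`` standardises the 10-nt bin against the mean and sample standard
    deviation of the other bins; it is 0 when that sd is 0 (including the
    no-pairs case).
    """

    overlap_counts: dict[int, float]
    z10: float


def _position_base_counts(
    seqs: Iterable[tuple[str, int]], k: int
) -> tuple[dict[int, Counter], Counter]:
    per_pos: dict[int, Counter] = {p: Counter() for p in range(1, k + 1)}
    overall: Counter = Counter()
    n_seqs = 0
    for seq, count in seqs:
        n_seqs += 1
        dna = normalize_dna(seq)
        for i, b in enumerate(dna):
            if b == "N":
                continue
            base = as_rna_base(b)
            overall[base] += count
            if i < k:
                per_pos[i + 1][base] += count
    if n_seqs == 0:
        raise ValueError("no sequences provided")
    return per_pos, overall


def positional_base_frequencies(
    seqs: Iterable[tuple[str, int]], k: int
) -> PositionalBaseMatrix:
    """Base fractions at positions 1..k, count-weighted.

    Sequences shorter than ``k`` contribute only to the positions they cover;
    positions with no coverage are omitted from the matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_pos, _ = _position_base_counts(seqs, k)
    freq: dict[int, dict[str, float]] = {}
    for pos, counts in per_pos.items():
        total = sum(counts.values())
        if total == 0:
            continue
        freq[pos] = {b: counts[b] / total for b in RNA_BASES}
    return PositionalBaseMatrix(freq)


def position_enrichment(
    seqs: Iterable[tuple[str, int]], base: str, k: int
) -> tuple[dict[int, float], int]:
    """Per-position enrichment of ``base`` over its sequence-wide fraction.

    ``enrichment(p) = freq(base at p) / overall freq(base)``; returns the
    enrichment map and the argmax position (ties break to the smallest p).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    target = as_rna_base(base)
    if target not in RNA_BASES:
        raise ValueError(f"invalid base {base!r}")
    per_pos, overall = _position_base_counts(seqs, k)
    grand = sum(overall.values())
    overall_frac = overall[target] / grand if grand else 0.0
    if overall_frac == 0.0:
        raise ValueError(f"base {base!r} never occurs; enrichment undefined")
    enrichment: dict[int, float] = {}
    for pos, counts in per_pos.items():
        total = sum(counts.values())
        if total == 0:
            continue
        enrichment[pos] = (counts[target] / total) / overall_frac
    argmax = min(p for p, e in enrichment.items() if e == max(enrichment.values()))
    return enrichment, argmax


def first_base_by_length(seqs: Iterable[tuple[str, int]]) -> FirstBaseByLength:
    """Per observed read length, count-weighted fraction of each first base."""
    counts: dict[int, Counter] = defaultdict(Counter)
    for seq, count in seqs:
        dna = normalize_dna(seq)
        if not dna or dna[0] == "N":
            continue
        counts[len(dna)][as_rna_base(dna[0])] += count
    freq = {
        length: {b: c[b] / sum(c.values()) for b in RNA_BASES}
        for length, c in counts.items()
    }
    return FirstBaseByLength(freq)


def _z_score(bins: dict[int, float]) -> float:
    others = [bins[o] for o in OVERLAP_RANGE if o != PING_PONG_OVERLAP]
    n = len(others)
    mean = sum(others) / n
    var = sum((x - mean) ** 2 for x in others) / (n - 1)
    sd = math.sqrt(var)
    if sd == 0.0:
        return 0.0
    return (bins[PING_PONG_OVERLAP] - mean) / sd


def ping_pong_profile(alignments: Sequence[AlignmentRecord]) -> PingPongProfile:
    """Tally opposite-strand 5'-5' overlaps of 1..20 nt and compute z10.

    For a plus-strand read with 5' end at ``a`` and a minus-strand read with
    5' end at ``b`` on the same chromosome, the overlap is ``b - a + 1``.
    Each qualifying pair contributes ``count_plus * count_minus``.
    """
    bins: dict[int, float] = {o: 0.0 for o in OVERLAP_RANGE}
    # weight of minus-strand 5' ends per chromosome
    minus: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    plus: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for aln in alignments:
        side = plus if aln.strand == "+" else minus
        side[aln.chrom][aln.five_prime] += aln.count
    for chrom, plus_ends in plus.items():
        minus_ends = minus.get(chrom)
        if not minus_ends:
            continue
        for a, wp in plus_ends.items():
            for o in OVERLAP_RANGE:
                wm = minus_ends.get(a + o - 1)
                if wm:
                    bins[o] += wp * wm
    return PingPongProfile(bins, _z_score(bins))


def ping_pong_profile_naive(alignments: Sequence[AlignmentRecord]) -> PingPongProfile:
    """All-pairs reference implementation of :func:`ping_pong_profile`.

    Quadratic in the number of alignments; used as an independent oracle in
    tests, not in analysis code.
    """
    bins: dict[int, float] = {o: 0.0 for o in OVERLAP_RANGE}
    for p in alignments:
        if p.strand != "+":
            continue
        for m in alignments:
            if m.strand != "-" or m.chrom != p.chrom:
                continue
            o = m.five_prime - p.five_prime + 1
            if 1 <= o <= 20:
                bins[o] += p.count * m.count
    return PingPongProfile(bins, _z_score(bins))
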