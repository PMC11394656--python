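"""Small-RNA read profiling: ncRNA classification, length histograms, and
candidate piRNA calling.

A testis small-RNA library is a mixture of miRNA, rRNA-, tRNA-, snRNA- and
snoRNA-derived fragments, piRNAs and unannotated material.  Known ncRNA
classes are recognised by exact (sub)sequence match against reference sets;
reads that match nothing but fall in the piRNA length window and carry a
5' uridine (1U) or an adenine at position 10 (10A) are called candidate
piRNAs.  All tallies are copy-number weighted, following the collapsed-FASTA
convention in which a record ``>id_xN`` stands for N identical reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequences import normalize_dna

#: Default candidate piRNA length window (nt).
DEFAULT_PIRNA_WINDOW = (27, 32)

#: Alternative, wider window some mammalian testis datasets use.
WIDE_PIRNA_WINDOW = (24, 33)

#: Order in which known ncRNA classes are tried during classification.
CLASS_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed small-RNA read.

    ``count`` is the copy number of the collapsed sequence (>= 1); ``sample``
    optionally records the library of origin.
    """

    id: str
    sequence: str
    count: int = 1
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read {self.id}: count must be >= 1, got {self.count}")
        seq = normalize_dna(self.sequence)
        if not set(seq) <= set("ACGTN"):
            raise ValueError(f"read {self.id}: invalid characters in sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PiRNACandidate:
    """A read retained by the 1U / 10A candidate rule, with the rule flags."""

    read: SmallRNARead
    first_is_U: bool
    tenth_is_A: bool


@dataclass
class LengthHistogram:
    counts: dict[int, int]
    modal_length: int

    def __getitem__(self, length: int) -> int:
        return self.counts.get(length, 0)


@dataclass
class ClassComposition:
    """Percent of total (count-weighted) reads per small-RNA class."""

    percents: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, cls: str) -> float:
        return self.percents.get(cls, 0.0)


def _passes_candidate_rule(seq_dna: str) -> tuple[bool, bool]:
    first_u = seq_dna[0] == "T"
    tenth_a = len(seq_dna) >= 10 and seq_dna[9] == "A"
    return first_u, tenth_a


def call_pirna_candidates(
    reads: Iterable[SmallRNARead],
    window: tuple[int, int] = DEFAULT_PIRNA_WINDOW,
) -> list[PiRNACandidate]:
    """Call candidate piRNAs by length window and the 1U-or-10A rule.

    A read is retained iff ``window[0] <= length <= window[1]`` and its first
    base is U (1U) or its tenth base is A (10A).  The returned flags record
    which of the two rules fired.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window min {lo} > max {hi}")
    if lo < 10:
        raise ValueError(f"window min must be >= 10 so position 10 exists, got {lo}")
    out: list[PiRNACandidate] = []
    for read in reads:
        if not lo <= read.length <= hi:
            continue
        first_u, tenth_a = _passes_candidate_rule(normalize_dna(read.sequence))
        if first_u or tenth_a:
            out.append(PiRNACandidate(read, first_u, tenth_a))
    return out


def classify_reads(
    reads: Sequence[SmallRNARead],
    references: Mapping[str, Iterable[str]],
    pirna_window: tuple[int, int] = DEFAULT_PIRNA_WINDOW,
) -> dict[str, str]:
    """Label each read with a small-RNA class.

    Classes are tried in the fixed priority order rRNA -> tRNA -> snRNA ->
    snoRNA -> miRNA; a read matches a class when its sequence equals, or is an
    exact substring of, any reference sequence of that class.  Unmatched reads
    passing the candidate piRNA rule are labelled ``piRNA``; everything else is
    ``other``.  Deterministic and independent of read order.
    """
    # one joined haystack per class; '#' stops matches spanning two references
    haystacks: dict[str, str] = {}
    for cls, seqs in references.items():
        joined = "#".join(normalize_dna(s) for s in seqs)
        if joined:
            haystacks[cls] = joined

    lo, hi = pirna_window
    labels: dict[str, str] = {}
    for read in reads:
        seq = normalize_dna(read.sequence)
        label = None
        for cls in CLASS_PRIORITY:
            hay = haystacks.get(cls)
            if hay is not None and seq in hay:
                label = cls
                break
        if label is None:
            if lo <= len(seq) <= hi and any(_passes_candidate_rule(seq)):
                label = "piRNA"
            else:
                label = "other"
        labels[read.id] = label
    return labels


def length_histogram(
    reads: Iterable[SmallRNARead],
    restrict_class: str | None = None,
    labels: Mapping[str, str] | None = None,
) -> LengthHistogram:
    """Count-weighted read-length histogram; ties break to the smallest length."""
    if restrict_class is not None and labels is None:
        raise ValueError("labels are required when restrict_class is given")
    counts: Counter[int] = Counter()
    for read in reads:
        if restrict_class is not None and labels.get(read.id) != restrict_class:
            continue
        counts[read.length] += read.count
    if not counts:
        raise ValueError("no reads selected: empty histogram")
    peak = max(counts.values())
    modal = min(length for length, c in counts.items() if c == peak)
    return LengthHistogram(dict(counts), modal)


def class_composition(
    labels: Mapping[str, str],
    reads: Sequence[SmallRNARead],
) -> ClassComposition:
    """Percent of total copy-weighted reads per class, over labelled reads."""
    by_id = {r.id: r for r in reads}
    unknown = [rid for rid in labels if rid not in by_id]
    if unknown:
        raise KeyError(f"labels refer to unknown read ids, e.g. {unknown[0]!r}")
    totals: Counter[str] = Counter()
    grand = 0
    for rid, cls in labels.items():
        c = by_id[rid].count
        totals[cls] += c
        grand += c
    if grand == 0:
        raise ValueError("no reads to summarise")
    return ClassComposition({cls: 100.0 * c / grand for cls, c in totals.items()})
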