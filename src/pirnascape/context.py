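"""Genomic context of mapped piRNAs: repeat / gene / other assignment.

Mapped piRNAs are classified into a three-way genomic origin: repeat regions,
gene regions, or the unannotated remainder ("other").  A read is assigned to
the first category in priority order (repeat before gene by default,
reflecting the transposon-silencing role of repeat-derived piRNAs) for which
at least ``min_overlap_fraction`` of its bases fall inside that category's
intervals.  Overlap is strand-agnostic: piRNAs can silence transposons from
either strand.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .signatures import AlignmentRecord

CATEGORIES = ("repeat", "gene", "other")


@dataclass(frozen=True)
class AnnotationInterval:
    """A BED-style annotated interval of category ``repeat`` or ``gene``."""

    chrom: str
    start: int
    end: int
    category: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")
        if self.category not in ("repeat", "gene"):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class CategoryAssignment:
    read_id: str
    category: str
    overlap_bases: int


@dataclass
class CategorySummary:
    """Count-weighted percent of assigned piRNAs per genomic category."""

    percents: dict[str, float]

    def __getitem__(self, category: str) -> float:
        return self.percents.get(category, 0.0)


class CategoryIndex:
    """Merged, sorted per-(chrom, category) intervals for fast coverage sums."""

    def __init__(self, annotation: Iterable[AnnotationInterval]):
        raw: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        for iv in annotation:
            raw[(iv.chrom, iv.category)].append((iv.start, iv.end))
        self._merged: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        for key, ivs in raw.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[key] = ([s for s, _ in merged], [e for _, e in merged])

    def overlap_bases(self, chrom: str, start: int, end: int, category: str) -> int:
        """Bases of [start, end) covered by ``category`` intervals on chrom."""
        entry = self._merged.get((chrom, category))
        if entry is None:
            return 0
        starts, ends = entry
        total = 0
        # first merged interval that could reach start
        i = bisect_right(ends, start)
        while i < len(starts) and starts[i] < end:
            total += min(end, ends[i]) - max(start, starts[i])
            i += 1
        return total


def assign_category(
    aln: AlignmentRecord,
    annotation: Iterable[AnnotationInterval] | CategoryIndex,
    min_overlap_fraction: float = 0.5,
    priority: Sequence[str] = ("repeat", "gene"),
) -> CategoryAssignment:
    """Assign one mapped read to repeat / gene / other under the priority rule."""
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise ValueError(
            f"min_overlap_fraction must be in (0, 1], got {min_overlap_fraction}"
        )
    index = annotation if isinstance(annotation, CategoryIndex) else CategoryIndex(annotation)
    length = aln.end - aln.start
    for category in priority:
        ov = index.overlap_bases(aln.chrom, aln.start, aln.end, category)
        if ov / length >= min_overlap_fraction:
            return CategoryAssignment(aln.read_id, category, ov)
    return CategoryAssignment(aln.read_id, "other", 0)


def assign_categories(
    alignments: Iterable[AlignmentRecord],
    annotation: Iterable[AnnotationInterval],
    min_overlap_fraction: float = 0.5,
    priority: Sequence[str] = ("repeat", "gene"),
) -> list[CategoryAssignment]:
    """Vector form of :func:`assign_category` sharing one interval index."""
    index = CategoryIndex(annotation)
    return [
        assign_category(aln, index, min_overlap_fraction, priority)
        for aln in alignments
    ]


def category_summary(
    assignments: Sequence[CategoryAssignment],
    counts: Mapping[str, int],
) -> CategorySummary:
    """Count-weighted percent per category over all assigned reads."""
    if not assignments:
        raise ValueError("no assignments to summarise")
    weighted: Counter[str] = Counter()
    for a in assignments:
        try:
            c = counts[a.read_id]
        except KeyError:
            raise KeyError(f"no copy number for read {a.read_id!r}") from None
        weighted[a.category] += c
    total = sum(weighted.values())
    return CategorySummary({cat: 100.0 * weighted.get(cat, 0) / total for cat in CATEGORIES})


def assign_category_bruteforce(
    aln: AlignmentRecord,
    annotation: Sequence[AnnotationInterval],
    min_overlap_fraction: float = 0.5,
    priority: Sequence[str] = ("repeat", "gene"),
) -> CategoryAssignment:
    """Per-base oracle for :func:`assign_category` (tests only).

    Marks every covered base of the read explicitly instead of using the
    merged-interval index.
    """
    length = aln.end - aln.start
    for category in priority:
        covered = set()
        for iv in annotation:
            if iv.chrom != aln.chrom or iv.category != category:
                continue
            covered.update(range(max(aln.start, iv.start), min(aln.end, iv.end)))
        if len(covered) / length >= min_overlap_fraction:
            return CategoryAssignment(aln.read_id, category, len(covered))
    return CategoryAssignment(aln.read_id, "other", 0)
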