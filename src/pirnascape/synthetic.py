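"""Synthetic two-condition testis small-RNA data with full ground truth.

The generator emulates the statistical structure of a seasonal-breeder
testis small-RNA experiment: two conditions (breeding-season breeders, BSB,
and non-breeding-season animals, NBS) whose libraries differ mainly in their
piRNA share; piRNA lengths of 27-32 nt peaking at 30 nt against a miRNA peak
near 21-22 nt; 1U / 10A base biases; ping-pong partner pairs whose 5' ends
overlap by exactly 10 nt on opposite strands; a repeat / gene / other genomic
origin mix; and negative-binomial count matrices with a configurable
condition effect skewed toward upregulation in BSB.

Every read carries truth labels (class, genomic category, biogenesis role,
ping-pong partner), and every genome-derived read's sequence equals the
substring of the library's *realised* genome (returned as ``truth.genome``)
at its alignment coordinates, reverse-complemented on the minus strand.
All outputs are deterministic functions of (config, seed).

Bias mechanics: the 1U and 10A biases are written into a copy of the genome
at the read's first and tenth positions (yielding the realised genome), so
the sequence/coordinate invariant holds.  Within a ping-pong pair the two
biased positions are shared genomic bases - the primary's first base is the
secondary's tenth and vice versa - so a primary's 1U implies its partner's
10A by complementarity, exactly as in the ping-pong cycle itself.
Primaries carry both biases (the 10A preference is a population-level
feature of these libraries, not a secondary-only one), each drawn
independently with its own probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .context import AnnotationInterval
from .profile import SmallRNARead
from .references import load_reference_classes
from .sequences import reverse_complement
from .signatures import AlignmentRecord

CLASS_ORDER = ("piRNA", "miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "other")
ORIGIN_ORDER = ("repeat", "gene", "other")

#: Fragment-length range (nt, inclusive) for rRNA/tRNA/snRNA/snoRNA-derived reads.
FRAGMENT_LENGTHS = (18, 34)

#: Lengths used for unannotated ("other") reads; deliberately outside the
#: default piRNA window so class truth stays recoverable.
OTHER_LENGTHS = tuple(range(18, 27)) + tuple(range(33, 39))

# Longest possible footprint of a ping-pong pair: both reads at the maximum
# piRNA length minus the 10-nt 5' overlap.
_MAX_PAIR_SPAN = 32 + 32 - 10

DEFAULT_CLASS_FRACTIONS: dict[str, dict[str, float]] = {
    # piRNA shares are the midpoints of the observed per-condition ranges;
    # the remaining mass is split over the known classes with miRNA dominant.
    "BSB": {
        "piRNA": 0.678, "miRNA": 0.15, "rRNA": 0.07, "tRNA": 0.04,
        "snRNA": 0.02, "snoRNA": 0.012, "other": 0.03,
    },
    "NBS": {
        "piRNA": 0.237, "miRNA": 0.40, "rRNA": 0.15, "tRNA": 0.09,
        "snRNA": 0.04, "snoRNA": 0.033, "other": 0.05,
    },
}

DEFAULT_PIRNA_LENGTH_DIST: dict[int, float] = {
    27: 0.05, 28: 0.10, 29: 0.20, 30: 0.35, 31: 0.20, 32: 0.10,
}

DEFAULT_ORIGIN_FRACTIONS: dict[str, float] = {"repeat": 0.15, "gene": 0.01, "other": 0.84}


def _check_fraction_map(name: str, fractions: Mapping, tol: float = 1e-9) -> None:
    total = sum(fractions.values())
    if abs(total - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1, got {total}")
    if any(v < 0 for v in fractions.values()):
        raise ValueError(f"{name} has negative entries")


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic-data generator.

    See module docstring for what each group of parameters emulates.  The
    defaults are the package's reference study conditions.
    """

    class_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_CLASS_FRACTIONS.items()}
    )
    pirna_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PIRNA_LENGTH_DIST)
    )
    mirna_length_mode: int = 22
    q1U: float = 0.85
    q10A: float = 0.85
    pingpong_fraction: float = 0.3
    origin_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORIGIN_FRACTIONS)
    )
    nb_mean: float = 500.0
    nb_dispersion: float = 0.05
    de_fraction: float = 0.2
    de_up_share: float = 0.886
    effect_log2fc: float = 2.0
    n_reads: int = 200_000
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.class_fractions:
            raise ValueError("class_fractions must name at least one condition")
        for condition, fracs in self.class_fractions.items():
            if not fracs:
                raise ValueError(f"empty class fractions for condition {condition!r}")
            _check_fraction_map(f"class_fractions[{condition!r}]", fracs)
            unknown = set(fracs) - set(CLASS_ORDER)
            if unknown:
                raise ValueError(f"unknown classes {sorted(unknown)}")
        _check_fraction_map("pirna_length_dist", self.pirna_length_dist)
        if not set(self.pirna_length_dist) <= set(range(27, 33)):
            raise ValueError("pirna_length_dist support must lie within 27..32 nt")
        _check_fraction_map("origin_fractions", self.origin_fractions)
        if set(self.origin_fractions) - set(ORIGIN_ORDER):
            raise ValueError("origin_fractions keys must be repeat/gene/other")
        for name in ("q1U", "q10A", "pingpong_fraction", "de_fraction", "de_up_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.nb_mean <= 0:
            raise ValueError("nb_mean must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 per condition")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["pirna_length_dist"] = {int(k): v for k, v in raw["pirna_length_dist"].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class SyntheticGenome:
    name: str
    sequence: str
    annotation: list[AnnotationInterval]

    def category_blocks(self) -> dict[str, list[tuple[int, int]]]:
        """Per-category half-open blocks; 'other' is the annotation complement."""
        blocks: dict[str, list[tuple[int, int]]] = {"repeat": [], "gene": [], "other": []}
        for iv in self.annotation:
            blocks[iv.category].append((iv.start, iv.end))
        occupied = sorted(blocks["repeat"] + blocks["gene"])
        pos = 0
        for s, e in occupied:
            if s > pos:
                blocks["other"].append((pos, s))
            pos = max(pos, e)
        if pos < len(self.sequence):
            blocks["other"].append((pos, len(self.sequence)))
        return blocks


@dataclass
class TruthTable:
    """Ground-truth labels for generated reads and/or count matrices.

    ``reads``: per read id - true class, genomic category, biogenesis role
    (primary/secondary/n/a) and ping-pong partner id.
    ``expression``: per piRNA id - true DE status and true log2FC (BSB over NBS).
    ``genome``: the realised genome of a simulated library - the input genome
    with the library's 1U/10A bias bases written in, against which every
    alignment's sequence/coordinate invariant holds.
    """

    reads: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    genome: "SyntheticGenome | None" = None


def simulate_genome(
    length: int,
    repeat_fraction: float,
    gene_fraction: float,
    seed: int,
    name: str = "chr1",
) -> SyntheticGenome:
    """Uniform-random genome with disjoint repeat and gene blocks.

    Block base coverage matches the requested fractions exactly (rounding to
    whole bases); the remainder is unannotated "other" sequence.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if repeat_fraction < 0 or gene_fraction < 0 or repeat_fraction + gene_fraction > 0.9:
        raise ValueError("require repeat_fraction, gene_fraction >= 0 and sum <= 0.9")
    rng = np.random.default_rng(seed)

    def block_lengths(total: int, lo: int, hi: int) -> list[int]:
        lens: list[int] = []
        remaining = total
        while remaining > 0:
            l = min(int(rng.integers(lo, hi + 1)), remaining)
            lens.append(l)
            remaining -= l
        if len(lens) >= 2 and lens[-1] < 60:  # avoid slivers too short for reads
            sliver = lens.pop()
            lens[-1] += sliver
        return lens

    blocks = [("repeat", l) for l in block_lengths(round(length * repeat_fraction), 300, 1500)]
    blocks += [("gene", l) for l in block_lengths(round(length * gene_fraction), 500, 3000)]
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    other_total = length - sum(l for _, l in blocks)
    n_gaps = len(blocks) + 1
    w = rng.dirichlet(np.ones(n_gaps))
    gaps = np.floor(w * other_total).astype(int)
    gaps[-1] += other_total - gaps.sum()

    annotation: list[AnnotationInterval] = []
    pos = 0
    for i, (category, l) in enumerate(blocks):
        pos += int(gaps[i])
        annotation.append(AnnotationInterval(name, pos, pos + l, category))
        pos += l

    seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    sequence = seq.choose(np.frombuffer(b"ACGT", dtype=np.uint8)).tobytes().decode()
    return SyntheticGenome(name, sequence, annotation)


class _LocusSampler:
    """Draws read start positions uniformly inside category blocks.

    A locus for footprint length ``span`` is drawn from blocks of the
    requested category with probability proportional to the number of start
    positions that keep the whole footprint inside the block.
    """

    def __init__(self, blocks: Mapping[str, list[tuple[int, int]]], rng: np.random.Generator):
        self._rng = rng
        self._starts = {c: np.array([s for s, _ in b], dtype=np.int64) for c, b in blocks.items()}
        self._lens = {c: np.array([e - s for s, e in b], dtype=np.int64) for c, b in blocks.items()}
        self._cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def draw(self, category: str, span: int) -> int:
        key = (category, span)
        if key not in self._cache:
            usable = np.maximum(self._lens.get(category, np.empty(0, dtype=np.int64)) - span + 1, 0)
            total = int(usable.sum())
            if total == 0:
                raise ValueError(
                    f"no {category!r} block can hold a {span}-nt read footprint"
                )
            self._cache[key] = (np.cumsum(usable), usable)
        cum, usable = self._cache[key]
        r = int(self._rng.integers(0, cum[-1]))
        i = int(np.searchsorted(cum, r, side="right"))
        offset = r - (cum[i - 1] if i else 0)
        return int(self._starts[category][i] + offset)


def simulate_library(
    config: GeneratorConfig,
    genome: SyntheticGenome,
    condition: str,
    seed: int,
) -> tuple[list[SmallRNARead], list[AlignmentRecord], TruthTable]:
    """Generate one small-RNA library for ``condition``.

    Returns collapsed reads (each with copy number 1 and a unique id),
    genome alignments for every piRNA read, and the truth table.  piRNA reads
    are drawn from genome loci per ``origin_fractions``; a
    ``pingpong_fraction`` share of them are secondary reads, each antisense
    to a distinct primary with an exact 10-nt 5'-5' overlap (the share is
    capped at 0.5 since every secondary needs its own primary).  Known-class
    reads are drawn from the packaged reference sequences; "other" reads are
    random sequences outside the piRNA length window.
    """
    config.validate()
    if condition not in config.class_fractions:
        raise ValueError(f"no class fractions for condition {condition!r}")
    rng = np.random.default_rng(seed)
    fracs = config.class_fractions[condition]
    probs = np.array([fracs.get(c, 0.0) for c in CLASS_ORDER])
    class_counts = dict(zip(CLASS_ORDER, rng.multinomial(config.n_reads, probs)))

    genome_arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    sampler = _LocusSampler(genome.category_blocks(), rng)
    forced: set[int] = set()

    n_pi = class_counts["piRNA"]
    n_sec = min(int(round(config.pingpong_fraction * n_pi)), n_pi // 2)
    n_pri = n_pi - n_sec

    lengths = np.array(sorted(config.pirna_length_dist), dtype=np.int64)
    lprobs = np.array([config.pirna_length_dist[int(l)] for l in lengths])
    L1 = rng.choice(lengths, size=n_pri, p=lprobs) if n_pri else np.empty(0, np.int64)
    L2 = rng.choice(lengths, size=n_sec, p=lprobs) if n_sec else np.empty(0, np.int64)
    plus = rng.random(n_pri) < 0.5
    origin_probs = np.array([config.origin_fractions.get(c, 0.0) for c in ORIGIN_ORDER])
    origins = rng.choice(np.arange(3), size=n_pri, p=origin_probs)
    bias1 = rng.random(n_pri) < config.q1U
    bias10 = rng.random(n_pri) < config.q10A
    alt1 = rng.integers(0, 3, size=n_pri)
    alt10 = rng.integers(0, 3, size=n_pri)

    # genome byte codes for the forced positions, by strand
    A, C, G, T = (ord(b) for b in "ACGT")
    plus_c1 = (T, (A, C, G))     # read base U when biased, else non-U
    plus_c10 = (A, (C, G, T))    # read base A when biased, else non-A
    minus_c1 = (A, (C, G, T))    # read base = complement(genome base)
    minus_c10 = (T, (A, C, G))

    # Loci are drawn unconditionally, so pair geometry never depends on
    # genome content and incidental opposite-strand 5'-overlap offsets stay
    # uniform (no artificial structure in the ping-pong null).  Bias bases
    # are then written into the genome first-write-wins, all position-1
    # writes before all position-10 writes: two reads sharing a position-1
    # coordinate draw from the same law, so realised 1U rates are exact,
    # and the only dilution is of 10A at the rare coordinates a position-1
    # write claimed first (proportional to reads per genome base).
    pri_coords: list[tuple[int, int, str, str]] = []
    sec_coords: list[tuple[int, int, str, str]] = []
    c1_writes: list[tuple[int, int]] = []
    c10_writes: list[tuple[int, int]] = []
    for i in range(n_pri):
        paired = i < n_sec
        l1 = int(L1[i])
        l2 = int(L2[i]) if paired else 0
        span = l1 + l2 - 10 if paired else l1
        category = ORIGIN_ORDER[origins[i]]
        p = sampler.draw(category, span)
        if plus[i]:
            s0 = p + (l2 - 10 if paired else 0)
        else:
            s0 = p
        e0 = s0 + l1
        c1, c10 = (s0, s0 + 9) if plus[i] else (e0 - 1, e0 - 10)
        spec1, spec10 = (plus_c1, plus_c10) if plus[i] else (minus_c1, minus_c10)
        c1_writes.append((c1, spec1[0] if bias1[i] else spec1[1][alt1[i]]))
        c10_writes.append((c10, spec10[0] if bias10[i] else spec10[1][alt10[i]]))
        strand = "+" if plus[i] else "-"
        pri_coords.append((s0, e0, strand, category))
        if paired:
            if plus[i]:
                sec_coords.append((s0 + 10 - l2, s0 + 10, "-", category))
            else:
                sec_coords.append((e0 - 10, e0 - 10 + l2, "+", category))

    for coord, value in c1_writes + c10_writes:
        if coord not in forced:
            forced.add(coord)
            genome_arr[coord] = value

    final_genome = genome_arr.tobytes().decode()
    realised_genome = SyntheticGenome(genome.name, final_genome, genome.annotation)

    reads: list[SmallRNARead] = []
    alignments: list[AlignmentRecord] = []
    truth_rows: list[tuple[str, str, str, str, str]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        rid = f"{condition}_{counter:06d}"
        counter += 1
        return rid

    def emit_genomic(start: int, end: int, strand: str, category: str, role: str) -> str:
        rid = next_id()
        seq = final_genome[start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(SmallRNARead(rid, seq, 1, condition))
        alignments.append(AlignmentRecord(rid, genome.name, start, end, strand, 1))
        truth_rows.append((rid, "piRNA", category, role, ""))
        return rid

    pri_ids = [emit_genomic(*pc, "primary") for pc in pri_coords]
    for j, sc in enumerate(sec_coords):
        sid = emit_genomic(*sc, "secondary")
        truth_rows[-1] = (sid, "piRNA", sc[3], "secondary", pri_ids[j])
        # symmetric partner link on the primary
        pr = truth_rows[j]
        truth_rows[j] = (pr[0], pr[1], pr[2], pr[3], sid)

    references = load_reference_classes()
    mir_by_len: dict[int, list[str]] = {}
    for s in references["miRNA"]:
        mir_by_len.setdefault(len(s), []).append(s)
    mir_lens = np.array(sorted(mir_by_len))
    mode = config.mirna_length_mode
    mir_target = np.array([mode - 2, mode - 1, mode, mode + 1])
    mir_probs = np.array([0.08, 0.27, 0.50, 0.15])

    for cls in ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "other"):
        n = class_counts[cls]
        if n == 0:
            continue
        if cls == "miRNA":
            want = rng.choice(mir_target, size=n, p=mir_probs)
            for k in range(n):
                avail = mir_lens[np.argmin(np.abs(mir_lens - want[k]))]
                pool = mir_by_len[int(avail)]
                seq = pool[int(rng.integers(0, len(pool)))]
                reads.append(SmallRNARead(next_id(), seq, 1, condition))
                truth_rows.append((reads[-1].id, cls, "n/a", "n/a", ""))
        elif cls == "other":
            lens = rng.choice(np.array(OTHER_LENGTHS), size=n)
            for k in range(n):
                raw = rng.integers(0, 4, size=int(lens[k]), dtype=np.uint8)
                seq = raw.choose(np.frombuffer(b"ACGT", dtype=np.uint8)).tobytes().decode()
                reads.append(SmallRNARead(next_id(), seq, 1, condition))
                truth_rows.append((reads[-1].id, cls, "n/a", "n/a", ""))
        else:
            pool = references[cls]
            ref_idx = rng.integers(0, len(pool), size=n)
            frag = rng.integers(FRAGMENT_LENGTHS[0], FRAGMENT_LENGTHS[1] + 1, size=n)
            for k in range(n):
                ref = pool[int(ref_idx[k])]
                fl = min(int(frag[k]), len(ref))
                start = int(rng.integers(0, len(ref) - fl + 1))
                reads.append(SmallRNARead(next_id(), ref[start : start + fl], 1, condition))
                truth_rows.append((reads[-1].id, cls, "n/a", "n/a", ""))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "true_class", "category", "role", "partner"],
    ).set_index("read_id")
    return reads, alignments, TruthTable(reads=truth, genome=realised_genome)


def simulate_count_matrix(config: GeneratorConfig, n_pirnas: int, seed: int):
    """Negative-binomial piRNA count matrix with planted condition effects.

    A ``de_fraction`` share of piRNAs get their mean multiplied by
    ``2**effect_log2fc`` in BSB (an "up" piRNA, with probability
    ``de_up_share``) or in NBS ("down").  Counts are NB(mean, dispersion)
    with Var = mu + dispersion * mu^2, independently per replicate.
    Returns (ExpressionMatrix of counts, TruthTable with expression labels).
    """
    from .expression import ExpressionMatrix  # local import to avoid cycle

    config.validate()
    rng = np.random.default_rng(seed)
    ids = [f"pi_{i:06d}" for i in range(n_pirnas)]
    is_de = rng.random(n_pirnas) < config.de_fraction
    is_up = rng.random(n_pirnas) < config.de_up_share
    status = np.where(is_de, np.where(is_up, "up", "down"), "ns")
    true_fc = np.where(
        is_de, np.where(is_up, config.effect_log2fc, -config.effect_log2fc), 0.0
    )

    mult = 2.0 ** config.effect_log2fc
    mu_bsb = np.where(status == "up", config.nb_mean * mult, config.nb_mean)
    mu_nbs = np.where(status == "down", config.nb_mean * mult, config.nb_mean)
    r = 1.0 / config.nb_dispersion
    reps = config.n_replicates

    def draw(mu: np.ndarray) -> np.ndarray:
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(n_pirnas, reps))

    bsb = draw(mu_bsb)
    nbs = draw(mu_nbs)
    samples = [f"BSB_{i + 1}" for i in range(reps)] + [f"NBS_{i + 1}" for i in range(reps)]
    values = pd.DataFrame(np.hstack([bsb, nbs]), index=ids, columns=samples)
    conditions = pd.Series(
        ["BSB"] * reps + ["NBS"] * reps, index=samples, name="condition"
    )
    truth = TruthTable(
        expression=pd.DataFrame(
            {"status": status, "true_log2fc": true_fc}, index=pd.Index(ids, name="pirna_id")
        )
    )
    return ExpressionMatrix(values, conditions, "count"), truth
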