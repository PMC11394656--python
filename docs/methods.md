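# Methods

This note documents the models and procedures implemented in `pirnascape`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Background and scope

PIWI-interacting RNAs (piRNAs) are 24–33 nt germline small RNAs that silence
transposons and regulate germ-cell mRNAs. Two biogenesis routes leave
sequence fingerprints: primary piRNAs carry a 5′ uridine (**1U**), and
ping-pong amplified secondary piRNAs carry an adenine at position 10
(**10A**) and lie antisense to their initiating partner with the two 5′ ends
overlapping by exactly 10 nt. The package implements the desk-scale portion
of a seasonal-breeder testis small-RNA analysis: candidate piRNA calling,
biogenesis-signature profiling, genomic-origin assignment, TPM-based
differential expression between breeding-season (BSB) and non-breeding-season
(NBS) libraries, and construction of a bipartite piRNA–mRNA regulatory
network. Upstream read QC/trimming and genome alignment are out of scope
(standard tools do them), as are GO/KEGG enrichment and any wet-lab steps.

## Candidate piRNA calling

A read is a candidate piRNA when its length lies in a window and its first
base is U **or** its tenth base is A. The default window is 27–32 nt
(`DEFAULT_PIRNA_WINDOW`); a wider 24–33 nt preset (`WIDE_PIRNA_WINDOW`) is
shipped for datasets reported with the broader range. U and T are treated as
equivalent everywhere. Known ncRNA classes are recognised first by exact
(sub)sequence match against reference sets, in the fixed priority order
rRNA → tRNA → snRNA → snoRNA → miRNA; the candidate rule applies only to
reads that match no reference. Exact-substring matching was chosen over
alignment for determinism and testability; the priority order reflects the
usual contamination-removal order of small-RNA annotation pipelines. All
tallies are copy-number weighted (collapsed-FASTA `>id_xN` convention);
length-histogram ties break to the smallest length.

## Biogenesis signatures

*Positional base matrix.* Count-weighted base fractions at 1-based positions
1..k; shorter reads contribute only to positions they cover. Per-position
enrichment of a base is its positional frequency divided by its
sequence-wide frequency; argmax ties break to the smallest position.

*Ping-pong profile.* Coordinates are BED-style (0-based, half-open); a
minus-strand read's 5′ end is `end − 1`. For a plus-strand 5′ end at `a` and
a minus-strand 5′ end at `b` on the same chromosome the 5′-overlap is
`b − a + 1`; overlaps 1..20 are tallied with weight `count₊ × count₋`,
regardless of read extents (pure offset counting, the standard practice).
The enrichment statistic is

```
z10 = (c10 − mean{c_o : o ≠ 10}) / sd{c_o : o ≠ 10}     (sample sd; z10 = 0 if sd = 0)
```

with z10 > 1.96 used as the working detection threshold. **Caveat:** z10 is
standardised against only 19 reference bins, so under a ping-pong-free null
it follows approximately √(1+1/19)·t₁₈, not N(0,1); the 1.96 cutoff is
therefore exceeded in ≈7% (not 5%) of null libraries. The test suite
measures exactly this (7/100 pre-registered null seeds). A binomial test on
bin 10 would be a lighter-tailed alternative but is not the default; the
z-score form is kept because it is the field's common convention. Pair
enumeration uses a per-chromosome hash sweep whose contract is exact
equality with the naive all-pairs oracle (tested).

## Genomic context

Mapped piRNAs are assigned to one of three origins — repeat, gene, other —
by a priority rule: the first category (default order repeat, then gene)
covering at least `min_overlap_fraction` (default 0.5) of the read's bases
wins; otherwise "other". Overlap is strand-agnostic (piRNAs silence
transposons from either strand), repeat precedes gene because of the
transposon-silencing emphasis of repeat-derived piRNAs, and "other" is the
annotation complement. Same-category intervals are merged before coverage
is computed, so summaries are invariant to interval order and splitting.
Each read is assumed to have one primary alignment.

## Differential expression

Expression is TPM in the small-RNA sense: reads per million mapped reads,
no length normalisation (a small RNA is sequenced end to end). Columns of a
TPM matrix sum to 10⁶. For each piRNA,

```
log2FC = log2((mean TPM in BSB + pseudo) / (mean TPM in NBS + pseudo)),   pseudo = 1 TPM
```

and the p-value comes from a Welch (unequal-variance) two-sample t-test on
log2(TPM + pseudo). A piRNA is "up" when log2FC > 1 and p < 0.05, "down"
when log2FC < −1 and p < 0.05 (raw p by default; Benjamini–Hochberg is
available behind a flag). Degenerate rows with zero variance in both groups
get p = 1 when the means are equal, else the p-value is floored at 1e-12.
The Welch-on-log choice is transparent and adequate for 3 vs 3 designs; a
shrinkage NB framework is deliberately out of scope.

**Known limitation (composition bias).** Per-million scaling forces columns
to a common total, so when differential expression is asymmetric (here
skewed toward BSB), the non-DE majority is shifted in the opposite
direction — with 20% DE at |log2FC| = 2 skewed 0.886 toward BSB, null
piRNAs' log2FC shifts by ≈ −0.5 and a tail of them crosses the down-call
thresholds. Sensitivity for true effects and the direction of called true
effects are unaffected (both tested); only the up:down ratio *among calls*
is compressed relative to the planted ratio. Median-of-ratios style
normalisation would remove this but would depart from the TPM convention
this pipeline follows.

## Target prediction and network

The duplex scorer is an explicit simplified stand-in for thermodynamic
target predictors (miRanda/RNAhybrid class): the piRNA binds antisense, its
reverse complement is slid along the mRNA, and each offset scores +1 per
Watson–Crick pair, +0.5 per G:U wobble, −1 per mismatch; the best site wins
(ties to the smallest site start). The "seed" is piRNA positions 2–11, and
targets are kept when score ≥ `min_score` (default 25 for 30-nt piRNAs) and
seed matches ≥ 9. There is no ΔG, gap or bulge model; externally produced
target tables can be supplied instead (`--edges`). Network edges connect DE
piRNAs to DE mRNAs only; duplicate edges collapse, so an mRNA's degree
counts distinct piRNA regulators. Exports: SIF (`piRNA regulates mRNA`),
GraphML with status/score attributes, and a lossless TSV round trip.

## The synthetic-data generator

The generator is first-class, tested code. It emulates the statistical
structure of the two-condition testis experiment and plants ground truth
for every downstream stage:

- **Class mixture** per condition (multinomial): piRNA 0.678 in BSB and
  0.237 in NBS (midpoints of the observed per-condition ranges), remainder
  split over miRNA/rRNA/tRNA/snRNA/snoRNA/other with miRNA dominant.
- **piRNA lengths** 27–32 nt with mode 30:
  {27: 0.05, 28: 0.10, 29: 0.20, 30: 0.35, 31: 0.20, 32: 0.10}; miRNA
  lengths peak at `mirna_length_mode` (22 nt).
- **Base biases** q1U = q10A = 0.85: strong but imperfect, so signatures are
  detectable yet non-degenerate. Both biases apply to primary reads — the
  position-10 preference is a population-level feature of these libraries —
  and propagate to paired secondaries by complementarity (a primary's first
  base *is* its partner's tenth on the other strand).
- **Ping-pong pairs**: `pingpong_fraction` (default 0.3) of piRNA reads are
  secondaries, each antisense to a distinct primary with an exact 10-nt
  5′–5′ overlap. Because every secondary needs its own primary the fraction
  is capped at 0.5; requesting more yields half/half (all paired).
- **Genomic origins** {repeat: 0.15, gene: 0.01, other: 0.84} on a uniform
  random genome with disjoint repeat/gene blocks whose base coverage matches
  the requested fractions exactly. Reads (and the full footprint of a
  ping-pong pair) are placed wholly inside a block of their category, so
  category truth is exactly recoverable by the 0.5-overlap rule.
- **Counts**: NB(mean 500, dispersion 0.05; Var = μ + φμ²), 3 replicates per
  condition; a `de_fraction` (0.2) of piRNAs get their mean multiplied by
  2^2 in BSB ("up", probability 0.886) or in NBS ("down").
- **Non-piRNA reads** are drawn from small packaged *synthetic* reference
  FASTAs (random sequences standing in for class databases); "other" reads
  are random sequences with lengths outside the piRNA window so class truth
  stays identifiable.

*Bias placement.* Read loci are drawn uniformly within category blocks,
**unconditioned** on genome content, and the 1U/10A bases are then written
into a copy of the genome (the *realised* genome, returned with the truth
table) — first all position-1 bases, then all position-10 bases, first
write wins. This design is deliberate: placement that conditions on
existing genome bases enriches incidental opposite-strand 10-nt overlaps
≈8-fold (1U-selected and 10A-selected positions coincide), while collision
*rejection* suppresses overlaps 1/10/19 geometrically; both would corrupt
the ping-pong null. With unconditioned placement the null overlap profile
is uniform. The cost is a small dilution of the realised 10A rate
(≈ primaries/genome-length, i.e. ≤0.8 percentage points on the default 5 Mb
genome at 200k reads) and rare unavoidable exceptions where two
opposite-strand reads share a 5′ base. Realised 1U rates are exact because
position-1 writes are applied first and same-position draws follow the same
law. A default genome of 5 Mb (15% repeat, 1% gene) keeps these effects
negligible at the default library size of 200,000 reads.

*Determinism.* Every output is a deterministic function of (config, seed);
identical inputs give byte-identical genomes, reads, alignments, truth
tables and count matrices.

*What is not emulated*: sequencing error, adapter contamination, quality
scores, multi-mapping, piRNA cluster structure, repeat-family substructure,
and any real sequence content (references are random). Passing recovery
tests therefore demonstrates that the analysis stages invert the generative
model they target, not that they are robust to artefacts real libraries
contain.

## Problem sizes used in the test and acceptance runs

Recovery runs use 200,000-read libraries on the 5 Mb genome for composition
and length profiles, 100,000 reads for genomic-origin recovery, 50,000
piRNA-only reads for the secondary-piRNA adenine signal, 100 × 10,000-read
piRNA-only libraries on a 200 kb genome for the ping-pong null battery, and
5,000-piRNA count matrices (3 vs 3) for differential-expression recovery —
sizes at which the targeted quantities' sampling error is an order of
magnitude smaller than the tolerances being checked.
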