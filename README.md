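# pirnascape

Profiling of testis small-RNA libraries with a focus on PIWI-interacting
RNAs (piRNAs): candidate calling, biogenesis signatures, genomic context,
differential expression between breeding-season (BSB) and non-breeding-season
(NBS) conditions, and piRNA–mRNA regulatory networks — plus a synthetic
two-condition data generator with full ground truth for validating every
stage.

piRNAs are 24–33 nt germline small RNAs that silence transposons and tune
germ-cell mRNAs. Their biogenesis leaves sequence fingerprints this package
measures:

- **1U / 10A candidate rule** — a read in the length window (default
  27–32 nt) with a 5′ uridine or an adenine at position 10 is a candidate
  piRNA.
- **Ping-pong signature** — opposite-strand piRNA pairs whose 5′ ends
  overlap by exactly 10 nt; quantified by
  `z10 = (c10 − mean{c_o : o≠10}) / sd{c_o : o≠10}` over 5′-overlap bins
  o = 1..20.
- **Genomic origin** — each mapped piRNA is assigned repeat / gene / other
  by a ≥50%-overlap priority rule.
- **Differential expression** — TPM (reads per million, no length
  normalisation), Welch t-test on log2(TPM+1), calls at |log2FC| > 1 and
  p < 0.05, positive log2FC meaning higher in BSB.
- **Targets and network** — a simplified antisense complementarity scorer
  (Watson–Crick +1, G:U wobble +0.5, mismatch −1, seed = piRNA positions
  2–11) links DE piRNAs to DE mRNAs in a bipartite network exportable as
  SIF / GraphML / TSV.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a dataset and run the pipeline from the shell (library functions
`pirnascape.simulate_library`, `classify_reads`, `ping_pong_profile`,
`de_test`, ... expose the same steps in Python):

```sh
$ pirnascape simulate --config demo_cfg.yaml --outdir demo --seed 1 \
      --genome-length 500000 --n-pirnas 2000
wrote synthetic dataset to demo

$ pirnascape profile --reads demo/BSB_reads.fa --out-prefix demo/bsb
5000 reads; piRNA 66.28%; 3419 candidates; modal length 30 nt

$ pirnascape signatures --aln demo/BSB_alignments.bed \
      --reads demo/bsb_candidates.fa --out-prefix demo/bsb
z10 = 319.83; A-enrichment argmax position = 10

$ pirnascape context --aln demo/BSB_alignments.bed \
      --anno demo/annotation.bed --out demo/bsb_context.tsv
{"repeat": 15.65, "gene": 0.95, "other": 83.40}

$ pirnascape de --counts demo/counts.tsv --design demo/design.tsv --out demo/de.tsv
441 DE piRNAs (341 up, 100 down in BSB)
```

Reading the output: the BSB library is piRNA-dominated (66.3% of reads,
against a generator setting of 67.8% before imperfect 1U/10A biases), the
candidate length distribution peaks at 30 nt, the ping-pong z-score is far
above the 1.96 working threshold because 30% of piRNAs were generated as
10-nt-overlap partners, adenine enrichment peaks at position 10 as expected
for ping-pong secondaries, the mapped piRNAs fall ~15% / ~1% / ~84% into
repeat / gene / other regions, and the DE calls skew toward upregulation in
the breeding season as planted (de_up_share = 0.886).

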