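"""Readers and writers for the plain-text formats the toolkit exchanges.

Reads travel as collapsed FASTA (``>id_xN`` encodes copy number N) or FASTQ;
alignments and annotation as BED6; matrices, truth tables and summaries as
TSV.  Sequence parsing goes through Biopython, tables through pandas.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import AnnotationInterval
from .expression import ExpressionMatrix
from .profile import LengthHistogram, ClassComposition, SmallRNARead
from .signatures import AlignmentRecord
from .synthetic import SyntheticGenome

_COUNT_SUFFIX = re.compile(r"_x(\d+)$")


def read_reads_fasta(path: str, sample: str | None = None) -> list[SmallRNARead]:
    """Read collapsed FASTA; ids without an ``_xN`` suffix get count 1."""
    reads = []
    for rec in SeqIO.parse(path, "fasta"):
        m = _COUNT_SUFFIX.search(rec.id)
        count = int(m.group(1)) if m else 1
        rid = _COUNT_SUFFIX.sub("", rec.id)
        reads.append(SmallRNARead(rid, str(rec.seq), count, sample))
    return reads


def write_reads_fasta(reads: Iterable[SmallRNARead], path: str) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}_x{r.count}", description="")
        for r in reads
    ]
    SeqIO.write(records, path, "fasta")


def read_reads_fastq(path: str, sample: str | None = None) -> list[SmallRNARead]:
    return [
        SmallRNARead(rec.id, str(rec.seq), 1, sample)
        for rec in SeqIO.parse(path, "fastq")
    ]


def write_reads_fastq(reads: Iterable[SmallRNARead], path: str) -> None:
    """FASTQ with uniform placeholder qualities (no error model)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=f"{r.id}_x{r.count}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def write_genome_fasta(genome: SyntheticGenome, path: str) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="synthetic genome")
    SeqIO.write([rec], path, "fasta")


def read_genome_fasta(path: str, annotation: list[AnnotationInterval] | None = None) -> SyntheticGenome:
    rec = next(SeqIO.parse(path, "fasta"))
    return SyntheticGenome(rec.id, str(rec.seq).upper(), annotation or [])


def write_alignments_bed(alignments: Iterable[AlignmentRecord], path: str) -> None:
    """BED6 with the read id in the name field and copy number as score."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t{a.count}\t{a.strand}\n")


def read_alignments_bed(path: str) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(AlignmentRecord(name, chrom, int(start), int(end), strand, int(score)))
    return out


def write_annotation_bed(annotation: Iterable[AnnotationInterval], path: str) -> None:
    """BED6 with the category in the name field."""
    with open(path, "w") as fh:
        for iv in annotation:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.category}\t0\t{iv.strand}\n")


def read_annotation_bed(path: str) -> list[AnnotationInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) > 5 else "."
            out.append(AnnotationInterval(chrom, int(start), int(end), name, strand))
    return out


def read_annotation_gff3(
    path: str, type_map: Mapping[str, str]
) -> list[AnnotationInterval]:
    """GFF3 annotation; feature types are mapped to categories via ``type_map``.

    Example: ``{"repeat_region": "repeat", "gene": "gene"}``.  Features whose
    type is not in the map are ignored.  GFF3 is 1-based inclusive; the
    intervals returned are 0-based half-open.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                continue
            chrom, _, ftype, start, end, _, strand = fields[:7]
            if ftype not in type_map:
                continue
            out.append(
                AnnotationInterval(chrom, int(start) - 1, int(end), type_map[ftype], strand)
            )
    return out


def read_counts_tsv(counts_path: str, design_path: str) -> ExpressionMatrix:
    """Count matrix (piRNAs x samples) plus a sidecar design table.

    The design TSV has columns ``sample`` and ``condition``.
    """
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    conditions = pd.Series(
        design["condition"].values, index=design["sample"].values, name="condition"
    )
    return ExpressionMatrix(values, conditions, "count")


def write_matrix_tsv(matrix: ExpressionMatrix, counts_path: str, design_path: str) -> None:
    matrix.values.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample": matrix.conditions.index, "condition": matrix.conditions.values}
    ).to_csv(design_path, sep="\t", index=False)


def write_length_histogram_tsv(hist: LengthHistogram, path: str) -> None:
    pd.DataFrame(
        sorted(hist.counts.items()), columns=["length_nt", "count"]
    ).to_csv(path, sep="\t", index=False)


def write_composition_tsv(comp: ClassComposition, path: str) -> None:
    pd.DataFrame(
        sorted(comp.percents.items()), columns=["class", "percent"]
    ).to_csv(path, sep="\t", index=False)


def read_mrna_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_status_table(path: str) -> dict[str, str]:
    """DE table TSV with columns ``id`` and ``status``; keeps up/down rows."""
    df = pd.read_csv(path, sep="\t")
    id_col = "id" if "id" in df.columns else df.columns[0]
    return {
        str(row[id_col]): row["status"]
        for _, row in df.iterrows()
        if row["status"] in ("up", "down")
    }
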