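"""Packaged synthetic reference sequences for the known ncRNA classes.

These are small, randomly generated stand-ins for the miRNA/rRNA/tRNA/
snRNA/snoRNA reference databases a real annotation pipeline would use; they
exist so that classification and the synthetic library generator share one
closed reference universe.  They are synthetic and carry no biological
sequence content.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from Bio import SeqIO

_FILES = {
    "miRNA": "mirna_synthetic.fa",
    "rRNA": "rrna_synthetic.fa",
    "tRNA": "trna_synthetic.fa",
    "snRNA": "snrna_synthetic.fa",
    "snoRNA": "snorna_synthetic.fa",
}


@lru_cache(maxsize=1)
def load_reference_classes() -> dict[str, tuple[str, ...]]:
    """Class name -> tuple of reference sequences (DNA, uppercase)."""
    out: dict[str, tuple[str, ...]] = {}
    base = resources.files("pirnascape").joinpath("data/references")
    for cls, fname in _FILES.items():
        with base.joinpath(fname).open() as fh:
            out[cls] = tuple(str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta"))
    return out
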