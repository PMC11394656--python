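"""Small shared helpers for nucleotide strings.

All modules normalise sequences to uppercase DNA (U -> T) before any
comparison, so RNA- and DNA-spelled inputs behave identically.
"""

from __future__ import annotations

DNA_BASES = "ACGT"

_NORMALIZE = str.maketrans("acgtuUnN", "ACGTTTNN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_dna(seq: str) -> str:
    """Uppercase and spell in DNA (U and u become T); N is preserved."""
    return seq.translate(_NORMALIZE)


def complement(seq: str) -> str:
    return normalize_dna(seq).translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def as_rna_base(base: str) -> str:
    """Map a single DNA base to the RNA alphabet used in reports (T -> U)."""
    b = normalize_dna(base)
    return "U" if b == "T" else b
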