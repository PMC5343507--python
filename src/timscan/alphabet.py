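"""Amino-acid and codon alphabets shared across the package.

A saturation-mutagenesis library covers all 64 codons at each position;
outcomes are tracked as 21 amino-acid classes: the 20 standard amino acids
(the WT amino acid itself is a class, reached through synonymous codons)
plus the stop class.
"""

from __future__ import annotations

import itertools

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

#: Canonical ordering of the 20 amino acids (alphabetical one-letter codes).
AA20: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Symbol used for the stop outcome class.
STOP = "*"

#: The 21 outcome classes of a saturation library: 20 amino acids + stop.
OUTCOME_CLASSES: tuple[str, ...] = AA20 + (STOP,)

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)

#: codon -> one-letter amino acid, with stops mapped to ``STOP``.
CODON_TO_AA: dict[str, str] = {
    codon: standard_dna_table.forward_table.get(codon, STOP) for codon in ALL_CODONS
}

#: amino acid (or STOP) -> tuple of codons encoding it.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in ALL_CODONS if CODON_TO_AA[c] == aa) for aa in OUTCOME_CLASSES
}


def translate_codon(codon: str) -> str:
    """Translate a single codon; stop codons return ``'*'``."""
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a DNA codon: {codon!r}")
    return CODON_TO_AA[codon]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
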