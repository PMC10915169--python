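"""Codon alphabet, indexing and translation tables.

Codons are indexed 0..63 in lexicographic order over the DNA alphabet
(AAA=0 ... TTT=63).  Sense codons are the 61 non-stop codons; amino acids
use one-letter codes.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"

#: All 64 codons in lexicographic order.
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

#: The 61 sense codons (lexicographic order preserved).
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

SENSE_INDICES: np.ndarray = np.array(
    [CODON_INDEX[c] for c in SENSE_CODONS], dtype=np.int64
)

#: codon -> one-letter amino acid ('*' for stops).
CODON_TO_AA: dict[str, str] = {c: str(Seq(c).translate()) for c in CODONS}

AMINO_ACIDS: tuple[str, ...] = tuple(
    sorted({aa for aa in CODON_TO_AA.values() if aa != "*"})
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codons_of(sequence: str) -> list[str]:
    """Split an in-frame CDS into codons (sequence length must be 3n)."""
    if len(sequence) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    return [sequence[i : i + 3] for i in range(0, len(sequence), 3)]


def encode(codon_list: list[str]) -> np.ndarray:
    """Map codon strings to integer indices (0..63)."""
    return np.array([CODON_INDEX[c] for c in codon_list], dtype=np.int16)


def decode(indices: np.ndarray) -> list[str]:
    """Inverse of :func:`encode`."""
    return [CODONS[int(i)] for i in indices]
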