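"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")

DNA_ALPHABET = set("ACGT")
RNA_ALPHABET = set("ACGU")


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


# Integer encoding used by the numba folding kernel: A=0, C=1, G=2, U/T=3.
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGU"):
    _ENC[ord(_b)] = _i
_ENC[ord("T")] = 3


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 (A=0, C=1, G=2, U/T=3).

    Raises ValueError on characters outside the nucleotide alphabet.
    """
    arr = _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({c for c in seq.upper() if c not in "ACGTU"})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return arr


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
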