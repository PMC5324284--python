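"""Short tandem target mimic (STTM) construct and primer design.

An STTM knocks down a miRNA with two identical bulged binding sites separated
by a spacer.  Each binding site is the DNA reverse complement of the mature
with a trinucleotide bulge (CTA by default) inserted between the bases
complementary to miRNA positions 10 and 11 (1-based from the mature 5' end),
so the mimic binds but is not cleaved.  The full insert is flanked by HindIII
(AAGCTT) and PstI (CTGCAG) recognition sequences for cloning, and the two
long primers are the exact complementary strands of the insert.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp_dna, rna_to_dna, RNA_ALPHABET
from .targets import detect_mimicry, scan_transcriptome

HINDIII = "AAGCTT"
PSTI = "CTGCAG"

#: 48-nt spacer adopted from standard STTM practice
DEFAULT_SPACER = "GTTGTTGTTGTTATGGTCTAATTTAAATATGGTCTAAAGAAGAAGAAT"

BULGE_AFTER_POSITION = 10  # bulge sits between bases pairing positions 10 and 11


def design_binding_site(mature: str, bulge: str = "CTA") -> str:
    """DNA binding site: reverse complement of the mature with the bulge
    inserted between the bases complementary to positions 10 and 11.

    With an empty bulge this degenerates to a plain reverse complement (a
    cleavable site, not a mimic).
    """
    m = mature.upper().replace("T", "U")
    if not (19 <= len(m) <= 25):
        raise ValueError(f"mature must be 19-25 nt, got {len(m)}")
    if any(c not in RNA_ALPHABET for c in m):
        bad = sorted({c for c in m if c not in RNA_ALPHABET})
        raise ValueError(f"mature contains non-RNA characters: {bad}")
    m_dna = rna_to_dna(m)
    s = BULGE_AFTER_POSITION
    # target read 5'->3': complement of the miRNA 3' half, bulge, 5' half
    return revcomp_dna(m_dna[s:]) + bulge.upper() + revcomp_dna(m_dna[:s])


@dataclass
class STTMConstruct:
    mirna_id: str
    binding_site: str
    spacer: str
    full_insert: str  # HindIII + site + spacer + site + PstI
    forward_primer: str
    reverse_primer: str
    notes: str = ""


def _find_all(seq: str, motif: str) -> list[int]:
    out, p = [], seq.find(motif)
    while p != -1:
        out.append(p)
        p = seq.find(motif, p + 1)
    return out


def _longest_stem(seq: str, min_loop: int = 3) -> int:
    """Length of the longest perfect Watson-Crick inverted repeat (stem) that
    could form a hairpin within the sequence."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    n, best = len(seq), 0
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            k = 0
            while i + k < j - k - min_loop and comp[seq[i + k]] == seq[j - k]:
                k += 1
            if k > best:
                best = k
    return best


def build_construct(
    mature: str,
    mirna_id: str = "mirna",
    spacer: str = DEFAULT_SPACER,
    bulge: str = "CTA",
    max_spacer_stem: int = 8,
) -> STTMConstruct:
    """Assemble the STTM insert and its complementary long primer pair.

    Validates that the spacer is 40-60 nt with weak self-structure (no perfect
    hairpin stem longer than ``max_spacer_stem`` base pairs; random 48-mers
    rarely exceed 8) and that the HindIII and PstI recognition sequences occur
    exactly once each in the final insert (a site or spacer containing either
    is a design conflict).
    """
    if not (40 <= len(spacer) <= 60):
        raise ValueError(f"spacer must be 40-60 nt, got {len(spacer)}")
    site = design_binding_site(mature, bulge)
    for name, motif in (("HindIII", HINDIII), ("PstI", PSTI)):
        for label, part in (("spacer", spacer), ("binding site", site)):
            hits = _find_all(part, motif)
            if hits:
                raise ValueError(
                    f"{name} recognition sequence inside the {label} at position {hits[0] + 1}"
                )
    stem = _longest_stem(spacer)
    if stem > max_spacer_stem:
        raise ValueError(
            f"spacer folds back on itself too strongly ({stem}-bp perfect stem)"
        )
    insert = HINDIII + site + spacer + site + PSTI
    for name, motif in (("HindIII", HINDIII), ("PstI", PSTI)):
        if len(_find_all(insert, motif)) != 1:
            raise ValueError(f"{name} recognition sequence occurs more than once in the insert")
    return STTMConstruct(
        mirna_id=mirna_id,
        binding_site=site,
        spacer=spacer,
        full_insert=insert,
        forward_primer=insert,
        reverse_primer=revcomp_dna(insert),
        notes=f"two identical bulged sites ({bulge} opposite positions 10-11), "
        f"{len(spacer)}-nt spacer",
    )


def digest(insert: str) -> list[str]:
    """Simulated HindIII/PstI double digestion of the insert (one strand).

    HindIII cuts A^AGCTT; PstI cuts CTGCA^G.  Returns the ordered fragments.
    """
    cut_points = []
    for p in _find_all(insert, HINDIII):
        cut_points.append(p + 1)
    for p in _find_all(insert, PSTI):
        cut_points.append(p + 5)
    pieces, prev = [], 0
    for c in sorted(cut_points):
        pieces.append(insert[prev:c])
        prev = c
    pieces.append(insert[prev:])
    return [p for p in pieces if p]


def verify_construct(construct: STTMConstruct, mature: str) -> dict:
    """Cross-check a design with the target-prediction module.

    The binding site must be classified as a mimic (bulge opposite positions
    9-11) and must NOT be reported as a cleavage site for the same miRNA.
    """
    seq = {"sttm": construct.full_insert}
    mimics = detect_mimicry({construct.mirna_id: mature}, seq)
    cleavage = [
        s
        for s in scan_transcriptome({construct.mirna_id: mature}, seq)
        if s.category == "cleavage"
    ]
    fragments = digest(construct.full_insert)
    return {
        "is_mimic": len(mimics) >= 2,  # both tandem sites detected
        "n_mimic_sites": len(mimics),
        "is_cleavage_site": len(cleavage) > 0,
        "n_fragments": len(fragments),
        "fragments": fragments,
        "primers_complementary": construct.reverse_primer
        == revcomp_dna(construct.forward_primer),
    }
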