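"""Plant miRNA target prediction, target mimicry and conserved lncRNAs.

Target sites are scored by a position-weighted complementarity expectation in
the psRNATarget default convention: per duplex position, mismatch 1.0, G:U
wobble 0.5, indel 2.0, all doubled within the seed (miRNA positions 2-13,
1-based from the 5' end); sites are reported up to expectation 3.0 and
classified translational when positions 9-11 carry a mismatch, cleavage
otherwise.  An endogenous target mimic (eTM) pairs the miRNA with a 2-5 nt
unpaired target bulge opposite miRNA positions 9-11 while the flanks pair
with expectation at or under the cutoff.  Conserved lncRNA candidates come
from a 4-step screen over syntenic ortholog pairs: intergenic alignment
(e <= 1e-6), expression evidence (>= 1 tag mapped), and a secondary-structure
z-score versus dinucleotide shuffles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import dna_to_rna
from .folding import nussinov, dinucleotide_shuffle

SEED_RANGE = (2, 13)  # miRNA positions, 1-based inclusive
CENTRAL_RANGE = (9, 11)
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
INDEL_PENALTY = 2.0
DEFAULT_CUTOFF = 3.0

_PAIR_OK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _position_weight(pos_1based: int) -> float:
    return 2.0 if SEED_RANGE[0] <= pos_1based <= SEED_RANGE[1] else 1.0


def _pair_penalty(mirna_base: str, target_base: str, pos_1based: int) -> float:
    pair = (mirna_base, target_base)
    if pair in _PAIR_OK:
        p = 0.0
    elif pair in _WOBBLE:
        p = WOBBLE_PENALTY
    else:
        p = MISMATCH_PENALTY
    return p * _position_weight(pos_1based)


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive on the transcript
    end: int
    expectation: float
    category: str  # "cleavage" | "translational"
    alignment: tuple[str, str, str]  # miRNA 5'->3', pairing symbols, target 3'->5'


def _duplex_positions(mature: str, window: str):
    """Yield (miRNA base, target base, miRNA position 1-based) for an ungapped
    antiparallel duplex; window length must equal mature length."""
    m = dna_to_rna(mature)
    t = dna_to_rna(window)[::-1]  # target read 3'->5' against miRNA 5'->3'
    for k, (mb, tb) in enumerate(zip(m, t), start=1):
        yield mb, tb, k


def score_window_ungapped(mature: str, window: str) -> float:
    if len(window) != len(mature):
        raise ValueError("ungapped scoring needs a window of mature length")
    return sum(_pair_penalty(mb, tb, k) for mb, tb, k in _duplex_positions(mature, window))


def score_target_site(mature: str, window: str, max_gaps: int = 1) -> tuple[float, tuple[str, str, str]]:
    """Expectation and alignment for a miRNA against one target window.

    A banded global alignment minimizes the summed per-position penalties;
    indels cost 2.0, doubled in the seed.  Penalties are keyed to the miRNA
    position so the seed weighting follows the miRNA, not the target.
    """
    m = dna_to_rna(mature)
    t = dna_to_rna(window)[::-1]
    if abs(len(t) - len(m)) > max_gaps:
        raise ValueError("window length outside mature length +/- max gaps")
    for s in (m, t):
        if any(c not in "ACGU" for c in s):
            raise ValueError(f"non-nucleotide characters in {s!r}")
    nm, nt = len(m), len(t)
    INF = float("inf")
    D = np.full((nm + 1, nt + 1), INF)
    D[0, 0] = 0.0
    for i in range(1, nm + 1):
        D[i, 0] = D[i - 1, 0] + INDEL_PENALTY * _position_weight(i)
    for j in range(1, nt + 1):
        D[0, j] = D[0, j - 1] + INDEL_PENALTY  # target insertion before miRNA pos 1
    for i in range(1, nm + 1):
        w = _position_weight(i)
        for j in range(1, nt + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + _pair_penalty(m[i - 1], t[j - 1], i),
                D[i - 1, j] + INDEL_PENALTY * w,
                D[i, j - 1] + INDEL_PENALTY * w,
            )
    # traceback for the reported alignment
    i, j = nm, nt
    a_m, a_sym, a_t = [], [], []
    while i > 0 or j > 0:
        w = _position_weight(i) if i > 0 else 1.0
        if i > 0 and j > 0 and math.isclose(
            D[i, j], D[i - 1, j - 1] + _pair_penalty(m[i - 1], t[j - 1], i)
        ):
            pair = (m[i - 1], t[j - 1])
            sym = "|" if pair in _PAIR_OK else ("o" if pair in _WOBBLE else " ")
            a_m.append(m[i - 1]); a_sym.append(sym); a_t.append(t[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and math.isclose(D[i, j], D[i - 1, j] + INDEL_PENALTY * w):
            a_m.append(m[i - 1]); a_sym.append(" "); a_t.append("-")
            i -= 1
        else:
            a_m.append("-"); a_sym.append(" "); a_t.append(t[j - 1])
            j -= 1
    aln = ("".join(reversed(a_m)), "".join(reversed(a_sym)), "".join(reversed(a_t)))
    return float(D[nm, nt]), aln


def _categorize(mature: str, window: str) -> str:
    """Translational when a central (9-11) position mismatches, else cleavage."""
    for mb, tb, k in _duplex_positions(mature, window):
        if CENTRAL_RANGE[0] <= k <= CENTRAL_RANGE[1]:
            if (mb, tb) not in _PAIR_OK and (mb, tb) not in _WOBBLE:
                return "translational"
    return "cleavage"


def scan_transcriptome(
    matures: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetSite]:
    """All sites with expectation <= cutoff; overlapping sites per
    miRNA-transcript pair collapse to the best-scoring (ties 5'-most).

    Scanning is ungapped (window length = mature length); the gap-capable
    scorer remains available through score_target_site.
    """
    sites: list[TargetSite] = []
    for mid in sorted(matures):
        mature = dna_to_rna(matures[mid])
        L = len(mature)
        weights = np.array([_position_weight(k) for k in range(1, L + 1)])
        m_arr = np.frombuffer(mature.encode(), dtype=np.uint8)
        for tid in sorted(transcripts):
            tx = dna_to_rna(transcripts[tid])
            n = len(tx)
            if n < L:
                continue
            # vectorized ungapped penalties over every window
            t_arr = np.frombuffer(tx.encode(), dtype=np.uint8)
            n_win = n - L + 1
            penalties = np.zeros(n_win)
            # miRNA position k pairs target base at window_start + (L-1) - (k-1)
            for k in range(1, L + 1):
                tb = t_arr[L - k : L - k + n_win]
                mb = m_arr[k - 1]
                pen = np.full(n_win, MISMATCH_PENALTY)
                comp = {65: 85, 85: 65, 71: 67, 67: 71}[mb]  # A<->U, G<->C
                pen[tb == comp] = 0.0
                if mb == 71:  # G:U
                    pen[tb == 85] = WOBBLE_PENALTY
                elif mb == 85:  # U:G
                    pen[tb == 71] = WOBBLE_PENALTY
                penalties += pen * weights[k - 1]
            hits = np.nonzero(penalties <= cutoff)[0]
            # collapse overlapping windows to the best-scoring, ties 5'-most
            chosen: list[tuple[int, float]] = []
            for p in hits:
                e = float(penalties[p])
                if chosen and p <= chosen[-1][0] + L - 1:
                    if e < chosen[-1][1]:
                        chosen[-1] = (int(p), e)
                else:
                    chosen.append((int(p), e))
            for p, e in chosen:
                window = tx[p : p + L]
                _expect, aln = score_target_site(mature, window, max_gaps=0)
                sites.append(
                    TargetSite(
                        mirna_id=mid,
                        transcript_id=tid,
                        start=p + 1,
                        end=p + L,
                        expectation=e,
                        category=_categorize(mature, window),
                        alignment=aln,
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# target mimicry


@dataclass
class MimicSite:
    mirna_id: str
    lncrna_id: str
    start: int  # 1-based inclusive on the lncRNA
    end: int
    bulge_length: int
    bulge_after_position: int  # miRNA position (1-based) 5' of the bulge
    flank_expectation: float


def detect_mimicry(
    matures: dict[str, str],
    lncrnas: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    bulge_lengths: tuple[int, int] = (2, 5),
    bulge_positions: tuple[int, int] = (9, 11),
) -> list[MimicSite]:
    """eTM sites: a 2-5 nt unpaired target bulge opposite miRNA positions
    9-11 with flanks pairing at expectation <= cutoff (bulge excluded).
    Perfect cleavable complements are not mimics (they carry no bulge).
    """
    out: list[MimicSite] = []
    for mid in sorted(matures):
        mature = dna_to_rna(matures[mid])
        L = len(mature)
        for lid in sorted(lncrnas):
            lnc = dna_to_rna(lncrnas[lid])
            found: list[MimicSite] = []
            for b in range(bulge_lengths[0], bulge_lengths[1] + 1):
                span = L + b
                for p in range(0, len(lnc) - span + 1):
                    window = lnc[p : p + span]
                    for s in range(bulge_positions[0], bulge_positions[1] + 1):
                        # along the target 5'->3': first the part pairing the
                        # miRNA 3' region (positions s+1..L), then the bulge,
                        # then the part pairing positions 1..s
                        left, right = window[: L - s], window[L - s + b :]
                        exp = sum(
                            _pair_penalty(mb, tb, k)
                            for k, (mb, tb) in enumerate(
                                zip(mature[s:], left[::-1]), start=s + 1
                            )
                        ) + sum(
                            _pair_penalty(mb, tb, k)
                            for k, (mb, tb) in enumerate(
                                zip(mature[:s], right[::-1]), start=1
                            )
                        )
                        if exp <= cutoff:
                            found.append(
                                MimicSite(mid, lid, p + 1, p + span, b, s, float(exp))
                            )
            # best site per overlap cluster, ties 5'-most then smaller bulge
            found.sort(key=lambda m: (m.flank_expectation, m.start, m.bulge_length))
            kept: list[MimicSite] = []
            for site in found:
                if all(
                    site.end < k.start or site.start > k.end for k in kept
                ):
                    kept.append(site)
            out.extend(sorted(kept, key=lambda m: m.start))
    return out


# ---------------------------------------------------------------------------
# conserved lncRNA screen


# blastn-style ungapped Karlin-Altschul parameters (match +1 / mismatch -2)
_DNA_LAMBDA = 1.33
_DNA_K = 0.621


def _dna_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


@dataclass
class ConservedLncRNACandidate:
    gene_a: str
    gene_b: str
    region_a: tuple[str, int, int]  # chrom, start, end of the intergenic flank
    region_b: tuple[str, int, int]
    e_value: float
    expressed: bool
    structure_z: float


def _intergenic_flank(
    genes: pd.DataFrame, genome: dict[str, str], gene_id: str, side: str = "down"
) -> tuple[str, int, int] | None:
    g = genes.set_index("gene_id").loc[gene_id]
    chrom_genes = genes[genes.chrom == g.chrom].sort_values("start")
    glen = len(genome[g.chrom])
    if side == "down":
        later = chrom_genes[chrom_genes.start > g.end]
        end = int(later.start.min()) - 1 if not later.empty else glen
        start = int(g.end) + 1
    else:
        earlier = chrom_genes[chrom_genes.end < g.start]
        start = int(earlier.end.max()) + 1 if not earlier.empty else 1
        end = int(g.start) - 1
    if end - start + 1 < 30:
        return None
    return (str(g.chrom), start, end)


def mfe_zscore(
    sequence: str, rng: np.random.Generator, n_shuffles: int = 100
) -> float:
    """z-score of the folding energy proxy (negative maximal pair count)
    against dinucleotide shuffles; structured sequences score below -1."""
    real = -nussinov(sequence).n_pairs
    null = np.array(
        [-nussinov(dinucleotide_shuffle(sequence, rng)).n_pairs for _ in range(n_shuffles)],
        dtype=float,
    )
    sd = null.std()
    if sd == 0:
        return 0.0
    return float((real - null.mean()) / sd)


def screen_conserved_lncrna(
    ortholog_pairs: list[tuple[str, str]],
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    tags: list[str],
    seed: int = 0,
    max_evalue: float = 1e-6,
    z_threshold: float = -1.0,
    n_shuffles: int = 100,
    max_region: int = 400,
) -> list[ConservedLncRNACandidate]:
    """4-step conserved-lncRNA screen over syntenic ortholog pairs:
    align downstream intergenic flanks (e <= max_evalue), require >= 1 tag
    mapped to the conserved region, and a structure z-score < z_threshold.
    """
    rng = np.random.default_rng(seed)
    aligner = _dna_local_aligner()
    out = []
    tagset = sorted(set(tags))
    for ga, gb in ortholog_pairs:
        fa = _intergenic_flank(genes_a, genome_a, ga)
        fb = _intergenic_flank(genes_b, genome_b, gb)
        if fa is None or fb is None:
            continue  # gene at chromosome end or no flank: skipped
        seq_a = genome_a[fa[0]][fa[1] - 1 : fa[2]][:max_region]
        seq_b = genome_b[fb[0]][fb[1] - 1 : fb[2]][:max_region]
        score = float(aligner.score(seq_a, seq_b))
        e = _DNA_K * len(seq_a) * len(seq_b) * math.exp(-_DNA_LAMBDA * score)
        if e > max_evalue:
            continue
        expressed = any(t in seq_a or t in seq_b for t in tagset)
        if not expressed:
            continue
        z = mfe_zscore(seq_a, rng, n_shuffles)
        if z < z_threshold:
            out.append(ConservedLncRNACandidate(ga, gb, fa, fb, e, expressed, z))
    return out


# ---------------------------------------------------------------------------
# curated gene-list intersection


def intersect_gene_lists(
    sites: list[TargetSite],
    curated: pd.DataFrame,
    transcript_to_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Inner join of target sites with a curated (gene_id, label, annotation)
    list, keeping site coordinates — the Table-1 shape."""
    rows = []
    for s in sites:
        gene = (
            transcript_to_gene.get(s.transcript_id, s.transcript_id)
            if transcript_to_gene
            else s.transcript_id
        )
        rows.append(
            {
                "mirna": s.mirna_id,
                "target_gene": gene,
                "target_locus": f"{s.transcript_id}:{s.start}:{s.end}:+",
                "expectation": s.expectation,
                "category": s.category,
            }
        )
    site_df = pd.DataFrame(
        rows, columns=["mirna", "target_gene", "target_locus", "expectation", "category"]
    )
    return site_df.merge(curated, left_on="target_gene", right_on="gene_id", how="inner").drop(
        columns=["gene_id"]
    )
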