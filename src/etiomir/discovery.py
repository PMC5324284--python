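"""Candidate novel miRNA discovery from genome-mapped tags.

The pipeline follows the miRDeep-style plant/monocot regime: map tags to the
genome, excise precursor windows around read stacks, fold each window with
the internal base-pair-maximization folder, demand a hairpin in which the
mature arm is at least 60% paired to the star arm, at least 90% of the read
signature is consistent with mature/star/loop placement, and any star reads
respect the Dicer duplex's 2-nt 3' overhang.  Surviving candidates are
screened for conservation against known matures (gapped global alignment,
identity over alignment columns, 90% cutoff), kept only when their total TPQ
over all 8 samples strictly exceeds 10, and named
``<species>_<chromosome two digits>_<order two digits>`` with discovery
order sorted by precursor start per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import revcomp_dna, dna_to_rna
from .folding import FoldResult, nussinov
from . import expression


@dataclass(frozen=True)
class Hit:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    mismatches: int


@dataclass
class GenomeMapping:
    hits: dict[str, list[Hit]] = field(default_factory=dict)
    dropped_multimappers: int = 0


def _exact_hits(genome_seq: str, query: str) -> list[int]:
    out, p = [], genome_seq.find(query)
    while p != -1:
        out.append(p)
        p = genome_seq.find(query, p + 1)
    return out


def _mismatch_hits(genome_arr: np.ndarray, query: str, max_mm: int) -> list[tuple[int, int]]:
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    L = len(q)
    if L > len(genome_arr):
        return []
    mism = np.zeros(len(genome_arr) - L + 1, dtype=np.int32)
    for k in range(L):
        mism += genome_arr[k : k + len(mism)] != q[k]
    pos = np.nonzero(mism <= max_mm)[0]
    return [(int(p), int(mism[p])) for p in pos]


def map_tags(
    tag_sequences: list[str],
    genome: dict[str, str],
    max_mismatch: int = 0,
    max_hits: int = 5,
) -> GenomeMapping:
    """Map tag sequences to both genome strands.

    Reports all loci with <= max_mismatch substitutions; tags exceeding
    max_hits loci are dropped and tallied.
    """
    mapping = GenomeMapping()
    arrays = (
        {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in genome.items()}
        if max_mismatch > 0
        else {}
    )
    for tag in tag_sequences:
        hits: list[Hit] = []
        for strand, query in (("+", tag), ("-", revcomp_dna(tag))):
            for chrom in sorted(genome):
                if max_mismatch == 0:
                    found = [(p, 0) for p in _exact_hits(genome[chrom], query)]
                else:
                    found = _mismatch_hits(arrays[chrom], query, max_mismatch)
                for p, mm in found:
                    hits.append(Hit(chrom, p + 1, p + len(tag), strand, mm))
        if not hits:
            continue
        if len(hits) > max_hits:
            mapping.dropped_multimappers += 1
            continue
        mapping.hits[tag] = hits
    return mapping


@dataclass
class PrecursorCandidate:
    chrom: str
    start: int  # 1-based inclusive, genomic
    end: int
    strand: str
    sequence: str  # RNA, 5'->3' on the candidate strand
    clipped: bool = False
    fold: FoldResult | None = None
    # signature: (tag, rel_start 0-based on candidate 5'->3', count vector)
    signature: list[tuple[str, int, np.ndarray]] = field(default_factory=list)
    mature_rel: tuple[int, int] | None = None  # [start, end) on candidate
    star_rel: tuple[int, int] | None = None
    score: "CandidateScore | None" = None

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"

    def mature_seq(self) -> str:
        s, e = self.mature_rel
        return self.sequence[s:e]

    def star_seq(self) -> str:
        s, e = self.star_rel
        return self.sequence[max(s, 0) : e]


@dataclass
class CandidateScore:
    structure_score: float  # mature-arm paired fraction
    signature_score: float  # consistent read fraction
    star_support: bool
    total: float
    passed: bool
    reasons: list[str]


def _merge_stacks(hits: list[Hit]) -> list[tuple[str, str, int, int]]:
    """Merge overlapping hits per (chrom, strand) into read stacks."""
    by_key: dict[tuple[str, str], list[Hit]] = {}
    for h in hits:
        by_key.setdefault((h.chrom, h.strand), []).append(h)
    stacks = []
    for (chrom, strand), hs in sorted(by_key.items()):
        hs = sorted(hs, key=lambda h: h.start)
        cur_s, cur_e = hs[0].start, hs[0].end
        for h in hs[1:]:
            if h.start <= cur_e + 1:
                cur_e = max(cur_e, h.end)
            else:
                stacks.append((chrom, strand, cur_s, cur_e))
                cur_s, cur_e = h.start, h.end
        stacks.append((chrom, strand, cur_s, cur_e))
    return stacks


def excise_candidates(
    mapping: GenomeMapping,
    genome: dict[str, str],
    window: tuple[int, int] = (20, 230),
    max_precursor: int = 300,
) -> list[PrecursorCandidate]:
    """Excise two precursor windows (window and its mirror) per read stack."""
    all_hits = [h for hs in mapping.hits.values() for h in hs]
    stacks = _merge_stacks(all_hits)
    seen: set[tuple[str, int, int, str]] = set()
    out = []
    up, down = window
    for chrom, strand, s, e in stacks:
        glen = len(genome[chrom])
        for left, right in ((up, down), (down, up)):
            if strand == "-":  # upstream/downstream are strand-relative
                left, right = right, left
            ws, we = s - left, e + right
            if we - ws + 1 > max_precursor:
                we = ws + max_precursor - 1
            clipped = ws < 1 or we > glen
            ws, we = max(ws, 1), min(we, glen)
            key = (chrom, ws, we, strand)
            if key in seen:
                continue
            seen.add(key)
            seq = genome[chrom][ws - 1 : we]
            if strand == "-":
                seq = revcomp_dna(seq)
            out.append(
                PrecursorCandidate(chrom, ws, we, strand, dna_to_rna(seq), clipped=clipped)
            )
    return out


def attach_signatures(
    candidates: list[PrecursorCandidate],
    mapping: GenomeMapping,
    tag_counts: pd.DataFrame,
):
    """Place mapped tags onto each candidate (strand-matched, contained)."""
    sample_cols = [c for c in tag_counts.columns if c != "length"]
    for cand in candidates:
        sig = []
        for tag, hits in mapping.hits.items():
            counts = tag_counts.loc[tag, sample_cols].to_numpy(dtype=float)
            for h in hits:
                if h.chrom != cand.chrom or h.strand != cand.strand:
                    continue
                if h.start < cand.start or h.end > cand.end:
                    continue
                if cand.strand == "+":
                    rel = h.start - cand.start
                else:
                    rel = cand.end - h.end
                sig.append((tag, rel, counts))
        cand.signature = sorted(sig, key=lambda t: (t[1], t[0]))


def _infer_star(fold: FoldResult, mature: tuple[int, int]) -> tuple[int, int] | None:
    """Star interval from the pairing of the mature arm (2-nt 3' overhangs)."""
    table = fold.pair_table()
    partners = [table[i] for i in range(*mature) if i in table]
    if not partners:
        return None
    lo, hi = min(partners), max(partners)
    if lo > mature[1] - 1:  # star arm downstream of mature
        return lo + 2, hi + 2 + 1
    return lo - 2, hi - 2 + 1


def score_candidate(
    cand: PrecursorCandidate,
    min_mature_paired: float = 0.60,
    min_signature_consistency: float = 0.90,
    max_precursor: int = 300,
    mature_slack: int = 2,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CandidateScore:
    """Fold-structure and read-signature scoring with pass/fail filters."""
    if not cand.signature:
        score = CandidateScore(0.0, 0.0, False, 0.0, False, ["no signature reads"])
        cand.score = score
        return score
    if cand.fold is None:
        cand.fold = nussinov(cand.sequence)
    reasons = []
    if len(cand.sequence) > max_precursor:
        reasons.append("precursor longer than cap")

    # mature = highest-count signature tag; ties by 5'-most placement
    def total_count(entry):
        return float(entry[2].sum())

    best = max(cand.signature, key=lambda e: (total_count(e), -e[1]))
    tag, rel, _counts = best
    mature = (rel, rel + len(tag))
    cand.mature_rel = mature

    table = cand.fold.pair_table()
    star = _infer_star(cand.fold, mature)
    cand.star_rel = star
    if star is None:
        score = CandidateScore(0.0, 0.0, False, 0.0, False, ["mature arm unpaired"])
        cand.score = score
        return score

    # mature-arm pairing: fraction of mature bases paired into the star region
    star_lo, star_hi = star[0] - 4, star[1] + 4
    paired = sum(
        1 for i in range(*mature) if i in table and star_lo <= table[i] < star_hi
    )
    structure_score = paired / (mature[1] - mature[0])
    if structure_score < min_mature_paired:
        reasons.append("mature arm under-paired")

    # signature consistency: reads must sit at mature, star, or inside loop
    loop_lo, loop_hi = (
        (mature[1], star[0]) if star[0] >= mature[1] else (star[1], mature[0])
    )
    consistent = 0.0
    total = 0.0
    star_support = False
    for tag_i, rel_i, counts_i in cand.signature:
        c = float(counts_i.sum())
        total += c
        s_i, e_i = rel_i, rel_i + len(tag_i)
        if abs(s_i - mature[0]) <= mature_slack:
            consistent += c
        elif abs(s_i - star[0]) <= mature_slack:
            consistent += c
            star_support = True
        elif loop_lo <= s_i and e_i <= loop_hi:
            consistent += c
    signature_score = consistent / total if total else 0.0
    if signature_score < min_signature_consistency:
        reasons.append("inconsistent read signature")

    w_struct, w_sig, w_star = weights
    total_score = w_struct * structure_score + w_sig * signature_score + (
        w_star if star_support else 0.0
    )
    score = CandidateScore(
        structure_score, signature_score, star_support, total_score, not reasons, reasons
    )
    cand.score = score
    return score


def resolve_overlaps(candidates: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Collapse candidates with overlapping genomic loci to the best-scoring
    one (ties: '+' strand, then 5'-most start)."""
    passing = [c for c in candidates if c.score and c.score.passed]
    passing.sort(key=lambda c: (c.chrom, c.start))
    kept: list[PrecursorCandidate] = []
    for cand in passing:
        merged = False
        for i, other in enumerate(kept):
            if other.chrom == cand.chrom and not (
                cand.end < other.start or cand.start > other.end
            ):
                better = max(
                    (other, cand),
                    key=lambda c: (c.score.total, c.strand == "+", -c.start),
                )
                kept[i] = better
                merged = True
                break
        if not merged:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# conservation screen


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity(a: str, b: str) -> float:
    """Identity of the best gapped global alignment: matches / columns."""
    aln = _aligner().align(a.upper().replace("T", "U"), b.upper().replace("T", "U"))[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


def check_conservation(
    candidate_matures: dict[str, str],
    known_matures: dict[str, str],
    cutoff: float = 0.90,
) -> pd.DataFrame:
    """All candidate-vs-known hits with identity >= cutoff."""
    if not candidate_matures or not known_matures:
        raise ValueError("both candidate and known mature sets must be nonempty")
    rows = []
    for cid in sorted(candidate_matures):
        for kid in sorted(known_matures):
            ident = alignment_identity(candidate_matures[cid], known_matures[kid])
            if ident >= cutoff:
                rows.append({"candidate": cid, "known": kid, "identity": ident})
    return pd.DataFrame(rows, columns=["candidate", "known", "identity"])


# ---------------------------------------------------------------------------
# expression filter and naming


@dataclass
class NovelMiRNA:
    name: str
    mature_seq: str  # RNA
    star_seq: str
    chrom: str
    start: int
    end: int
    strand: str
    score: CandidateScore
    tpq: np.ndarray  # length 8

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"


def filter_by_expression(
    candidates: list[PrecursorCandidate],
    tpq_rows: dict[str, np.ndarray],
    min_total_tpq: float = 10.0,
) -> list[PrecursorCandidate]:
    """Retain candidates whose total TPQ over all samples strictly exceeds
    the cutoff."""
    kept = []
    for cand in candidates:
        tpq = tpq_rows.get(cand.locus)
        if tpq is None:
            raise KeyError(f"no TPQ row for candidate {cand.locus}")
        if len(tpq) != 8:
            raise ValueError(f"TPQ vector for {cand.locus} must cover all 8 samples")
        if float(np.sum(tpq)) > min_total_tpq:
            kept.append(cand)
    return kept


def _chrom_number(chrom: str) -> int:
    digits = "".join(c for c in chrom if c.isdigit())
    if not digits:
        raise ValueError(f"cannot extract chromosome number from {chrom!r}")
    return int(digits)


def name_candidates(
    candidates: list[PrecursorCandidate],
    species_tag: str,
    tpq_rows: dict[str, np.ndarray] | None = None,
) -> list[NovelMiRNA]:
    """Assign `<sp>_<cc>_<oo>` names by start coordinate per chromosome."""
    loci = [(c.chrom, c.start, c.end, c.strand) for c in candidates]
    if len(set(loci)) != len(loci):
        raise ValueError("duplicate candidate loci; cannot assign unique names")
    named = []
    by_chrom: dict[str, list[PrecursorCandidate]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom, key=_chrom_number):
        for order, cand in enumerate(sorted(by_chrom[chrom], key=lambda c: c.start), 1):
            name = f"{species_tag}_{_chrom_number(chrom):02d}_{order:02d}"
            tpq = (
                tpq_rows[cand.locus]
                if tpq_rows is not None
                else np.zeros(8)
            )
            named.append(
                NovelMiRNA(
                    name,
                    cand.mature_seq(),
                    cand.star_seq(),
                    cand.chrom,
                    cand.start,
                    cand.end,
                    cand.strand,
                    cand.score,
                    np.asarray(tpq, dtype=float),
                )
            )
    return named


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class DiscoveryReport:
    n_stack_candidates: int
    n_prefilter: int  # folded+scored candidates (the "potential" set)
    n_pass_structure: int
    n_retained: int  # after the TPQ > 10 filter
    novel: list[NovelMiRNA] = field(default_factory=list)
    conservation_hits: pd.DataFrame | None = None


def discover(
    tags: pd.DataFrame,
    genome: dict[str, str],
    species_tag: str,
    known_matures: dict[str, str] | None = None,
    max_mismatch: int = 0,
    max_hits: int = 5,
    window: tuple[int, int] = (20, 230),
    min_total_tpq: float = 10.0,
    conservation_cutoff: float = 0.90,
) -> DiscoveryReport:
    """Run the full discovery pipeline on a collapsed tag table."""
    sample_cols = [c for c in tags.columns if c != "length"]
    mapping = map_tags(list(tags.index), genome, max_mismatch, max_hits)
    candidates = excise_candidates(mapping, genome, window)
    attach_signatures(candidates, mapping, tags)
    candidates = [c for c in candidates if c.signature]
    for cand in candidates:
        score_candidate(cand)
    kept = resolve_overlaps(candidates)

    # per-sample totals of clean genome-mapped reads (TPQ denominator)
    mapped = tags.loc[[t for t in tags.index if t in mapping.hits], sample_cols]
    totals = mapped.sum(axis=0)
    tpq_rows = {}
    for cand in kept:
        counts = np.zeros(len(sample_cols))
        for tag_i, rel_i, counts_i in cand.signature:
            if cand.mature_rel and abs(rel_i - cand.mature_rel[0]) <= 2:
                counts += counts_i
        tpq_rows[cand.locus] = (counts / totals.to_numpy(dtype=float)) * 250_000.0

    retained = filter_by_expression(kept, tpq_rows, min_total_tpq)
    novel = name_candidates(retained, species_tag, tpq_rows)
    report = DiscoveryReport(
        n_stack_candidates=len(candidates),
        n_prefilter=len(candidates),
        n_pass_structure=len(kept),
        n_retained=len(retained),
        novel=novel,
    )
    if known_matures and novel:
        report.conservation_hits = check_conservation(
            {n.name: n.mature_seq for n in novel}, known_matures, conservation_cutoff
        )
    return report


def novel_table(novel: list[NovelMiRNA]) -> pd.DataFrame:
    """Candidate table in the `chrom:start:end:strand` locus dialect."""
    from .synthio import SAMPLES

    rows = []
    for n in novel:
        row = {
            "name": n.name,
            "locus": n.locus,
            "mature": n.mature_seq,
            "star": n.star_seq,
            "score": n.score.total,
        }
        row.update({f"tpq_{s}": v for s, v in zip(SAMPLES, n.tpq)})
        rows.append(row)
    return pd.DataFrame(rows)
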