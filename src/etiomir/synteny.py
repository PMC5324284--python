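"""Ortholog pairing, collinear block chaining and miRNA synteny.

Orthologs are reciprocal best hits under a protein Smith-Waterman scorer with
a Karlin-Altschul-style e-value approximation (a precomputed 12-column hit
table can be imported instead).  Two regions are collinear when a chain of at
least five ortholog anchors runs in the same order on both genomes with no
more than ten genes inserted between consecutive anchors on either genome.
A pair of miRNA genes is syntenic when they share a family and each precursor
lies fully within the respective span of one paired block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# ungapped BLASTP-style Karlin-Altschul parameters for BLOSUM62
_KA_LAMBDA = 0.318
_KA_K = 0.13


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float
    e_value: float


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def translate_cds(cds: str) -> str:
    return str(Seq(cds).translate(to_stop=True))


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def find_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    max_evalue: float = 1e-10,
) -> list[OrthologPair]:
    """Reciprocal best hits between two proteomes under the internal scorer."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be nonempty")
    aligner = _protein_aligner()
    m_total = sum(len(s) for s in proteome_a.values())
    n_total = sum(len(s) for s in proteome_b.values())
    scores: dict[tuple[str, str], float] = {}
    for ga in sorted(proteome_a):
        for gb in sorted(proteome_b):
            scores[(ga, gb)] = float(aligner.score(proteome_a[ga], proteome_b[gb]))
    best_a = {
        ga: max(sorted(proteome_b), key=lambda gb: scores[(ga, gb)]) for ga in proteome_a
    }
    best_b = {
        gb: max(sorted(proteome_a), key=lambda ga: scores[(ga, gb)]) for gb in proteome_b
    }
    pairs = []
    for ga, gb in sorted(best_a.items()):
        if best_b[gb] != ga:
            continue
        s = scores[(ga, gb)]
        e = _evalue(s, m_total, n_total)
        if e <= max_evalue:
            pairs.append(OrthologPair(ga, gb, s, e))
    return pairs


def read_hit_table(path) -> list[OrthologPair]:
    """Import a 12-column tabular alignment hit table as ortholog pairs."""
    cols = [
        "query", "subject", "identity", "length", "mismatches", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    best = df.sort_values("bitscore", ascending=False).drop_duplicates("query")
    return [
        OrthologPair(r.query, r.subject, float(r.bitscore), float(r.evalue))
        for r in best.itertuples()
    ]


# ---------------------------------------------------------------------------
# collinearity


@dataclass
class CollinearBlock:
    block_id: str
    anchors: list[tuple[str, str]]  # ordered ortholog pairs
    chrom_a: str
    chrom_b: str
    span_a: tuple[int, int]  # genomic interval, 1-based inclusive
    span_b: tuple[int, int]
    max_gap: int

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _anchor_frame(
    orthologs: list[OrthologPair], genes_a: pd.DataFrame, genes_b: pd.DataFrame
) -> pd.DataFrame:
    ga = genes_a.set_index("gene_id")
    gb = genes_b.set_index("gene_id")
    rows = []
    for p in orthologs:
        if p.gene_a not in ga.index or p.gene_b not in gb.index:
            continue
        a, b = ga.loc[p.gene_a], gb.loc[p.gene_b]
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "chrom_a": a.chrom,
                "chrom_b": b.chrom,
                "order_a": int(a.order_index),
                "order_b": int(b.order_index),
                "start_a": int(a.start),
                "end_a": int(a.end),
                "start_b": int(b.start),
                "end_b": int(b.end),
            }
        )
    return pd.DataFrame(rows)


def enumerate_maximal_chains(
    anchors: pd.DataFrame, max_gap: int = 10
) -> list[list[int]]:
    """All maximal valid chains (as anchor row-index lists) on one chromosome
    pair: ascending in order on both genomes, <= max_gap intervening genes
    between consecutive anchors on each genome."""
    idx = list(anchors.index)
    oa = anchors["order_a"].to_dict()
    ob = anchors["order_b"].to_dict()

    def linkable(i, j) -> bool:
        return (
            oa[j] > oa[i]
            and ob[j] > ob[i]
            and oa[j] - oa[i] - 1 <= max_gap
            and ob[j] - ob[i] - 1 <= max_gap
        )

    succ = {i: [j for j in idx if linkable(i, j)] for i in idx}
    pred = {i: [j for j in idx if linkable(j, i)] for i in idx}
    chains: list[list[int]] = []

    def extend(chain: list[int]):
        nxt = succ[chain[-1]]
        if not nxt:
            chains.append(chain)
            return
        for j in nxt:
            extend(chain + [j])

    for i in idx:
        if not pred[i]:  # maximal chains start at anchors with no predecessor
            extend([i])
    return chains


def chain_collinear(
    orthologs: list[OrthologPair],
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    min_anchors: int = 5,
    max_gap: int = 10,
) -> list[CollinearBlock]:
    """Chain ortholog anchors into collinear blocks.

    Maximal same-order chains are enumerated per chromosome pair; chains with
    fewer than min_anchors anchors are dropped; each anchor is assigned to at
    most one block (best chain by anchor count, ties leftmost on genome A).
    """
    frame = _anchor_frame(orthologs, genes_a, genes_b)
    blocks: list[CollinearBlock] = []
    if frame.empty:
        return blocks
    for (chrom_a, chrom_b), sub in sorted(frame.groupby(["chrom_a", "chrom_b"])):
        chains = enumerate_maximal_chains(sub, max_gap)
        chains = [c for c in chains if len(c) >= min_anchors]
        chains.sort(key=lambda c: (-len(c), int(sub.loc[c[0], "order_a"])))
        used: set[int] = set()
        for chain in chains:
            if any(i in used for i in chain):
                continue
            used.update(chain)
            rows = sub.loc[chain]
            gaps = [
                max(
                    int(rows.iloc[k + 1].order_a - rows.iloc[k].order_a - 1),
                    int(rows.iloc[k + 1].order_b - rows.iloc[k].order_b - 1),
                )
                for k in range(len(rows) - 1)
            ]
            blocks.append(
                CollinearBlock(
                    block_id=f"cb_{len(blocks) + 1:03d}",
                    anchors=list(zip(rows.gene_a, rows.gene_b)),
                    chrom_a=chrom_a,
                    chrom_b=chrom_b,
                    span_a=(int(rows.start_a.min()), int(rows.end_a.max())),
                    span_b=(int(rows.start_b.min()), int(rows.end_b.max())),
                    max_gap=max(gaps) if gaps else 0,
                )
            )
    return blocks


def validate_block(
    block: CollinearBlock,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    min_anchors: int = 5,
    max_gap: int = 10,
) -> bool:
    """Independent post-hoc check of a block's invariants."""
    if block.n_anchors < min_anchors:
        return False
    ga = genes_a.set_index("gene_id")
    gb = genes_b.set_index("gene_id")
    oa = [int(ga.loc[a, "order_index"]) for a, _ in block.anchors]
    ob = [int(gb.loc[b, "order_index"]) for _, b in block.anchors]
    for xs in (oa, ob):
        for u, v in zip(xs, xs[1:]):
            if v <= u or v - u - 1 > max_gap:
                return False
    return True


# ---------------------------------------------------------------------------
# miRNA synteny and clusters


@dataclass(frozen=True)
class MiRNASyntenyCall:
    mirna_a: str
    mirna_b: str
    family: str
    block_id: str | None
    syntenic: bool


def assign_mirna_synteny(
    mirnas_a: pd.DataFrame,
    mirnas_b: pd.DataFrame,
    blocks: list[CollinearBlock],
) -> list[MiRNASyntenyCall]:
    """Call same-family miRNA pairs syntenic when both precursors lie fully
    within the paired spans of one collinear block.

    The miRNA frames need columns: mirna_id, family_id, chrom, start, end.
    """
    calls = []
    for _, ma in mirnas_a.iterrows():
        for _, mb in mirnas_b.iterrows():
            if ma.family_id != mb.family_id:
                continue
            hit = None
            for blk in blocks:
                if (
                    ma.chrom == blk.chrom_a
                    and mb.chrom == blk.chrom_b
                    and blk.span_a[0] <= ma.start
                    and ma.end <= blk.span_a[1]
                    and blk.span_b[0] <= mb.start
                    and mb.end <= blk.span_b[1]
                ):
                    hit = blk.block_id
                    break
            calls.append(
                MiRNASyntenyCall(ma.mirna_id, mb.mirna_id, ma.family_id, hit, hit is not None)
            )
    return calls


def syntenic_family_summary(calls: list[MiRNASyntenyCall]) -> dict[str, bool]:
    """Per family: does at least one member pair fall within a syntenic block."""
    out: dict[str, bool] = {}
    for c in calls:
        out[c.family] = out.get(c.family, False) or c.syntenic
    return out


def detect_clusters(
    mirnas: pd.DataFrame, max_distance: int = 10_000
) -> list[list[str]]:
    """Single-linkage clusters of same-family precursors on one chromosome
    within max_distance nt; only clusters of >= 2 members are reported."""
    clusters = []
    for (_fam, _chrom), sub in mirnas.groupby(["family_id", "chrom"]):
        sub = sub.sort_values("start")
        current = [sub.iloc[0]]
        for _, row in sub.iloc[1:].iterrows():
            if row.start - current[-1].end <= max_distance:
                current.append(row)
            else:
                if len(current) >= 2:
                    clusters.append([r.mirna_id for r in current])
                current = [row]
        if len(current) >= 2:
            clusters.append([r.mirna_id for r in current])
    return clusters


def write_circos_links(path, blocks: list[CollinearBlock]):
    """CIRCOS-style link file: one line per block with both spans."""
    with open(path, "w") as fh:
        for blk in blocks:
            fh.write(
                f"{blk.chrom_a}\t{blk.span_a[0]}\t{blk.span_a[1]}\t"
                f"{blk.chrom_b}\t{blk.span_b[0]}\t{blk.span_b[1]}\n"
            )


def blocks_table(blocks: list[CollinearBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a,
                "span_a": f"{b.span_a[0]}-{b.span_a[1]}",
                "chrom_b": b.chrom_b,
                "span_b": f"{b.span_b[0]}-{b.span_b[1]}",
                "n_anchors": b.n_anchors,
                "max_gap": b.max_gap,
            }
            for b in blocks
        ]
    )
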