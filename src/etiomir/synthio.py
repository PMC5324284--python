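"""Seeded synthetic two-species small-RNA datasets with ground truth.

Emulates the de-etiolation study design at desk scale: two toy monocot-like
genomes with orthologous gene blocks laid out in conserved order, planted
miRNA hairpins whose mature/star duplexes obey Dicer 2-nt 3' overhang
geometry, per-time-point expected abundances drawn from archetype expression
shapes (flat / induced / repressed / transient), and adapter-ligated
small-RNA reads for 8 samples per species (7 de-etiolation time points:
0, 0.5, 1, 3, 6, 12, 24 h, plus 1 control) with contaminant admixture from a
labelled rRNA/tRNA/snRNA set.  Every non-contaminant read traces to exactly
one planted feature, so downstream discovery, expression, synteny and target
modules can all be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp_dna, rna_to_dna, dna_to_rna
from .folding import nussinov, paired_fraction

SAMPLES = ["h0", "h0.5", "h1", "h3", "h6", "h12", "h24", "control"]
TIME_POINTS_H = [0.0, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0]

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# per-time-point shape archetypes (7 points + control), unit mean scale
ARCHETYPES = {
    "flat": np.array([1, 1, 1, 1, 1, 1, 1, 1.0]),
    "induced": np.array([0.1, 0.25, 0.6, 1.4, 2.4, 3.4, 4.0, 1.0]),
    "repressed": np.array([4.0, 3.0, 2.2, 1.4, 0.8, 0.4, 0.2, 1.0]),
    "transient": np.array([0.3, 1.5, 4.0, 3.0, 1.2, 0.5, 0.3, 1.0]),
}


@dataclass(frozen=True)
class GenomeSpec:
    """Layout request for one toy genome."""

    species_tag: str
    n_chromosomes: int
    chrom_lengths: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        if not self.species_tag or not self.species_tag.islower():
            raise ValueError("species_tag must be a nonempty lowercase label")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must list one length per chromosome")
        if any(l < 10_000 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be >= 10,000 nt")


@dataclass
class PlantedMiRNA:
    """One planted hairpin with its expression ground truth."""

    mirna_id: str
    family_id: str
    species: str
    mature_seq: str  # RNA, 20-24 nt
    star_seq: str  # RNA
    chrom: str
    start: int  # precursor locus, 1-based inclusive
    end: int
    strand: str
    precursor_seq: str  # DNA, forward-strand of the precursor
    mature_offset: int  # 0-based offset of mature within precursor
    abundance: np.ndarray  # expected reads per sample, length 8

    def mature_dna(self) -> str:
        return rna_to_dna(self.mature_seq)

    def star_dna(self) -> str:
        return rna_to_dna(self.star_seq)


@dataclass(frozen=True)
class ReadSimConfig:
    adapter: str = DEFAULT_ADAPTER
    depth: int = 10_000
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0
    length_window: tuple[int, int] = (18, 26)
    read_length: int = 40
    star_fraction: float = 0.1

    def __post_init__(self):
        if not (0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be within [0, 0.05]")
        if not (0 <= self.contaminant_fraction < 1):
            raise ValueError("contaminant_fraction must be within [0, 1)")
        if len(self.adapter) < 6:
            raise ValueError("adapter must be at least 6 nt")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring downstream stages."""

    genomes: dict[str, dict[str, str]] = field(default_factory=dict)
    species_order: tuple[str, str] | None = None  # (species A, species B)
    genes: dict[str, pd.DataFrame] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    intended_blocks: list[dict] = field(default_factory=list)
    mirnas: dict[str, list[PlantedMiRNA]] = field(default_factory=dict)
    contaminants: list[tuple[str, str, str]] = field(default_factory=list)
    known_matures: list[tuple[str, str]] = field(default_factory=list)
    transcripts: dict[str, str] = field(default_factory=dict)
    target_sites: list[dict] = field(default_factory=list)
    mimic_lncrnas: dict[str, str] = field(default_factory=dict)
    mimic_sites: list[dict] = field(default_factory=list)
    true_counts: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genomes and gene models


_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


def _random_cds(rng: np.random.Generator, n_codons: int = 100) -> str:
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def _mutate_cds(rng: np.random.Generator, cds: str, codon_rate: float = 0.10) -> str:
    """Ortholog copy: swap ~codon_rate of internal codons (no stops created)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for k in range(1, len(codons) - 1):
        if rng.random() < codon_rate:
            codons[k] = str(rng.choice(_CODONS))
    return "".join(codons)


def make_genomes(
    spec_a: GenomeSpec,
    spec_b: GenomeSpec,
    n_ortholog_blocks: int,
    genes_per_block: int,
    seed: int,
    max_insertions: int = 12,
    n_background_genes: int = 12,
) -> GroundTruth:
    """Build two genomes with planted collinear ortholog blocks.

    Each block contributes ``genes_per_block`` ortholog anchor pairs in the
    same order in both genomes; between consecutive anchors a randomized
    number (0..max_insertions) of non-orthologous genes is inserted
    independently per genome, so downstream chaining is exercised against the
    >=5 anchors / <=10 inserted genes rule.  Ortholog coding sequences share
    >=80% nucleotide identity.
    """
    if n_ortholog_blocks > 0 and genes_per_block < 5:
        raise ValueError("genes_per_block must be >= 5 so planted blocks are chainable")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(species_order=(spec_a.species_tag, spec_b.species_tag))

    # plan gene order per species as lists of (gene_id, cds) per chromosome
    plans = {
        spec_a.species_tag: [[] for _ in range(spec_a.n_chromosomes)],
        spec_b.species_tag: [[] for _ in range(spec_b.n_chromosomes)],
    }
    counters = {spec_a.species_tag: 0, spec_b.species_tag: 0}

    def new_gene(sp: str, cds: str) -> tuple[str, str]:
        counters[sp] += 1
        return f"{sp}_g{counters[sp]:04d}", cds

    def add_background(sp: str, chrom_idx: int, n: int):
        for _ in range(n):
            plans[sp][chrom_idx].append(new_gene(sp, _random_cds(rng)))

    for b in range(n_ortholog_blocks):
        ca = b % spec_a.n_chromosomes
        cb = b % spec_b.n_chromosomes
        add_background(spec_a.species_tag, ca, n_background_genes)
        add_background(spec_b.species_tag, cb, n_background_genes)
        anchors = []
        gaps_a, gaps_b = [], []
        for g in range(genes_per_block):
            if g > 0:
                na = int(rng.integers(0, max_insertions + 1))
                nb = int(rng.integers(0, max_insertions + 1))
                add_background(spec_a.species_tag, ca, na)
                add_background(spec_b.species_tag, cb, nb)
                gaps_a.append(na)
                gaps_b.append(nb)
            cds_a = _random_cds(rng)
            cds_b = _mutate_cds(rng, cds_a)
            ga = new_gene(spec_a.species_tag, cds_a)
            gb = new_gene(spec_b.species_tag, cds_b)
            plans[spec_a.species_tag][ca].append(ga)
            plans[spec_b.species_tag][cb].append(gb)
            anchors.append((ga[0], gb[0]))
            truth.ortholog_pairs.append((ga[0], gb[0]))
        max_gap = max(gaps_a + gaps_b) if gaps_a or gaps_b else 0
        truth.intended_blocks.append(
            {
                "block_id": f"block_{b + 1:02d}",
                "anchors": anchors,
                "gaps_a": gaps_a,
                "gaps_b": gaps_b,
                "max_gap": max_gap,
                "recoverable": max_gap <= 10,
            }
        )
    for sp, spec in ((spec_a.species_tag, spec_a), (spec_b.species_tag, spec_b)):
        for ci in range(spec.n_chromosomes):
            add_background(sp, ci, n_background_genes)

    # lay genes onto chromosomes and assemble sequences
    for spec in (spec_a, spec_b):
        sp = spec.species_tag
        genome: dict[str, str] = {}
        rows = []
        for ci in range(spec.n_chromosomes):
            chrom = f"chr{ci + 1}"
            length = spec.chrom_lengths[ci]
            seq = list(random_dna(rng, length))
            pos = int(rng.integers(500, 900))
            for order, (gid, cds) in enumerate(plans[sp][ci], start=1):
                end = pos + len(cds) - 1
                if end > length - 500:
                    raise ValueError(
                        f"{sp} {chrom} too short ({length} nt) for requested gene count"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                placed = cds if strand == "+" else revcomp_dna(cds)
                seq[pos - 1 : pos - 1 + len(cds)] = list(placed)
                rows.append(
                    {
                        "gene_id": gid,
                        "chrom": chrom,
                        "start": pos,
                        "end": end,
                        "strand": strand,
                        "order_index": order,
                        "cds": cds,
                    }
                )
                pos = end + 1 + int(rng.integers(400, 900))
            genome[chrom] = "".join(seq)
        truth.genomes[sp] = genome
        truth.genes[sp] = pd.DataFrame(rows)
    return truth


# ---------------------------------------------------------------------------
# miRNA planting


def _make_hairpin(rng: np.random.Generator, mature_rna: str) -> tuple[str, str, int]:
    """Precursor DNA around a mature: flank5+mature+loop+revcomp(mature)+flank3.

    Returns (precursor_dna, star_rna, mature_offset).  The star strand starts
    2 nt into the 3' arm so the mature/star duplex carries 2-nt 3' overhangs
    on both strands.
    """
    mature_dna = rna_to_dna(mature_rna)
    flank5 = random_dna(rng, 5)
    loop = random_dna(rng, int(rng.integers(8, 15)))
    flank3 = random_dna(rng, 5)
    arm3 = revcomp_dna(mature_dna)
    precursor = flank5 + mature_dna + loop + arm3 + flank3
    star_dna = arm3[2:] + flank3[:2]
    return precursor, dna_to_rna(star_dna), len(flank5)


def _random_mature(rng: np.random.Generator) -> str:
    length = int(rng.integers(20, 25))
    return "".join(rng.choice(list("ACGU"), size=length))


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    s = list(seq)
    pos = rng.choice(len(s), size=n_subs, replace=False)
    for p in pos:
        s[p] = str(rng.choice([b for b in "ACGU" if b != s[p]]))
    return "".join(s)


def default_family_plan(n_per_species: int) -> dict[str, int]:
    """Conserved families with 1-2 members per species summing to n."""
    plan: dict[str, int] = {}
    remaining, k = n_per_species, 1
    while remaining > 0:
        members = 2 if (remaining >= 2 and k % 3 == 0) else 1
        plan[f"fam{k:02d}"] = members
        remaining -= members
        k += 1
    return plan


def _block_spans(truth: GroundTruth) -> dict[str, list[tuple[str, int, int]]]:
    """Genomic span (chrom, start, end) of each recoverable intended block,
    per species, in block order."""
    sp_a, sp_b = truth.species_order
    spans: dict[str, list[tuple[str, int, int]]] = {sp_a: [], sp_b: []}
    for blk in truth.intended_blocks:
        if not blk["recoverable"]:
            continue
        for sp, col in ((sp_a, 0), (sp_b, 1)):
            genes = truth.genes[sp].set_index("gene_id")
            rows = genes.loc[[a[col] for a in blk["anchors"]]]
            spans[sp].append(
                (str(rows.chrom.iloc[0]), int(rows.start.min()), int(rows.end.max()))
            )
    return spans


def plant_mirnas(
    truth: GroundTruth,
    n_per_species: int,
    family_plan: dict[str, int] | None = None,
    seed: int = 0,
    base_abundance: tuple[float, float] = (40.0, 250.0),
    max_attempts: int = 200,
    within_blocks: bool = False,
) -> GroundTruth:
    """Plant hairpin precursors into intergenic space of both genomes.

    Conserved families share mature sequences >=90% identical across species
    (0-1 substitutions); members within a species share the mature exactly.
    Each planted precursor is verified to fold with >=60% of its mature arm
    paired (true by construction: the arms are exact inverted repeats).
    With within_blocks=True, families are placed into the intergenic gaps of
    paired recoverable ortholog blocks (same block pair in both species), so
    the family is syntenic by construction.
    """
    rng = np.random.default_rng(seed)
    if family_plan is None:
        family_plan = default_family_plan(n_per_species)
    species = sorted(truth.genomes)
    spans = _block_spans(truth) if within_blocks else None
    if within_blocks and not any(spans.values()):
        raise ValueError("within_blocks=True but no recoverable ortholog blocks planted")
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for sp in species:
        genes = truth.genes[sp]
        for _, g in genes.iterrows():
            occupied.setdefault((sp, g.chrom), []).append((int(g.start), int(g.end)))
        truth.mirnas.setdefault(sp, [])

    archetype_names = sorted(ARCHETYPES)
    counters = {sp: {} for sp in species}
    for fam_idx, (family_id, members) in enumerate(sorted(family_plan.items())):
        base_mature = _random_mature(rng)
        shape = ARCHETYPES[archetype_names[fam_idx % len(archetype_names)]]
        for sp in species:
            n_subs = int(rng.integers(0, 2))  # keep cross-species identity >=90%
            mature = base_mature if sp == species[0] else _substitute(rng, base_mature, n_subs)
            for _m in range(members):
                precursor, star, offset = _make_hairpin(rng, mature)
                placed = False
                for _try in range(max_attempts):
                    if within_blocks:
                        blk = spans[sp][fam_idx % len(spans[sp])]
                        chrom, lo, hi = blk
                        if hi - lo < len(precursor) + 100:
                            raise RuntimeError("block span too small for a precursor")
                        start = int(rng.integers(lo, hi - len(precursor)))
                    else:
                        chroms = sorted(truth.genomes[sp])
                        chrom = chroms[int(rng.integers(len(chroms)))]
                        glen = len(truth.genomes[sp][chrom])
                        start = int(rng.integers(300, glen - len(precursor) - 300))
                    end = start + len(precursor) - 1
                    ivs = occupied.setdefault((sp, chrom), [])
                    if any(not (end < s - 50 or start > e + 50) for s, e in ivs):
                        continue
                    seq = truth.genomes[sp][chrom]
                    truth.genomes[sp][chrom] = (
                        seq[: start - 1] + precursor + seq[start - 1 + len(precursor) :]
                    )
                    ivs.append((start, end))
                    placed = True
                    break
                if not placed:
                    raise RuntimeError(
                        f"could not place precursor for {family_id} in {sp} without overlap"
                    )
                fold = nussinov(precursor)
                frac = paired_fraction(fold, offset, offset + len(mature))
                if frac < 0.6:  # pragma: no cover - construction guarantees this
                    raise RuntimeError("planted hairpin fails the structural filter")
                counters[sp].setdefault(chrom, 0)
                counters[sp][chrom] += 1
                base = float(np.exp(rng.uniform(np.log(base_abundance[0]), np.log(base_abundance[1]))))
                mir = PlantedMiRNA(
                    mirna_id=f"{sp}-{family_id}-{counters[sp][chrom]}-{chrom}",
                    family_id=family_id,
                    species=sp,
                    mature_seq=mature,
                    star_seq=star,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+",
                    precursor_seq=precursor,
                    mature_offset=offset,
                    abundance=base * shape,
                )
                truth.mirnas[sp].append(mir)
    return truth


def make_contaminants(seed: int, n_per_class: int = 4) -> list[tuple[str, str, str]]:
    """Random sequences labelled rRNA/tRNA/snRNA for the contaminant screen."""
    rng = np.random.default_rng(seed)
    out = []
    for cls in ("rRNA", "tRNA", "snRNA"):
        for i in range(n_per_class):
            length = int(rng.integers(120, 301))
            out.append((cls, f"{cls}_{i + 1}", random_dna(rng, length)))
    return out


def make_known_matures(
    truth: GroundTruth, seed: int, fraction_known: float = 0.6, n_decoys: int = 10
) -> list[tuple[str, str]]:
    """miRBase-style known-mature catalogue: a subset of planted families
    (under miR-style names) plus unrelated decoy matures."""
    rng = np.random.default_rng(seed)
    known: list[tuple[str, str]] = []
    families = sorted({m.family_id for sp in truth.mirnas for m in truth.mirnas[sp]})
    n_known = int(round(fraction_known * len(families)))
    for i, fam in enumerate(families[:n_known]):
        sp = sorted(truth.mirnas)[0]
        mature = next(m.mature_seq for m in truth.mirnas[sp] if m.family_id == fam)
        known.append((f"osa-miR{9000 + i}", mature))
    for j in range(n_decoys):
        known.append((f"osa-miR{9500 + j}", _random_mature(rng)))
    truth.known_matures = known
    return known


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    s = list(seq)
    hits = np.nonzero(rng.random(len(s)) < rate)[0]
    for p in hits:
        s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
    return "".join(s)


def simulate_reads(
    truth: GroundTruth,
    cfg: ReadSimConfig,
    seed: int,
    species: str,
) -> dict[str, list[tuple[str, str, str]]]:
    """Simulate per-sample reads for one species.

    Returns {sample: [(read_id, sequence, quality), ...]}.  Mature (and a
    star_fraction of star) read counts are Poisson around the planted
    abundances; contaminant counts are Poisson(depth * contaminant_fraction);
    each read is insert + 3' adapter truncated to the read length, with
    uniform substitution errors on the insert.  Also fills
    truth.true_counts[species] with the realized mature counts per sample.
    """
    rng = np.random.default_rng(seed)
    mirnas = truth.mirnas.get(species, [])
    samples: dict[str, list[tuple[str, str, str]]] = {s: [] for s in SAMPLES}
    count_rows = []
    qual = "I" * cfg.read_length
    for si, sample in enumerate(SAMPLES):
        records = []
        realized = {}
        for mir in mirnas:
            n_mat = int(rng.poisson(mir.abundance[si]))
            n_star = int(rng.poisson(cfg.star_fraction * mir.abundance[si]))
            realized[mir.mirna_id] = n_mat
            for kind, n, insert in (
                ("mat", n_mat, mir.mature_dna()),
                ("star", n_star, mir.star_dna()),
            ):
                for r in range(n):
                    ins = _apply_errors(rng, insert, cfg.error_rate)
                    read = (ins + cfg.adapter)[: cfg.read_length]
                    records.append((f"{mir.mirna_id}|{kind}|{r}", read))
        n_cont = int(rng.poisson(cfg.depth * cfg.contaminant_fraction))
        if n_cont and not truth.contaminants:
            raise ValueError("contaminant_fraction > 0 but truth has no contaminant set")
        for r in range(n_cont):
            cls, cid, cseq = truth.contaminants[int(rng.integers(len(truth.contaminants)))]
            flen = int(rng.integers(cfg.length_window[0], cfg.length_window[1] + 1))
            p = int(rng.integers(0, len(cseq) - flen + 1))
            ins = _apply_errors(rng, cseq[p : p + flen], cfg.error_rate)
            read = (ins + cfg.adapter)[: cfg.read_length]
            records.append((f"cont|{cls}|{cid}|{r}", read))
        order = rng.permutation(len(records))
        samples[sample] = [
            (f"{species}_{sample}_{i}|{records[k][0]}", records[k][1], qual[: len(records[k][1])])
            for i, k in enumerate(order)
        ]
        row = {"sample": sample}
        row.update(realized)
        count_rows.append(row)
    truth.true_counts[species] = (
        pd.DataFrame(count_rows).set_index("sample").T.fillna(0).astype(int)
    )
    return samples


# ---------------------------------------------------------------------------
# planted targets / mimic lncRNAs (for target prediction and correlation tests)


def plant_targets(
    truth: GroundTruth,
    seed: int,
    species: str | None = None,
    n_targets: int | None = None,
    noise_sd: float = 0.3,
) -> GroundTruth:
    """Embed perfect-complement target sites in synthetic transcripts.

    Each chosen miRNA gets one transcript with a single reverse-complement
    site; the transcript's expression over the 7 time points is inversely
    proportional to the miRNA's (repressive regulation) with multiplicative
    log-normal noise.
    """
    rng = np.random.default_rng(seed)
    species_list = [species] if species else sorted(truth.mirnas)
    for sp in species_list:
        mirnas = truth.mirnas[sp]
        chosen = mirnas if n_targets is None else mirnas[:n_targets]
        for i, mir in enumerate(chosen):
            site = revcomp_dna(mir.mature_dna())
            left = random_dna(rng, int(rng.integers(80, 200)))
            right = random_dna(rng, int(rng.integers(80, 200)))
            tx_id = f"{sp}_tx{i + 1:03d}"
            truth.transcripts[tx_id] = left + site + right
            mir_prof = mir.abundance[:7]
            expr = 1000.0 / (mir_prof + 1.0)
            expr = expr * np.exp(rng.normal(0.0, noise_sd, size=7))
            truth.target_sites.append(
                {
                    "mirna_id": mir.mirna_id,
                    "mature": mir.mature_seq,
                    "transcript_id": tx_id,
                    "site_start": len(left) + 1,  # 1-based inclusive
                    "site_end": len(left) + len(site),
                    "target_expression": expr,
                }
            )
    return truth


def plant_mimic_lncrnas(
    truth: GroundTruth, seed: int, species: str | None = None, n_mimics: int = 2
) -> GroundTruth:
    """Embed eTM-style bulged sites (CTA opposite mature positions 10-11)."""
    rng = np.random.default_rng(seed)
    species_list = [species] if species else sorted(truth.mirnas)
    for sp in species_list:
        for i, mir in enumerate(truth.mirnas[sp][:n_mimics]):
            m = mir.mature_dna()
            site = revcomp_dna(m[10:]) + "CTA" + revcomp_dna(m[:10])
            left = random_dna(rng, int(rng.integers(60, 150)))
            right = random_dna(rng, int(rng.integers(60, 150)))
            lnc_id = f"{sp}_lnc{i + 1:02d}"
            truth.mimic_lncrnas[lnc_id] = left + site + right
            truth.mimic_sites.append(
                {
                    "mirna_id": mir.mirna_id,
                    "lncrna_id": lnc_id,
                    "site_start": len(left) + 1,
                    "site_end": len(left) + len(site),
                }
            )
    return truth


def plant_conserved_lncrnas(
    truth: GroundTruth, seed: int, n_lncrnas: int = 2, stem: int = 35, loop: int = 8
) -> list[dict]:
    """Plant a conserved structured (hairpin) lncRNA precursor into the
    downstream intergenic region of ortholog anchor pairs, in both genomes.

    Returns records with the planted region per species and an expressed
    fragment (a tag-sized substring) per region.
    """
    rng = np.random.default_rng(seed)
    if truth.species_order is None or not truth.ortholog_pairs:
        raise ValueError("needs two genomes with planted ortholog pairs")
    sp_a, sp_b = truth.species_order
    planted = []
    for k in range(n_lncrnas):
        ga, gb = truth.ortholog_pairs[k * 3 % len(truth.ortholog_pairs)]
        half = random_dna(rng, stem)
        core = half + random_dna(rng, loop) + revcomp_dna(half)
        rec = {"lnc_id": f"clnc{k + 1:02d}", "pairs": (ga, gb), "regions": {}}
        for sp, gid in ((sp_a, ga), (sp_b, gb)):
            genes = truth.genes[sp].set_index("gene_id")
            g = genes.loc[gid]
            start = int(g.end) + 60  # inside the downstream intergenic gap
            seq = core if sp == sp_a else _mutate_dna(rng, core, 0.03)
            chrom_seq = truth.genomes[sp][g.chrom]
            truth.genomes[sp][g.chrom] = (
                chrom_seq[: start - 1] + seq + chrom_seq[start - 1 + len(seq) :]
            )
            rec["regions"][sp] = {
                "chrom": str(g.chrom),
                "start": start,
                "end": start + len(seq) - 1,
                "fragment": seq[5:27],
            }
        planted.append(rec)
    return planted


def _mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    s = list(seq)
    for i in range(len(s)):
        if rng.random() < rate:
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    return "".join(s)


# ---------------------------------------------------------------------------
# writers


def write_fasta(path: str | Path, records: list[tuple[str, str]]):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(path: str | Path, records: list[tuple[str, str, str]]):
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_gff3(path: str | Path, genes: pd.DataFrame, source: str = "etiomir-synthio"):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_manifest(path: str | Path, truth: GroundTruth):
    """Ground-truth manifest (JSON): planted features and ortholog layout."""
    payload = {
        "species": sorted(truth.genomes),
        "ortholog_pairs": truth.ortholog_pairs,
        "intended_blocks": truth.intended_blocks,
        "mirnas": {
            sp: [
                {
                    "mirna_id": m.mirna_id,
                    "family_id": m.family_id,
                    "mature": m.mature_seq,
                    "star": m.star_seq,
                    "locus": f"{m.chrom}:{m.start}:{m.end}:{m.strand}",
                    "abundance": [float(x) for x in m.abundance],
                }
                for m in mirs
            ]
            for sp, mirs in truth.mirnas.items()
        },
        "target_sites": [
            {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in site.items()}
            for site in truth.target_sites
        ],
        "mimic_sites": truth.mimic_sites,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_dataset(out_dir: str | Path, truth: GroundTruth, reads: dict[str, dict]):
    """Write genomes, gene models, per-sample FASTQ, catalogues, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, genome in truth.genomes.items():
        write_fasta(out / f"{sp}_genome.fa", sorted(genome.items()))
        write_gff3(out / f"{sp}_genes.gff3", truth.genes[sp])
    for sp, samples in reads.items():
        for sample, records in samples.items():
            write_fastq(out / f"{sp}_{sample}.fastq", records)
    if truth.contaminants:
        write_fasta(
            out / "contaminants.fa",
            [(f"{cls}|{cid}", seq) for cls, cid, seq in truth.contaminants],
        )
    if truth.known_matures:
        write_fasta(out / "known_matures.fa", [(n, s) for n, s in truth.known_matures])
    write_manifest(out / "ground_truth.json", truth)
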