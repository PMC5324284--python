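# Methods

This document records the model behind each module, the parameter defaults
and why they were chosen, what the synthetic generator does and does not
capture, and the numerical conventions used throughout.

## Experimental design being modeled

Two grass species (tags `zm` and `os`) are profiled by small-RNA sequencing
at seven points after first illumination of etiolated seedlings — 0, 0.5, 1,
3, 6, 12 and 24 h (`synthio.TIME_POINTS_H`) — plus a light-grown `control`
library, giving the 8 samples in `synthio.SAMPLES`. Every analysis stage is
written against this design.

## Synthetic data generator (`synthio`)

**Genomes and gene models.** `make_genomes` lays random-codon CDSs (ATG +
non-stop codons + TAA, default 100 codons) on random-sequence chromosomes,
on random strands, with 400–900 nt intergenic gaps. Ortholog blocks
contribute anchor pairs in identical order in both genomes; ortholog CDSs
differ by ~10% random codon swaps, keeping nucleotide identity ≥ 80%.
Between consecutive anchors, 0–`max_insertions` (default 12) background genes
are inserted independently per genome, so by default some planted blocks
exceed the 10-inserted-gene chaining rule and are recorded as not
recoverable — the ground-truth manifest (`intended_blocks`) says which.
Blocks are separated by `n_background_genes` (default 12) background genes so
distinct blocks can never be chained together.

**miRNA hairpins.** A planted precursor is
`flank5(5) + mature + loop(8–14) + revcomp(mature) + flank3(5)`, with the
mature on the 5′ arm. The star strand starts 2 nt into the 3′ arm so the
mature/star duplex carries the biological 2-nt 3′ overhangs. Conserved
families share matures at ≥ 90% identity across species (0–1 substitutions).
Each family follows an abundance archetype (flat, induced, repressed,
transient) scaled by a log-uniform base of 40–250 expected reads.

**Reads.** A read is `insert + adapter` truncated to 40 nt, with the TruSeq
small-RNA 3′ adapter `TGGAATTCTCGGGTGCCAAGG`. Per-sample counts are Poisson
around the archetype abundance; 10% of a miRNA's reads come from the star
strand; sequencing errors are i.i.d. substitutions (default 0.5%);
contaminants (rRNA/tRNA/snRNA fragments of planted contaminant sources) make
up a configurable fraction of each library. Read names encode full
provenance, so tests can trace any read to its planted feature.

**Planted downstream features.** `plant_targets` writes transcripts with one
perfect reverse-complement site each and target expression inversely
proportional to the miRNA's time course with log-normal noise (repression).
`plant_mimic_lncrnas` writes eTM sites with a CTA bulge. 
`plant_conserved_lncrnas` inserts a 35-bp-stem hairpin lncRNA downstream of
an ortholog anchor pair in both genomes (3% divergence in the second), plus a
tag-sized expressed fragment.

**Realism and limits.** Genomes are i.i.d. random sequence: no repeats,
GC skew, transposons or gene families beyond the planted paralogs, so
mapping is easier than in a real grass genome (a real maize genome is ~85%
repetitive). Hairpins are perfect inverted repeats, so folding scores are
cleaner than real pre-miRNAs with internal loops. Expression noise is
Poisson + log-normal only — no batch effects or ligation bias. These
simplifications make planted-feature recovery a meaningful correctness check
but mean absolute performance numbers do not transfer to real data.

## Read cleaning (`preprocess`)

Reads are rejected when they contain an ambiguous base or have mean Phred
quality below 20. Adapter trimming takes the **leftmost** position where the
adapter matches with at most 1 mismatch per 10 aligned nucleotides and at
least 6 nt of overlap; inserts outside 18–26 nt are discarded (the plant
small-RNA size range with margin). Tags collapse into a per-sample count
table. The contaminant screen removes tags matching a contaminant sequence
full-length with ≤ 1 mismatch; it is implemented with exact and
single-position-masked substring dictionaries, so it is exhaustive without
alignment heuristics.

## Hairpin discovery (`discovery`)

Tags map to the genome by exact substring search on both strands (a
mismatch-tolerant numpy sliding-Hamming mode exists); tags with more than
`max_hits` (5) genomic hits are dropped as multimappers. Around each read
stack two windows are excised (20 nt upstream / 230 nt downstream and the
mirror, capped at 300 nt) so a mature on either hairpin arm is covered.
Candidates are folded with the internal Nussinov folder; they pass when
(a) ≥ 60% of the mature's bases pair into the star region of the hairpin,
(b) ≥ 90% of signature reads start within 2 nt of the mature 5′ end, with a
bonus for detected star reads; overlapping candidates resolve to the best
score per genomic region. Conservation screening aligns candidate matures
against known matures globally (match +1, mismatch −1, gap open −2, extend
−1) and calls a hit at identity ≥ 0.90 (matches / alignment columns).
Candidates failing conservation are retained as novel only when their total
TPQ across the 8 samples is **strictly greater than 10**. Novel names are
`<sp>_<chrom:02d>_<order:02d>` with order by start coordinate per chromosome.

## Expression (`expression`)

TPQ = count / (sample's clean genome-mapped reads) × 250,000, so every TPQ
column sums to exactly 250,000. Fold-change is
`ln(tpq_t / tpq_control)` after substituting 0.001 for values that are
exactly zero (only then — small nonzero values are used as-is). Family
profiles are member-wise TPQ sums. Time-course shapes are ordinary
least-squares cubic fits on raw hours (Vandermonde + `lstsq`; the
normal-equation solution agrees to ~1e-13 on these 7-point designs, and
x-rescaling is unnecessary because 24³ is small). Pearson correlation uses
`scipy.stats.pearsonr`, with constant inputs flagged as undefined rather
than raising.

## Folding (`folding`)

The folder is a Nussinov maximum base-pairing dynamic program (Watson-Crick
plus G:U, minimum loop 3, numba-compiled table, deterministic traceback) —
exact for its objective, verified against exhaustive structure enumeration
for sequences up to 20 nt. Maximum pairing is a crude proxy for free energy;
it is used only for relative judgments (paired fraction of the mature arm,
z-scores against dinucleotide shuffles) where the proxy's bias largely
cancels, never for absolute ΔG claims. `dinucleotide_shuffle` preserves the
exact dinucleotide multiset (Altschul–Erikson style).

## Synteny (`synteny`)

Orthologs are reciprocal best hits between translated CDSs under a local
BLOSUM62 aligner (gap open −11 / extend −1) with a Karlin–Altschul e-value
(λ = 0.318, K = 0.13, ungapped BLASTP-style constants), threshold 1e-10; a
precomputed 12-column hit table can be imported instead. Collinear chaining
enumerates **all maximal chains** per chromosome pair — ascending order on
both genomes, ≤ 10 genes inserted between consecutive anchors on either
genome — keeps chains with ≥ 5 anchors, and assigns each anchor to one block
(most anchors, ties leftmost). Exhaustive enumeration is feasible because
anchors per chromosome pair are few; it is verified against an independent
permutation-based oracle. miRNA pairs are syntenic when they share a family
and both precursors lie fully within one block's paired spans. Clusters are
single-linkage groups of same-family precursors ≤ 10 kb apart.

## Targets, mimics, conserved lncRNAs (`targets`)

Scoring follows the psRNATarget expectation convention: per duplex position,
mismatch 1.0, G:U wobble 0.5, indel 2.0, all doubled at miRNA positions 2–13;
sites are reported at expectation ≤ 3.0 and classified translational when a
central position (9–11) mismatches, cleavage otherwise. The transcriptome
scan is ungapped (vectorized over all windows; overlapping hits collapse to
the best, ties 5′-most); a gap-capable position-weighted
Needleman–Wunsch (`score_target_site`) exists for single-window scoring.
eTM detection requires a 2–5-nt target bulge opposite miRNA positions 9–11
with the flanks pairing at expectation ≤ 3.0 (bulge excluded); perfect
complements are cleavage sites, never mimics. The conserved-lncRNA screen
walks syntenic ortholog pairs: align downstream intergenic flanks (local DNA
aligner +1/−2, gaps −5/−2; e-value with λ = 1.33, K = 0.621; e ≤ 1e-6),
require ≥ 1 small-RNA tag contained in the region, and require a structure
z-score < −1 versus 100 dinucleotide shuffles (the z-score uses negative
Nussinov pair count as the energy proxy).

## STTM design (`sttm`)

The binding site is the DNA reverse complement of the mature with a
trinucleotide bulge (CTA) inserted between the bases complementary to miRNA
positions 10 and 11 — the bulge prevents AGO-mediated cleavage while
preserving binding. The insert is
`HindIII + site + 48-nt spacer + site + PstI`; the two long primers are the
exact complementary strands. Validation rejects spacers outside 40–60 nt,
spacers or sites containing a restriction motif (the motifs must occur
exactly once each in the insert), and spacers with a perfect hairpin stem
longer than 8 bp. The stem criterion replaced a Nussinov paired-fraction
threshold: under maximum pairing, random 48-mers pair ~68% of their bases,
so a fractional cutoff cannot separate designed spacers from hairpins, while
the longest perfect stem does (canonical spacer 4 bp, random 48-mers ≤ 8 bp,
deliberate hairpins 20+ bp). Digestion simulation cuts A^AGCTT and CTGCA^G
on the given strand, and `verify_construct` round-trips the design through
the target-prediction module: the insert must contain exactly two mimic
sites and no cleavage site for the same miRNA.

## Problem sizes and verification

Default verification sizes are the package's own choice, set so the full
test suite runs in well under a minute of compute after numba warmup:
2 × 2 × 300 kb genomes with 24 planted miRNAs for end-to-end discovery
(precision and recall both reach 1.0 at depth 3000), 100 random toys for
chaining, 75 sequences ≤ 20 nt for folding, 50 random transcripts for target
scanning, and 50 seeded trials for the repression-correlation rate. All
randomness flows through `numpy.random.default_rng` with explicit seeds, so
every number in the README and `results/acceptance.json` is reproducible.

## Limitations

- Exact-match mapping and modest genome sizes sidestep the multimapping
  ambiguity that dominates real maize small-RNA analysis.
- Maximum base pairing is not a thermodynamic model; real hairpin calls
  should use a free-energy folder.
- The Karlin–Altschul e-values use fixed ungapped parameters, not fitted
  gapped statistics; they are calibrated for ranking, not for absolute
  significance.
- The generator's repression model (target expression inversely proportional
  to miRNA abundance) is deliberately simple; it tests the correlation
  machinery, not regulatory biology.
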