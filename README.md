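# etiomir

Small-RNA analysis of de-etiolation time courses in a two-species (maize-like /
rice-like) setting: seeded synthetic data generation, read cleaning, miRNA
hairpin discovery, family expression dynamics, genome synteny, target and
target-mimicry prediction, and STTM knockdown construct design.

## The scientific problem

When an etiolated (dark-grown) seedling first sees light it rebuilds its
photosynthetic machinery within hours, and microRNAs help rewire that
transition. A typical study profiles small-RNA libraries at several time
points after illumination (here 0, 0.5, 1, 3, 6, 12 and 24 h) plus a
light-grown control, then asks:

1. Which reads are genuine miRNAs? Candidate precursors must map to the
   genome, fold into a hairpin with the mature sequence mostly paired to its
   star strand, show a clean read signature, and either match a known mature
   at ≥ 90% identity (conserved) or survive as novel calls above an
   expression floor (total TPQ > 10). Novel miRNAs are named
   `<species>_<chromosome>_<order>`, e.g. `os_03_07`.
2. How do miRNA *families* respond to light? Counts are normalized to TPQ
   (transcripts per quarter million: each library scaled so clean
   genome-mapped reads sum to 250,000), family members are summed, and
   ln fold-changes versus the control (substituting 0.001 for zeros) are
   summarized with cubic polynomial fits over raw hours.
3. Are miRNA genes syntenic between the two grasses? Reciprocal-best-hit
   orthologs (e ≤ 1e-10) are chained into collinear blocks (≥ 5 anchors in
   the same order, ≤ 10 inserted genes), and same-family precursor pairs
   contained in paired block spans are called syntenic; nearby same-family
   precursors (≤ 10 kb) form clusters.
4. What do the miRNAs regulate? Target sites are scored by position-weighted
   complementarity (mismatch 1.0, G:U wobble 0.5, indel 2.0, doubled at
   miRNA positions 2–13, cutoff 3.0); endogenous target mimics carry a
   2–5-nt bulge opposite positions 9–11; conserved structured lncRNAs pass a
   4-step screen (syntenic intergenic alignment e ≤ 1e-6, ≥ 1 mapped tag,
   folding z-score < −1 versus dinucleotide shuffles).
5. How would you knock a miRNA down? A short tandem target mimic (STTM):
   two bulged binding sites around a 48-nt spacer, flanked by HindIII and
   PstI sites, delivered as two complementary long primers.

Because real genomes and libraries are too big for a test suite, the package
ships a generator (`etiomir.synthio`) that plants every one of these features
into small genomes with a complete ground-truth manifest, so every pipeline
stage can be scored against what was actually planted.

## Worked example

Discover planted miRNAs end to end (this is `examples/03_discover_mirnas.py`,
trimmed; all examples are deterministic):

```python
from etiomir import discovery, preprocess, synthio

spec_zm = synthio.GenomeSpec("zm", 2, (150_000, 150_000), seed=1)
spec_os = synthio.GenomeSpec("os", 2, (150_000, 150_000), seed=2)
truth = synthio.make_genomes(spec_zm, spec_os, 2, 5, seed=3, max_insertions=8)
truth = synthio.plant_mirnas(truth, 8, seed=4, within_blocks=True)

cfg = synthio.ReadSimConfig(depth=2000, error_rate=0.005, contaminant_fraction=0.0)
reads = synthio.simulate_reads(truth, cfg, seed=7, species="zm")
per_sample = {
    s: preprocess.trim_sample(
        preprocess.quality_filter([(n, sq, [40] * len(sq)) for n, sq, _ in recs])[0],
        cfg.adapter,
    )[0]
    for s, recs in reads.items()
}
tags = preprocess.collapse_tags(per_sample)
report = discovery.discover(tags, truth.genomes["zm"], "zm")
print(discovery.novel_table(report.novel).head(3))
```

Actual output (columns trimmed for width):

```
candidate stacks: 54, folded/scored: 54, pass structure+signature: 8, retained (TPQ>10): 8
    name              locus                   mature                    tpq_h0   tpq_h24  tpq_control
zm_01_01 chr1:12981:13252:-   GGGGGGAACAUAGCUCAAUGUC             179392.446634   5458.52     52605.70
zm_01_02 chr1:13293:13564:-   GGGGGGAACAUAGCUCAAUGUC             179392.446634   5458.52     52605.70
zm_01_03 chr1:22972:23244:+  UUGUAUACGCCGUGAGUAGCUAC              15394.088670   6004.37     16961.65
recovered 8/8 planted miRNA loci
```

And an STTM design (`examples/07_sttm_design.py`):

```
mature miR1432 (21 nt): CUCAGGAGAGAUGACACCGAC
binding site   (24 nt): GTCGGTGTCATCTACTCTCCTGAG
full insert (108 nt):
  AAGCTTGTCGGTGTCATCTACTCTCCTGAGGTTGTT...CTCCTGAGCTGCAG
verification: mimic=True (sites=2), cleavage site=False
HindIII/PstI digestion -> 3 fragments (1 nt + 106 nt + 1 nt)
```

The `examples/` directory walks through each capability:

| script | capability |
| --- | --- |
| `01_simulate_dataset.py` | seeded two-species dataset with ground truth |
| `02_preprocess_reads.py` | quality filter, adapter trimming, tag collapsing, contaminants |
| `03_discover_mirnas.py` | hairpin discovery with all filters |
| `04_family_dynamics.py` | TPQ, fold-changes, cubic fits, correlation |
| `05_synteny.py` | orthologs, collinear blocks, miRNA synteny, clusters |
| `06_targets_and_mimics.py` | target scan, eTM detection, conserved lncRNAs |
| `07_sttm_design.py` | STTM construct and primers |

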