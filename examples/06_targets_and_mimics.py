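"""Predict miRNA targets, endogenous target mimics and conserved lncRNAs.

Position-weighted complementarity scoring (mismatch 1.0 / wobble 0.5 / indel
2.0, doubled at miRNA positions 2-13, cutoff 3.0), eTM detection with a
2-5-nt bulge opposite positions 9-11, the 4-step conserved-lncRNA screen, and
the curated gene-list intersection.
"""

import copy

import pandas as pd

from etiomir import synthio, targets

spec_zm = synthio.GenomeSpec("zm", 2, (150_000, 150_000), seed=1)
spec_os = synthio.GenomeSpec("os", 2, (150_000, 150_000), seed=2)
truth = synthio.make_genomes(spec_zm, spec_os, 2, 5, seed=3, max_insertions=8)
truth = synthio.plant_mirnas(truth, 8, seed=4, within_blocks=True)
truth = synthio.plant_targets(truth, seed=9, species="zm", n_targets=3)
truth = synthio.plant_mimic_lncrnas(truth, seed=10, species="zm")

matures = {m.mirna_id: m.mature_seq for m in truth.mirnas["zm"][:3]}

sites = targets.scan_transcriptome(matures, truth.transcripts)
print("predicted target sites:")
for s in sites:
    print(f"  {s.mirna_id} -> {s.transcript_id}:{s.start}-{s.end} "
          f"expectation={s.expectation} category={s.category}")
    mir_line, sym, tgt_line = s.alignment
    print(f"    miRNA  5' {mir_line} 3'\n              {sym}\n    target 3' {tgt_line} 5'")

mimics = targets.detect_mimicry(matures, truth.mimic_lncrnas)
print("\nendogenous target mimic sites:")
for m in mimics:
    print(f"  {m.mirna_id} ~ {m.lncrna_id}:{m.start}-{m.end} "
          f"bulge={m.bulge_length} nt after miRNA position {m.bulge_after_position}, "
          f"flank expectation={m.flank_expectation}")

lnc_truth = copy.deepcopy(truth)
records = synthio.plant_conserved_lncrnas(lnc_truth, seed=11)
tags = [reg["fragment"] for r in records for reg in r["regions"].values()]
cands = targets.screen_conserved_lncrna(
    lnc_truth.ortholog_pairs,
    lnc_truth.genes["zm"], lnc_truth.genes["os"],
    lnc_truth.genomes["zm"], lnc_truth.genomes["os"],
    tags, seed=12, n_shuffles=50,
)
print("\nconserved structured lncRNA candidates:")
for c in cands:
    print(f"  {c.gene_a} / {c.gene_b}  e={c.e_value:.2e}  structure z={c.structure_z:.2f}")

curated = pd.DataFrame(
    {
        "gene_id": [s.transcript_id for s in sites[:2]],
        "label": ["SBP-box TF", "ARF"],
        "annotation": ["squamosa promoter binding", "auxin response factor"],
    }
)
print("\nintersection with a curated gene list:")
print(targets.intersect_gene_lists(sites, curated).to_string(index=False))
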