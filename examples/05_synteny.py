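"""Find collinear blocks between the two genomes and call miRNA synteny.

Reciprocal-best-hit ortholog pairing of the translated gene models, chaining
into collinear blocks (>= 5 anchors, <= 10 inserted genes), miRNA synteny
calls by block containment, and 10-kb precursor clusters.
"""

import pandas as pd

from etiomir import synteny, synthio

spec_zm = synthio.GenomeSpec("zm", 2, (150_000, 150_000), seed=1)
spec_os = synthio.GenomeSpec("os", 2, (150_000, 150_000), seed=2)
truth = synthio.make_genomes(spec_zm, spec_os, 2, 5, seed=3, max_insertions=8)
truth = synthio.plant_mirnas(truth, 8, seed=4, within_blocks=True)

proteomes = {
    sp: {r.gene_id: synteny.translate_cds(r.cds) for r in truth.genes[sp].itertuples()}
    for sp in ("zm", "os")
}
pairs = synteny.find_orthologs(proteomes["zm"], proteomes["os"])
print(f"reciprocal best hits at e<=1e-10: {len(pairs)} "
      f"(planted anchors: {len(truth.ortholog_pairs)})")

blocks = synteny.chain_collinear(pairs, truth.genes["zm"], truth.genes["os"])
print(synteny.blocks_table(blocks).to_string(index=False))

mir_frames = {
    sp: pd.DataFrame(
        [
            {"mirna_id": m.mirna_id, "family_id": m.family_id,
             "chrom": m.chrom, "start": m.start, "end": m.end}
            for m in truth.mirnas[sp]
        ]
    )
    for sp in ("zm", "os")
}
calls = synteny.assign_mirna_synteny(mir_frames["zm"], mir_frames["os"], blocks)
summary = synteny.syntenic_family_summary(calls)
print("syntenic families:", summary)

clusters = synteny.detect_clusters(mir_frames["zm"])
print("10-kb precursor clusters (zm):", clusters or "none")
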