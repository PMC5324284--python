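"""Clean raw small-RNA reads into a collapsed tag table.

Quality filtering, 3' adapter trimming with the one-mismatch-per-10-nt rule,
tag collapsing across the 8 samples, contaminant screening, and the length
distribution that should peak at the canonical 21/24-nt plant small-RNA sizes.
"""

from etiomir import preprocess, synthio

spec_zm = synthio.GenomeSpec("zm", 2, (150_000, 150_000), seed=1)
spec_os = synthio.GenomeSpec("os", 2, (150_000, 150_000), seed=2)
truth = synthio.make_genomes(spec_zm, spec_os, 2, 5, seed=3, max_insertions=8)
truth = synthio.plant_mirnas(truth, 8, seed=4, within_blocks=True)
truth.contaminants = synthio.make_contaminants(seed=5)

cfg = synthio.ReadSimConfig(depth=2000, error_rate=0.005, contaminant_fraction=0.1)
reads = synthio.simulate_reads(truth, cfg, seed=7, species="zm")

per_sample = {}
for sample, recs in reads.items():
    kept, qc_tally = preprocess.quality_filter([(n, s, [40] * len(s)) for n, s, _ in recs])
    inserts, trim_tally = preprocess.trim_sample(kept, cfg.adapter)
    per_sample[sample] = inserts
    if sample == "h0":
        print(f"[{sample}] {qc_tally.total} raw reads, "
              f"{qc_tally.retained} pass QC, {len(inserts)} adapter-trimmed")

tags = preprocess.collapse_tags(per_sample)
print(f"unique tags across samples: {len(tags)}")

index = preprocess.ContaminantIndex(truth.contaminants)
tags, removed = preprocess.filter_contaminants(tags, index)
print("contaminant classes removed:")
print(removed)

dist = preprocess.length_distribution(tags)
print("tag length distribution (reads):")
print(dist["reads"].to_string())
print(f"modal read length: {dist['reads'].idxmax()} nt")
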