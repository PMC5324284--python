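"""Discover miRNA hairpins from a cleaned tag table.

Maps tags to the genome, excises candidate precursors, folds them with the
internal Nussinov folder, applies the read-signature and structure filters,
the 90% conservation screen against known matures, and the strict TPQ > 10
expression filter, then names candidates in the <species>_<chrom>_<order>
convention and compares the result with the planted ground truth.
"""

from etiomir import discovery, preprocess, synthio

spec_zm = synthio.GenomeSpec("zm", 2, (150_000, 150_000), seed=1)
spec_os = synthio.GenomeSpec("os", 2, (150_000, 150_000), seed=2)
truth = synthio.make_genomes(spec_zm, spec_os, 2, 5, seed=3, max_insertions=8)
truth = synthio.plant_mirnas(truth, 8, seed=4, within_blocks=True)
synthio.make_known_matures(truth, seed=6)

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

known = dict(truth.known_matures)
report = discovery.discover(tags, truth.genomes["zm"], "zm", known_matures=known)

print(f"candidate stacks: {report.n_stack_candidates}, folded/scored: {report.n_prefilter}, "
      f"pass structure+signature: {report.n_pass_structure}, retained (TPQ>10): {report.n_retained}")
print(discovery.novel_table(report.novel).to_string(index=False))

planted = {(m.chrom, m.start, m.end) for m in truth.mirnas["zm"]}
recovered = sum(
    any(n.chrom == c and not (n.end < s or n.start > e) for n in report.novel)
    for c, s, e in planted
)
print(f"recovered {recovered}/{len(planted)} planted miRNA loci")
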