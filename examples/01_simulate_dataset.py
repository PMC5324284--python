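"""Simulate a seeded two-species small-RNA de-etiolation dataset.

Builds two toy genomes (maize-like "zm" and rice-like "os") with collinear
ortholog blocks, plants conserved miRNA hairpins, simulates adapter-ligated
sequencing reads for the 7 time points plus the light-grown control, and
writes everything plus the ground-truth manifest to ./scratch/dataset.
"""

from pathlib import Path

from etiomir import synthio

OUT = Path(__file__).resolve().parent.parent / "scratch" / "dataset"

spec_zm = synthio.GenomeSpec("zm", 2, (150_000, 150_000), seed=1)
spec_os = synthio.GenomeSpec("os", 2, (150_000, 150_000), seed=2)
truth = synthio.make_genomes(
    spec_zm, spec_os, n_ortholog_blocks=2, genes_per_block=5, seed=3, max_insertions=8
)
truth = synthio.plant_mirnas(truth, 8, seed=4, within_blocks=True)
truth.contaminants = synthio.make_contaminants(seed=5)
synthio.make_known_matures(truth, seed=6)

cfg = synthio.ReadSimConfig(depth=2000, error_rate=0.005, contaminant_fraction=0.1)
reads = {sp: synthio.simulate_reads(truth, cfg, seed=7, species=sp) for sp in ("zm", "os")}

OUT.mkdir(parents=True, exist_ok=True)
synthio.write_dataset(OUT, truth, reads)

for sp in ("zm", "os"):
    genome_nt = sum(len(s) for s in truth.genomes[sp].values())
    n_reads = sum(len(r) for r in reads[sp].values())
    print(f"{sp}: {genome_nt:,} nt genome, {len(truth.genes[sp])} genes, "
          f"{len(truth.mirnas[sp])} planted miRNAs, {n_reads:,} reads over 8 samples")
print(f"planted ortholog anchor pairs: {len(truth.ortholog_pairs)}")
print(f"dataset written to {OUT}")
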