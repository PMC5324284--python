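import numpy as np
import pytest

from etiomir import synthio


@pytest.fixture(scope="session")
def small_truth():
    """A small two-species dataset shared by read-level tests."""
    spec_a = synthio.GenomeSpec("zm", 2, (120_000, 120_000), seed=1)
    spec_b = synthio.GenomeSpec("os", 2, (120_000, 120_000), seed=2)
    truth = synthio.make_genomes(
        spec_a, spec_b, n_ortholog_blocks=2, genes_per_block=5, seed=3, max_insertions=8
    )
    truth = synthio.plant_mirnas(truth, 6, seed=4, within_blocks=True)
    truth.contaminants = synthio.make_contaminants(seed=5)
    synthio.make_known_matures(truth, seed=6)
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
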