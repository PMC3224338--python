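import numpy as np
import pytest

from estsurvey import simulate


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete simulated library."""
    return simulate.SimConfig(n_genes=60, n_reads=800, seed=7,
                              length_range=(300, 800))


@pytest.fixture(scope="session")
def small_library(small_config):
    tr = simulate.build_transcriptome(small_config)
    weights = simulate.draw_weights(tr, small_config)
    reads, truth = simulate.generate_reads(tr, weights, small_config)
    return tr, weights, reads, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
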