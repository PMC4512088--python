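import numpy as np
import pytest
from hypothesis import settings

from sagetf import synthetic as sy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study configuration used across integration tests."""
    return sy.SimulationConfig(
        seed=7,
        n_genes=250,
        library_depth=1000,
        promoter_length=1501,
        footprint_block_length=400,
        enriched_term_size=20,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    transcriptome, truth = sy.simulate_transcriptome(small_config)
    libraries = sy.simulate_libraries(transcriptome, small_config)
    return transcriptome, truth, libraries


@pytest.fixture
def rng():
    return np.random.default_rng(42)
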