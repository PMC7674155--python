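import numpy as np
import pytest

from pmocphage.synthetic import CommunityConfig, simulate_community


@pytest.fixture(scope="session")
def community():
    """One default synthetic community shared across tests."""
    config = CommunityConfig(seed=1)
    genomes, truth = simulate_community(config)
    return config, genomes, truth


@pytest.fixture(scope="session")
def fast_config():
    """Smaller genomes for tests that iterate over many communities."""
    return CommunityConfig(genome_length_range=(15_000, 25_000), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
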