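import numpy as np
import pytest

from hybridscar import GenomeModel, SimConfig, StrainCatalog, substream


@pytest.fixture(scope="session")
def genome():
    return GenomeModel.example(n_chromosomes=3, length_bp=100_000_000,
                               map_length_morgans=1.0)


@pytest.fixture(scope="session")
def catalog(genome):
    return StrainCatalog.random(genome, 3000, substream(7, "catalog"))


@pytest.fixture()
def config():
    return SimConfig(mean_depth=80.0, base_error_rate=0.001,
                     n_catalog_sites=3000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
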