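import numpy as np
import pytest

from ktwsim import SpeciesParams, initialize, load_config, with_seed


@pytest.fixture
def four_species():
    return [SpeciesParams(i + 1, p) for i, p in enumerate((0.3, 0.5, 0.7, 0.9))]


@pytest.fixture
def small_lattice(four_species):
    """10x10 lattice, 4 species, 40% occupancy, fixed seed."""
    return initialize(four_species, width=10, height=10, fraction=0.4,
                      rng=np.random.default_rng(42))


@pytest.fixture
def default_config():
    return with_seed(load_config(), 7)
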