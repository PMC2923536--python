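import numpy as np
import pytest

from tillingkit.io import load_brapa_assays
from tillingkit.popsim import SimConfig, make_reference, mutagenize_population
from tillingkit.screen_stats import PopulationConstants


@pytest.fixture(scope="session")
def brapa_assays():
    return load_brapa_assays()


@pytest.fixture(scope="session")
def constants():
    return PopulationConstants()


@pytest.fixture(scope="session")
def small_config():
    """A fast 200 kb simulation scale for unit tests."""
    return SimConfig(reference_length=200_000, n_plants=64, seed=7,
                     per_gc_site_rate=2e-3)


@pytest.fixture(scope="session")
def small_population(small_config):
    rng = np.random.default_rng(small_config.seed)
    reference = make_reference(
        small_config.reference_length, small_config.reference_gc, rng
    )
    plants = mutagenize_population(reference, small_config, rng)
    return reference, plants
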