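import pytest

from mitopop.sim import (SimConfig, simulate_donor, simulate_population,
                         simulate_reference)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Mid-size study population shared across tests (read-only)."""
    return SimConfig(seed=42, n_lineages=5, isolates_per_lineage=6,
                     petite_fraction=0.1)


@pytest.fixture(scope="session")
def reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def population(small_config, reference):
    return simulate_population(reference, small_config)


@pytest.fixture(scope="session")
def donor(small_config):
    return simulate_donor(small_config)
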