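import pytest

from paracns.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle shared across tests."""
    return simulate_bundle(SimulationConfig(n_pairs=60, seed=11))
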