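import numpy as np
import pytest

from varlinks import SimulationConfig, simulate_2cycles


@pytest.fixture(scope="session")
def fixture_bundle():
    """One fully simulated study (genome, motifs, genotypes, expression,
    planted 2-cycles) shared across tests that only read it."""
    return simulate_2cycles(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
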