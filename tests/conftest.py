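import numpy as np
import pytest

from netconsist import SyntheticScenario, simulate


@pytest.fixture(scope="session")
def chain_data():
    """Large-n chain-truth paired dataset shared across recovery tests."""
    scenario = SyntheticScenario(p=10, n=2000, topology="chain",
                                 partial_corr_strength=0.3, seed=42)
    return simulate(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
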