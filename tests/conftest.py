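import numpy as np
import pytest

from telandscape.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One simulated landscape shared across read-only tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def perfect_sim():
    """Simulated landscape without truncation (every copy full length)."""
    return simulate(SimConfig(seed=12, truncation_prob=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
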