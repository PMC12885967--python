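import numpy as np
import pytest

from nirscoupling.coupling import WaveletConfig
from nirscoupling.spectral import load_default_extinction
from nirscoupling.synthetic import CouplingScenario

FS = 0.5


@pytest.fixture(scope="session")
def wcfg() -> WaveletConfig:
    return WaveletConfig()


@pytest.fixture(scope="session")
def extinction():
    return load_default_extinction(distance=1.0)


@pytest.fixture()
def scenario() -> CouplingScenario:
    """Full-length acquisition scenario: 30 min at 0.5 Hz."""
    return CouplingScenario(seed=42)


@pytest.fixture()
def short_scenario() -> CouplingScenario:
    """A 10-min scenario for tests that do not need the full record."""
    return CouplingScenario(duration=600.0, seed=42)


@pytest.fixture()
def time_vector():
    return np.arange(900) / FS
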