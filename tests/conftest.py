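import numpy as np
import pytest

from sacsim.config import default_config
from sacsim.experiments import Simulator
from sacsim.world import MappingParams, WorldRenderer


@pytest.fixture(scope="session")
def mapping():
    return MappingParams()


@pytest.fixture(scope="session")
def renderer():
    return WorldRenderer()


@pytest.fixture(scope="session")
def reference_config():
    return default_config()


@pytest.fixture(scope="session")
def simulator():
    """One shared closed-loop simulator; tests reset it via seeds."""
    return Simulator()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
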