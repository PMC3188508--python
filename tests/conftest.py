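import numpy as np
import pytest
from hypothesis import settings

from reachsim import RunConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    """The shipped default configuration (one parameter set for everything)."""
    return RunConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
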