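import numpy as np
import pytest
from hypothesis import settings

from cortiplast.core_io import Config

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def cfg() -> Config:
    return Config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
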