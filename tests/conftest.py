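import numpy as np
import pytest

from calanus_diapause import GeneratorConfig, ModelParams
from calanus_diapause.biometry import SYNTHETIC_ALLOMETRY


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def allometry():
    return SYNTHETIC_ALLOMETRY


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gen_config():
    return GeneratorConfig(seed=42)
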