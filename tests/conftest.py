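import numpy as np
import pytest
from hypothesis import settings

from eegleakage.simulate import GeneratorConfig, generate
from eegleakage.preprocess import prepare

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_dataset():
    """A minimal dataset: 2 subjects x 3 videos, 4 channels, 8 s at 32 Hz."""
    return generate(GeneratorConfig(S=2, V=3, C=4, f=32, D=8, seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured dataset used by split/pipeline tests."""
    return generate(GeneratorConfig(S=6, V=10, C=8, f=32, D=24, seed=7))


@pytest.fixture(scope="session")
def small_segments(small_dataset):
    return prepare(small_dataset, T=1.0, overlap=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
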