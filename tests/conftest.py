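import numpy as np
import pytest

from octflux.model import ModelConfig, build_model
from octflux.simulate import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model_config():
    """A fast architecture for unit tests (same topology, small widths)."""
    return ModelConfig(
        input_length=64,
        n_inception_modules=2,
        bottleneck_channels=3,
        n_filters_per_branch=3,
        kernel_sizes=(3, 5, 9),
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_model_config):
    return build_model(tiny_model_config, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """A small balanced dataset shared across read-only tests."""
    return generate_dataset(per_category=10, rng=42)
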