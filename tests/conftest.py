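import numpy as np
import pytest

from astromem import SynapseParams, TaskConfig, synthetic_feature_bank


@pytest.fixture(scope="session")
def params():
    """Published synapse parameter set."""
    return SynapseParams()


@pytest.fixture(scope="session")
def bank():
    """Small reproducible synthetic feature bank (8 x 64)."""
    return synthetic_feature_bank(8, dim=64, sparsity=0.8, overlap=0.1, seed=123)


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def short_task():
    """Shorter sessions (50 steps) for fast training tests."""
    return TaskConfig(length_ms=12_500, min_repeats=2, max_repeats=8)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
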