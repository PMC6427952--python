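import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lgnv1 import ModelConfig, WeightSet, init_weights


@pytest.fixture
def small_config() -> ModelConfig:
    """A 4x4-patch model small enough for exhaustive checks."""
    return ModelConfig(n_lgn=16, n_cortex=8)


@pytest.fixture
def small_weights(small_config) -> WeightSet:
    return init_weights(small_config, seed=1234)


def make_antisymmetric_weights(A: np.ndarray) -> WeightSet:
    """Exactly anti-symmetric Dale-split weights from a composite matrix."""
    pos = np.maximum(A, 0.0)
    neg = np.minimum(A, 0.0)
    return WeightSet(A_up_pos=pos, A_up_neg=neg, A_dn_pos=-neg, A_dn_neg=-pos)


@pytest.fixture
def antisym_factory():
    return make_antisymmetric_weights
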