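import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dlbclcea import CyclePlan, ModelConfig, default_parameters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def plan() -> CyclePlan:
    return CyclePlan()


@pytest.fixture
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def no_discount_config() -> ModelConfig:
    return ModelConfig(
        discount_rate_costs=0.0,
        discount_rate_effects=0.0,
        half_cycle_correction=False,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
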