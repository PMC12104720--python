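import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import collascore as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

SMALL_SHAPE = (48, 48, 24)


@pytest.fixture(scope="session")
def small_spec() -> cs.PhantomSpec:
    return cs.PhantomSpec(grid_shape=SMALL_SHAPE, seed=7, true_ratio=0.5)


@pytest.fixture(scope="session")
def small_case(small_spec) -> cs.PhantomCase:
    return cs.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def symmetric_case() -> cs.PhantomCase:
    return cs.generate_phantom(
        cs.PhantomSpec(grid_shape=SMALL_SHAPE, seed=3, true_ratio=1.0)
    )


@pytest.fixture(scope="session")
def tiny_model() -> cs.U2Net:
    """Very small nested-U net for shape/gradient tests."""
    cfg = cs.ModelConfig(n_encoder_stages=2, base_channels=4, rsu_depths=(2, 2))
    return cs.build_model(cfg, seed=0)


@pytest.fixture(scope="session")
def scaled_model() -> cs.U2Net:
    return cs.build_model(cs.ModelConfig.scaled(), seed=0)
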