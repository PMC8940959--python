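import numpy as np
import pytest

from mlec import GridSpec, WorldConfig, generate_world
from mlec.constrain import fast_mlt_overrides


@pytest.fixture(scope="session")
def coarse_world():
    """Small (10 deg) default-physics world shared by the slower tests."""
    return generate_world(WorldConfig(spec=GridSpec.global_grid(10.0), seed=11))


@pytest.fixture(scope="session")
def thin_overrides():
    return fast_mlt_overrides()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
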