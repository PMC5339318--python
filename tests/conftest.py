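import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from thermoshred.specs import (  # noqa: E402
    DIKEROGAMMARUS_VILLOSUS,
    GAMMARUS_PULEX,
    DesignSpec,
    GradientSpec,
)


@pytest.fixture
def gradient():
    return GradientSpec()


@pytest.fixture
def design():
    return DesignSpec()


@pytest.fixture
def small_design():
    """Cut-down replication for fast generator tests."""
    return DesignSpec(n_per_acclimation=6, n_replicates=3, n_control_per_temp=1)


@pytest.fixture
def gpulex():
    return GAMMARUS_PULEX


@pytest.fixture
def dvillosus():
    return DIKEROGAMMARUS_VILLOSUS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
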