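import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mahaniche import NicheParams, generate_space

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """The default virtual-species niche."""
    return NicheParams()


@pytest.fixture(scope="session")
def space():
    """The default synthetic regional climate space (fixed seed)."""
    return generate_space(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cluster_with_two_outliers():
    """12 clustered points plus 2 gross outliers (rows 12, 13)."""
    g = np.random.default_rng(42)
    return np.vstack([g.normal(0.0, 1.0, (12, 2)),
                      [[20.0, 20.0], [25.0, -18.0]]])


@pytest.fixture(scope="session")
def cluster_with_one_outlier():
    """20 tight clustered points plus 1 far outlier (row 20)."""
    g = np.random.default_rng(7)
    return np.vstack([g.normal(0.0, 1.0, (20, 2)), [[30.0, -25.0]]])
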