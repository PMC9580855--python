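import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_cloud(rng):
    """10^4 uniform points in the unit cube, for geometry oracles."""
    from smlmtk import PointCloud
    pos = rng.uniform(0, 1, (10_000, 3))
    return PointCloud(pos, np.arange(10_000, dtype=float),
                      {"intensity": rng.uniform(10, 100, 10_000)})
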