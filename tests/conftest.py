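import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid_2d():
    from cardionet import StructuredGrid

    return StructuredGrid((10, 10), (0.25, 0.25))


@pytest.fixture
def small_grid_3d():
    from cardionet import StructuredGrid

    return StructuredGrid((5, 5, 5), (0.25, 0.25, 0.25))


def random_unit_vectors(rng, n, dim):
    v = rng.standard_normal((n, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
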