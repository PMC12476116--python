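import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_atlas():
    from crpmap.synthetic import make_atlas
    return make_atlas(shape=(16, 16, 16), n_regions=60, voxel_size=3.0,
                      seed=42)


@pytest.fixture(scope="session")
def chain_edges():
    import numpy as np
    return np.array([[i, i + 1] for i in range(149)], dtype=np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
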