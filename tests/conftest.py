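import numpy as np
import pandas as pd
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
def toy_incubation():
    """Small, hand-checkable constant-temperature incubation table."""
    return pd.DataFrame(
        {
            "temperature_C": [27.0, 29.0, 30.0, 31.0, 33.0],
            "n_eggs": [50, 50, 50, 50, 50],
            "n_hatched": [40, 45, 44, 43, 20],
            "n_sexed": [40, 45, 44, 43, 20],
            "n_female": [1, 10, 22, 40, 20],
            "n_male": [39, 35, 22, 3, 0],
        }
    )


@pytest.fixture
def symmetric_matrix_factory(rng):
    def make(n, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        M = r.uniform(size=(n, n))
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 0.0)
        return M

    return make
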