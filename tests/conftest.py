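import numpy as np
import pytest

from hofcnet import synthio


@pytest.fixture(scope="session")
def tiny_config():
    """Miniature cohort configuration for fast end-to-end tests."""
    return synthio.GeneratorConfig(
        n_patient=4, n_control=4, n_regions=15, n_timepoints=80,
        module_sizes={"SMN": 3, "DMN": 3, "FPN": 3, "VN": 3, "SN": 3},
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return synthio.generate_cohort(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, p, scale=0.3):
    """Random symmetric matrix with zero diagonal (connectivity-like)."""
    a = rng.normal(0.0, scale, size=(p, p))
    m = np.clip((a + a.T) / 2.0, -0.95, 0.95)
    np.fill_diagonal(m, 0.0)
    return m
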