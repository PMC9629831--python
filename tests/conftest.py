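import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from moltmap.synthetic_data import SimConfig, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Scaled-down genome with all strata and six plantable families."""
    return SimConfig(n_genes=3000, seed=11)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Noise-free, mutation-free limit: downstream recovery must be exact."""
    return SimConfig(
        n_genes=1200, noise_sd=0.0, family_mutation_rate=0.0, seed=5
    )


@pytest.fixture(scope="session")
def clean_data(clean_cfg):
    return simulate(clean_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
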