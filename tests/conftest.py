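import numpy as np
import pytest

from dynrad import SimulationConfig, simulate_feature_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-signal cohort shared across read-only tests."""
    return simulate_feature_cohort(
        SimulationConfig(n_patients=40, n_features=30, n_informative=6, effect_size=1.0, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pytest_configure(config):
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True)
    settings.load_profile("deterministic")
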