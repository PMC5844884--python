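import numpy as np
import pytest

from enhancerkit.synth import StudyParams, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down synthetic study shared by fast integration tests."""
    params = StudyParams(
        n_per_state=25, n_up=30, n_down=30, n_undetected=10, n_patients=150
    )
    return simulate_study(params, seed=11)


@pytest.fixture(scope="session")
def full_study():
    """The default study conditions (200 enhancers per state, 2M tags)."""
    return simulate_study(StudyParams(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
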