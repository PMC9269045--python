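import numpy as np
import pytest

from gaitsynergy.profiles import make_profile
from gaitsynergy.synthetic import generate_trial, make_cohort


@pytest.fixture(scope="session")
def quiet_healthy_profile():
    """Healthy group profile with measurement noise switched off."""
    return make_profile("healthy", overrides={"noise_sd": 0.0})


@pytest.fixture(scope="session")
def quiet_healthy_trial(quiet_healthy_profile):
    return generate_trial(quiet_healthy_profile, 6, seed=11)


@pytest.fixture(scope="session")
def healthy_cohort():
    """Small default-noise healthy cohort shared across tests."""
    return make_cohort("healthy", 4, seed=101, n_cycles=6)
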