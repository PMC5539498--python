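import numpy as np
import pytest

from attnaccess.core import ATTENTION, NON_ATTENTION, Trial
from attnaccess.synthetic import SimConfig, SubjectProfile, generate_cohort


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def ideal_profile():
    """Zero-noise, zero-latency subject: attention is exactly the class mean."""
    return SubjectProfile(
        "ideal",
        mu_att=80.0,
        mu_non=20.0,
        sigma_within=0.0,
        tau_on=0.0,
        tau_off=0.0,
        poor_signal_rate=0.0,
    )


@pytest.fixture(scope="session")
def ideal_sessions(ideal_profile, sim_config):
    return generate_cohort([ideal_profile], sim_config)["ideal"]


@pytest.fixture(scope="session")
def noisy_sessions(sim_config):
    """A realistic separable subject used across modules."""
    profile = SubjectProfile(
        "noisy",
        mu_att=75.0,
        mu_non=25.0,
        sigma_within=10.0,
        ar_coeff=0.5,
        tau_on=2.0,
        tau_off=2.0,
        poor_signal_rate=0.0,
    )
    return generate_cohort([profile], sim_config)["noisy"]


def make_trial(
    attention,
    trial_type=ATTENTION,
    valid=None,
    bands=None,
    n_bands=8,
    trial_index=1,
):
    """Hand-constructed trial with constant default bands."""
    attention = np.asarray(attention, dtype=float)
    n = attention.shape[0]
    if bands is None:
        bands = np.full((n, n_bands), 100.0)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return Trial(
        subject_id="T",
        session_index=1,
        trial_index=trial_index,
        trial_type=trial_type,
        attention=attention,
        meditation=np.full(n, 50.0),
        bands=bands,
        poor_signal=np.zeros(n, dtype=int),
        valid=np.asarray(valid, dtype=bool),
    )
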