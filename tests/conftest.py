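import numpy as np
import pytest

from cibpcrm import (
    ObservationSet,
    PowerModelSpec,
    everolimus_fixture,
    init_posterior,
    update_posterior,
)


@pytest.fixture(scope="session")
def everolimus():
    return everolimus_fixture()


@pytest.fixture(scope="session")
def ev_model(everolimus):
    return everolimus.model


@pytest.fixture(scope="session")
def ev_prior_state(ev_model):
    return init_posterior(ev_model)


@pytest.fixture(scope="session")
def ev_state_c1(ev_prior_state):
    """Posterior after the first replay cohort: 3 non-DLTs at dose 1."""
    return update_posterior(ev_prior_state, ObservationSet.from_counts([3, 0, 0], [0, 0, 0]))


@pytest.fixture(scope="session")
def ev_state_c2(ev_state_c1):
    """Posterior after two replay cohorts: d1 0/3, d2 1/3."""
    return update_posterior(ev_state_c1, ObservationSet.from_counts([0, 3, 0], [0, 1, 0]))


class FakeHistory:
    """Minimal trial-history stand-in for exercising allocation rules."""

    def __init__(self, doses, n_dlts=0, last_cohort_had_dlt=False, cohort_size=3):
        self.doses_administered = tuple(doses)
        self.n_patients = cohort_size * len(doses)
        self.n_dlts = n_dlts
        self.last_cohort_had_dlt = last_cohort_had_dlt


@pytest.fixture
def fake_history():
    return FakeHistory
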