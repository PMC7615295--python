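import numpy as np
import pytest
from hypothesis import settings

import nisurv as nv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_ds(times, events, arms, label=""):
    return nv.SurvivalDataset(times, events, arms, label=label)


@pytest.fixture(scope="session")
def scen13_design():
    """Scenario-13-like design: control 3-year survival 90%, 250 per arm."""
    return nv.TrialDesign(s3_control=0.9, n_per_arm=250, true_hr=1.0)


@pytest.fixture(scope="session")
def exp_trial(scen13_design):
    """One simulated trial under equal exponential arms (all-data window)."""
    return nv.simulate_trial(nv.SimSpec(design=scen13_design, seed=12345))


@pytest.fixture(scope="session")
def exp_trial_tau(exp_trial):
    return nv.censor_at(exp_trial, 3.0)


@pytest.fixture(scope="session")
def fitted_model(exp_trial_tau):
    return nv.fit_flexpar(exp_trial_tau)
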