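import numpy as np
import pandas as pd
import pytest

from prlearn import (
    AgentParams,
    PopulationSpec,
    Phase,
    Role,
    TrialRecord,
    simulate_cohort,
    simulate_session,
)


@pytest.fixture(scope="session")
def m3_params():
    return AgentParams(model_id="M3", alpha_rew=0.8, alpha_pun=0.3,
                       tau_reinf=5.0, tau_stim=0.3)


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject M1 cohort used by quick inference tests."""
    spec = PopulationSpec(n_subjects=5, seed=11)
    data, truth = simulate_cohort(spec, model_id="M1")
    return spec, data, truth


@pytest.fixture(scope="session")
def simulated_session(m3_params):
    return simulate_session(m3_params, rng=123, subject="s1", condition="drug")


def make_trials(choices, outcomes, subject="s1", condition="c", start=1,
                roles=None):
    """Hand-build a consecutive trial sequence for toy examples."""
    recs = []
    for k, (c, o) in enumerate(zip(choices, outcomes)):
        trial = start + k
        recs.append(TrialRecord(
            subject=subject, condition=condition, trial=trial,
            phase=Phase.ACQUISITION if trial <= 40 else Phase.REVERSAL,
            choice=c, outcome=o,
            chosen_role=(roles[k] if roles else Role.NEUTRAL),
        ))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(7)
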