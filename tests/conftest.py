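import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import selfprior as sp
from selfprior.pipeline import exp1_stop_task

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def stop_task():
    return exp1_stop_task()


@pytest.fixture(scope="session")
def big_stop_task():
    return dataclasses.replace(exp1_stop_task(), trials_per_block=10_000)


@pytest.fixture(scope="session")
def observer_params():
    """A well-identified generative observer (w = 0.36)."""
    return sp.ObserverParams(prior_sd_px=40.0, evidence_sd_px=30.0, performance_sd_px=40.0)


def make_two_condition_dataset(
    n_per_condition=200,
    self_prior=24.0,
    agent_prior=40.0,
    self_evid=25.0,
    agent_evid=30.0,
    perf_sd=40.0,
    seed=0,
):
    """Self block + agent replay with known generative parameters."""
    tc = dataclasses.replace(exp1_stop_task(), trials_per_block=n_per_condition)
    sp_p = sp.ObserverParams(prior_sd_px=self_prior, evidence_sd_px=self_evid,
                             performance_sd_px=perf_sd)
    ag_p = sp.ObserverParams(prior_sd_px=agent_prior, evidence_sd_px=agent_evid,
                             performance_sd_px=perf_sd)
    sb = sp.simulate_stop_block(tc, sp_p, "self", seed=seed)
    ab = sp.simulate_agent_replay(sb, tc, ag_p, seed=seed + 10_000)
    return pd.concat([sb, ab], ignore_index=True)


@pytest.fixture(scope="session")
def two_condition_dataset():
    return make_two_condition_dataset(seed=42)
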