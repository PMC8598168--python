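import numpy as np
import pytest

import combicode as cc
from combicode.responses import ResponseMatrix


@pytest.fixture(scope="session")
def space5():
    return cc.enumerate_conditions(5, include_catch=True)


@pytest.fixture(scope="session")
def design5(space5):
    return cc.design_matrix(space5)


def make_response_matrix(pop, cfg, seed):
    """Amplitude-level ResponseMatrix (skips trace rendering for speed)."""
    table, amps = cc.simulate_trials(pop, cfg, seed=seed)
    space = cfg.space()
    resp = ResponseMatrix(values=amps, condition_ids=table.condition_ids(space), space=space)
    return table, resp


@pytest.fixture(scope="session")
def ln_session():
    """Mixed labeled-line / combination-selective population, 20 trials/condition."""
    cfg = cc.SessionConfig(n_neurons=60, trials_per_condition=20, seed=7, trial_noise_sd=0.15)
    pop = cc.sample_population(cfg, mixture=(0.4, 0.6, 0.0), seed=7)
    table, resp = make_response_matrix(pop, cfg, seed=8)
    return cfg, pop, table, resp
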