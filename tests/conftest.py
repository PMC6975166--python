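import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from acttime.task import TaskConfig, default_agent, generate_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def agent():
    return default_agent()


@pytest.fixture(scope="session")
def small_cohort(cfg, agent):
    """2 animals x 3 sessions x 150 trials of the default world."""
    return generate_cohort(2, 3, cfg, agent, rng=11, n_trials=150)


@pytest.fixture(scope="session")
def one_session(small_cohort):
    return small_cohort[small_cohort.session_id == "A1-S1"].reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
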