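import logging

import numpy as np
import pandas as pd
import pytest

from urnbid.agents import AgentProfile, CohortSpec, simulate_cohort
from urnbid.task import ColorScheme, build_session

# mixed-model singular-fit / empty-cell warnings are expected in small fixtures
logging.getLogger("urnbid").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scheme():
    return ColorScheme()


@pytest.fixture(scope="session")
def plan():
    return build_session(seed=1)


@pytest.fixture(scope="session")
def old_cohort():
    """One seeded old-like cohort at the canonical sample size."""
    trials, cov = simulate_cohort(CohortSpec.preset("old_like", seed=11))
    return trials, cov


@pytest.fixture(scope="session")
def recovery_cohort_factory():
    """Cohorts with fixed (known) generative weights, away from the bid floor."""

    def make(seed, **kw):
        means = dict(
            w_belief=0.5, w_ev_pos=0.05, w_ev_neg=0.1,
            ambiguity_premium=1.5, noise_sd=1.0,
        )
        means.update(kw)
        spec = CohortSpec(
            n_agents=46, label="recovery", seed=seed,
            means=AgentProfile(**means), sds={},
        )
        return simulate_cohort(spec)

    return make
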