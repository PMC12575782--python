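"""Session-scoped trained cohorts shared across the behavioural,
demixing, generalization and acceptance tests.

Training these once keeps the whole suite within a practical runtime:
five seeds of the recurrent and feedforward agents at the desk scale
(4,000 trials), plus a three-seed recurrent cohort trained with
probabilistic (p = 0.8) cue visibility.
"""

import numpy as np
import pytest

from hcnav.agents import AgentConfig
from hcnav.maze import PerturbationSpec
from hcnav.studies import train_cohort

COHORT_SEEDS = (0, 1, 2, 3, 4)
PROB_SEEDS = (10, 11, 12)


@pytest.fixture(scope="session")
def drqn_cfg():
    return AgentConfig(architecture="recurrent")


@pytest.fixture(scope="session")
def dqn_cfg():
    return AgentConfig(architecture="feedforward")


@pytest.fixture(scope="session")
def drqn_cohort():
    return train_cohort("recurrent", COHORT_SEEDS)


@pytest.fixture(scope="session")
def dqn_cohort():
    return train_cohort("feedforward", COHORT_SEEDS)


@pytest.fixture(scope="session")
def drqn_prob_cohort():
    pert = PerturbationSpec("probabilistic_cues", cue_prob=0.8)
    return train_cohort("recurrent", PROB_SEEDS, perturbation=pert)
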