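import numpy as np
import pytest

from protolearn import (
    CategoryStructure,
    build_model_bank,
    build_testing_schedule,
    build_training_schedule,
)
from protolearn.stimulus_design import TrialSchedule


@pytest.fixture(scope="session")
def structure():
    return CategoryStructure()


@pytest.fixture(scope="session")
def training_schedule(structure):
    return build_training_schedule(structure, "feedback", seed=11)


@pytest.fixture(scope="session")
def testing_schedule(structure, training_schedule):
    return build_testing_schedule(structure, training_schedule, seed=12)


@pytest.fixture(scope="session")
def model_bank(training_schedule):
    return build_model_bank(training_schedule)


@pytest.fixture(scope="session")
def long_testing_schedule(structure, training_schedule):
    """~500-trial evaluation segment: ten concatenated testing schedules."""
    trials = []
    for s in range(10):
        trials += build_testing_schedule(structure, training_schedule, seed=100 + s).trials
    return TrialSchedule(phase="testing", trials=trials)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
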