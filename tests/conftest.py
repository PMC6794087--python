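import numpy as np
import pytest

from foragefit.synthetic import CohortSpec, simulate_foraging, simulate_itc
from foragefit.task import (
    FORAGING_EXPERIMENTS,
    StateDurations,
    enumerate_chains,
    itc_environment,
)


@pytest.fixture(scope="session")
def durations():
    return StateDurations(decision_s=1.0, consumption_ul_per_s=20.0, gate_s=1.0)


@pytest.fixture(scope="session")
def travel_chains(durations):
    return enumerate_chains(FORAGING_EXPERIMENTS["travel_time"]["10s"], durations)


@pytest.fixture(scope="session")
def itc_chains(durations):
    return enumerate_chains(itc_environment("constant_rate"), durations)


@pytest.fixture(scope="session")
def small_foraging_cohort():
    spec = CohortSpec(
        task="foraging",
        experiment="travel_time",
        n_rats=3,
        patches_per_condition=60,
        seed=101,
    )
    return simulate_foraging(spec)


@pytest.fixture(scope="session")
def small_itc_cohort():
    # same seed and group distribution as the foraging cohort, so each rat
    # carries the same discount parameters in both tasks
    spec = CohortSpec(
        task="itc",
        experiment="itc",
        n_rats=3,
        episodes_per_condition=25,
        seed=101,
    )
    return simulate_itc(spec)
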