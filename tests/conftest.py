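import numpy as np
import pytest

from pursuitlab.design import (
    StimulusGeometry,
    TrialCondition,
    VisualCondition,
)
from pursuitlab.simulate import load_population_defaults, make_observers


@pytest.fixture(scope="session")
def geometry():
    return StimulusGeometry()


@pytest.fixture(scope="session")
def first_order_3():
    return TrialCondition(VisualCondition.PURSUIT_FIRST_ORDER, 3.0)


@pytest.fixture(scope="session")
def second_order_3():
    return TrialCondition(VisualCondition.PURSUIT_SECOND_ORDER, 3.0)


@pytest.fixture(scope="session")
def fixation_3():
    return TrialCondition(VisualCondition.FIXATION, 3.0)


def noise_free_population(**overrides):
    """Population defaults with every noise source switched off."""
    pop = load_population_defaults()
    pop["latency_sd_ms"] = {k: 0.0 for k in pop["latency_sd_ms"]}
    pop["fixation_noise_sd_deg"] = 0.0
    pop["timing_cv"] = 0.0
    pop["motor_sd_ms"] = 0.0
    pop["blink_prob"] = 0.0
    pop["saccade_rate_hz"] = {k: 0.0 for k in pop["saccade_rate_hz"]}
    pop.update(overrides)
    return pop


@pytest.fixture(scope="session")
def noise_free_observer():
    return make_observers(1, seed=0, population=noise_free_population(), jitter=False)[0]


@pytest.fixture(scope="session")
def default_observer():
    return make_observers(1, seed=0, jitter=False)[0]
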