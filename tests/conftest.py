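import numpy as np
import pytest

from painchain import (
    HIDDEN_LABELS,
    OBS_LABELS,
    UNOBSERVED,
    ConditionalTable,
    ObservationSchedule,
    PseudocountDistribution,
    build_model,
    preset_observer,
)


@pytest.fixture
def healthy():
    return preset_observer("healthy")


@pytest.fixture
def chronic():
    return preset_observer("chronic")


def random_model(rng: np.random.Generator, n_steps: int):
    """A random two-state chain with strictly positive parameters."""

    def dist(labels):
        lam = rng.dirichlet((2.0, 2.0))
        lam = np.clip(lam, 0.02, 0.98)
        lam = lam / lam.sum()
        return PseudocountDistribution(labels, lam, float(rng.uniform(5.0, 200.0)))

    prior = dist(HIDDEN_LABELS)
    transition = ConditionalTable(HIDDEN_LABELS, (dist(HIDDEN_LABELS), dist(HIDDEN_LABELS)))
    likelihood = ConditionalTable(HIDDEN_LABELS, (dist(OBS_LABELS), dist(OBS_LABELS)))
    return build_model(prior, transition, likelihood, n_steps)


def random_schedule(rng: np.random.Generator, n_steps: int) -> ObservationSchedule:
    symbols = np.array(["noxious", "harmless", UNOBSERVED])
    return ObservationSchedule(tuple(symbols[rng.integers(0, 3, size=n_steps)]))


@pytest.fixture
def model_factory():
    return random_model


@pytest.fixture
def schedule_factory():
    return random_schedule
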