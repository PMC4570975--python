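import numpy as np
import pytest

from dybm import (
    TrainingConfig,
    init_state,
    advance_state,
    train_until_memorized,
)
from dybm import fixtures


def random_instance(rng, n_neurons=3, history=12, density=0.4, max_delay=9):
    """A small model with random delays/parameters advanced through a random
    binary history; the workhorse input for oracle-based tests."""
    structure = fixtures.random_structure(n_neurons, 1, max_delay, rng)
    params = fixtures.random_parameters(structure, rng=rng)
    state = init_state(structure)
    hist = fixtures.random_sequence(n_neurons, history, density, rng).values
    for t in range(history):
        advance_state(state, hist[t])
    return structure, params, state, hist


@pytest.fixture(scope="session")
def trained_science():
    """A 7-neuron model trained to memorize the SCIENCE sequence (seed 0),
    shared by the anomaly and retrieval tests; returns the structure, the
    converged parameters, and the live post-training state."""
    target = fixtures.science_sequence()
    streams = fixtures.named_streams(0)
    structure = fixtures.random_structure(7, rng=streams["delays"])
    config = TrainingConfig(max_periods=130_000, check_every=10)
    result = train_until_memorized(target, structure, config, streams["params"])
    assert result.converged, "SCIENCE memorization failed for the shared seed"
    return structure, result
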