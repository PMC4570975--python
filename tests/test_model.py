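"""Core dynamics: queues, traces, energy, probabilities, generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dybm import (
    ModelStructure,
    Parameters,
    PatternSequence,
    init_state,
    compute_beta,
    beta_tensor,
    energy_neuron,
    energy_total,
    spike_probability,
    spike_probabilities,
    log_likelihood_step,
    advance_state,
    generate_deterministic,
    sample_step,
)
from dybm import fixtures
from conftest import random_instance
from _oracles import alpha_sum, beta_sum, energy_sum, gamma_sum


def uniform_structure(n, d, **kw):
    return ModelStructure(n, np.full((n, n), d), [0.25, 0.5, 0.75],
                          [0.25, 0.5, 0.75], **kw)


class TestStructure:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            uniform_structure(2, 0)          # delay < 1
        with pytest.raises(ValueError):
            ModelStructure(2, np.ones((2, 2)), [1.0], [0.5])   # decay >= 1
        with pytest.raises(ValueError):
            ModelStructure(2, np.ones((2, 2)), [], [0.5])      # K = 0

    def test_immutable(self):
        s = uniform_structure(2, 3)
        with pytest.raises(ValueError):
            s.delays[0, 0] = 5


class TestInitState:
    def test_unit_delay_means_empty_queues(self):
        state = init_state(uniform_structure(7, 1))
        for i in range(7):
            for j in range(7):
                assert state.queue(i, j).size == 0
        assert not state.synaptic_trace.any() and not state.neural_trace.any()
        assert state.clock == 0

    def test_queue_length_is_delay_minus_one(self):
        state = init_state(uniform_structure(2, 5))
        for i in range(2):
            for j in range(2):
                q = state.queue(i, j)
                assert q.size == 4 and not q.any()

    def test_deterministic(self):
        s = uniform_structure(3, 4)
        assert init_state(s) == init_state(s)


class TestBeta:
    def test_empty_and_spikeless_queues_are_zero(self):
        state = init_state(uniform_structure(2, 1))
        assert compute_beta(state, 0, 1, 0) == 0.0
        state = init_state(uniform_structure(2, 6))
        advance_state(state, [0, 0])
        assert compute_beta(state, 0, 1, 2) == 0.0

    def test_head_proximal_spikes_weigh_more(self):
        # d=4, mu=0.5: queue [1,0,0] (tail->head) vs [0,0,1]
        s = ModelStructure(1, [[4]], [0.5], [0.5])
        tail_spike = init_state(s)
        for x in ([0], [0], [1]):       # spike presented last -> at the tail
            advance_state(tail_spike, x)
        head_spike = init_state(s)
        for x in ([1], [0], [0]):       # spike presented first -> at the head
            advance_state(head_spike, x)
        assert list(tail_spike.queue(0, 0)) == [1, 0, 0]
        assert list(head_spike.queue(0, 0)) == [0, 0, 1]
        b_tail = compute_beta(tail_spike, 0, 0, 0)
        b_head = compute_beta(head_spike, 0, 0, 0)
        assert b_tail == pytest.approx(beta_sum(np.array([[0], [0], [1]]), 0.5, 4, 0))
        assert b_tail == pytest.approx(0.5 ** 3)
        assert b_head == pytest.approx(0.5 ** 1)
        assert b_tail < b_head

    def test_index_errors(self):
        state = init_state(uniform_structure(2, 2))
        with pytest.raises(IndexError):
            compute_beta(state, 2, 0, 0)
        with pytest.raises(IndexError):
            compute_beta(state, 0, 0, 3)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 5), steps=st.integers(0, 50))
def test_traces_equal_defining_sums(seed, n, steps):
    """After any history, the stored recursions reproduce the literal
    weighted sums defining the traces and queue summaries."""
    rng = np.random.default_rng(seed)
    structure = fixtures.random_structure(n, 1, 9, rng)
    state = init_state(structure)
    hist = fixtures.random_sequence(n, steps, 0.5, rng).values
    for t in range(steps):
        advance_state(state, hist[t])
    lam, mu, d = structure.synaptic_decay, structure.neural_decay, structure.delays
    beta = beta_tensor(state)
    for j in range(n):
        for l in range(mu.size):
            assert state.neural_trace[j, l] == pytest.approx(
                gamma_sum(hist, mu[l], j), abs=1e-10)
        for i in range(n):
            for k in range(lam.size):
                assert state.synaptic_trace[i, j, k] == pytest.approx(
                    alpha_sum(hist, lam[k], d[i, j], i), abs=1e-10)
            for l in range(mu.size):
                assert beta[i, j, l] == pytest.approx(
                    beta_sum(hist, mu[l], d[i, j], i), abs=1e-12)
                assert compute_beta(state, i, j, l) == pytest.approx(
                    beta[i, j, l], abs=1e-12)


def test_single_spike_reaches_synapse_after_the_conduction_delay():
    """A spike from neuron i with d[i,j]=3 first appears in alpha[i,j]
    exactly when it exits the queue, three steps after emission."""
    s = ModelStructure(2, [[3, 3], [3, 3]], [0.5], [0.5])
    state = init_state(s)
    advance_state(state, [1, 0])           # spike at t=0
    assert not state.synaptic_trace[0].any()
    advance_state(state, [0, 0])           # t=1: still queued
    assert not state.synaptic_trace[0].any()
    advance_state(state, [0, 0])           # t=2: arrives -> trace before t=3
    assert state.synaptic_trace[0, 0, 0] == pytest.approx(1.0)
    assert state.synaptic_trace[0, 1, 0] == pytest.approx(1.0)
    advance_state(state, [0, 0])           # decays thereafter
    assert state.synaptic_trace[0, 0, 0] == pytest.approx(0.5)


class TestEnergy:
    def test_zero_parameters_zero_energy(self):
        structure, _, state, _ = random_instance(np.random.default_rng(0))
        params = Parameters.zeros(structure)
        for j in range(structure.n_neurons):
            assert energy_neuron(j, 0, state, params) == 0.0
            assert energy_neuron(j, 1, state, params) == 0.0

    def test_silent_neuron_has_zero_energy(self):
        structure, params, state, _ = random_instance(np.random.default_rng(1))
        for j in range(structure.n_neurons):
            assert energy_neuron(j, 0, state, params) == 0.0

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_term_by_term_oracle(self, seed):
        structure, params, state, hist = random_instance(np.random.default_rng(seed))
        for j in range(structure.n_neurons):
            assert energy_neuron(j, 1, state, params) == pytest.approx(
                energy_sum(j, 1, hist, params, structure), abs=1e-12)

    def test_total_is_sum_of_neuron_energies(self):
        rng = np.random.default_rng(5)
        structure, params, state, _ = random_instance(rng, n_neurons=4)
        x = fixtures.random_sequence(4, 1, 0.5, rng).values[0]
        total = sum(energy_neuron(j, int(x[j]), state, params) for j in range(4))
        assert energy_total(x, state, params) == pytest.approx(total, abs=1e-12)
        assert energy_total([0, 0, 0, 0], state, params) == 0.0

    def test_single_neuron_total_equals_neuron_energy(self):
        structure, params, state, _ = random_instance(np.random.default_rng(6), n_neurons=1)
        assert energy_total([1], state, params) == energy_neuron(0, 1, state, params)

    def test_energy_gap_independent_of_other_candidates(self):
        """E_j(1) - E_j(0) does not depend on what the other neurons are
        about to take at the same step (conditional independence)."""
        structure, params, state, _ = random_instance(np.random.default_rng(7), n_neurons=4)
        j = 2
        rng = np.random.default_rng(8)
        gaps = set()
        for _ in range(5):
            other = rng.integers(0, 2, 4)
            x1, x0 = other.copy(), other.copy()
            x1[j], x0[j] = 1, 0
            gaps.add(round(energy_total(x1, state, params)
                           - energy_total(x0, state, params), 12))
        assert len(gaps) == 1


class TestSpikeProbability:
    def test_zero_parameters_give_half(self):
        structure, _, state, _ = random_instance(np.random.default_rng(0))
        params = Parameters.zeros(structure)
        for j in range(structure.n_neurons):
            assert spike_probability(j, state, params, tau=1.0) == pytest.approx(0.5)

    def test_normalization(self):
        structure, params, state, _ = random_instance(np.random.default_rng(1))
        p = spike_probabilities(state, params, tau=0.7)
        assert np.all((0 <= p) & (p <= 1))
        np.testing.assert_allclose(p + (1 - p), 1.0, atol=1e-12)

    def test_unit_bias_gives_logistic_value(self):
        s = uniform_structure(1, 1)
        params = Parameters(np.array([1.0]), np.zeros((1, 1, 3)), np.zeros((1, 1, 3)))
        p = spike_probability(0, init_state(s), params, tau=1.0)
        assert p == pytest.approx(np.e / (1 + np.e), abs=1e-12)

    def test_extreme_energies_are_stable(self):
        s = uniform_structure(1, 1)
        for b, expect in ((1e4, 1.0), (-1e4, 0.0)):
            params = Parameters(np.array([b]), np.zeros((1, 1, 3)), np.zeros((1, 1, 3)))
            with np.errstate(over="raise"):
                p = spike_probability(0, init_state(s), params, tau=1.0)
            assert p == pytest.approx(expect)

    def test_rejects_nonpositive_temperature(self):
        structure, params, state, _ = random_instance(np.random.default_rng(2))
        for tau in (0.0, -1.0):
            with pytest.raises(ValueError):
                spike_probability(0, state, params, tau)


class TestLogLikelihood:
    def test_zero_parameters_seven_neurons(self):
        s = uniform_structure(7, 3)
        params = Parameters.zeros(s)
        state = init_state(s)
        x = np.array([1, 0, 1, 1, 0, 0, 1])
        assert log_likelihood_step(x, state, params) == pytest.approx(-7 * np.log(2))

    def test_decomposes_over_neurons(self):
        rng = np.random.default_rng(3)
        structure, params, state, _ = random_instance(rng, n_neurons=4)
        x = fixtures.random_sequence(4, 1, 0.5, rng).values[0]
        p = spike_probabilities(state, params, tau=1.0)
        expect = sum(np.log(p[j]) if x[j] else np.log(1 - p[j]) for j in range(4))
        assert log_likelihood_step(x, state, params) == pytest.approx(expect, abs=1e-12)

    def test_single_neuron_closed_form(self):
        s = uniform_structure(1, 1)
        params = Parameters(np.array([1.0]), np.zeros((1, 1, 3)), np.zeros((1, 1, 3)))
        ll = log_likelihood_step([1], init_state(s), params)
        assert ll == pytest.approx(np.log(np.e / (1 + np.e)))

    def test_rejects_non_binary(self):
        structure, params, state, _ = random_instance(np.random.default_rng(4))
        with pytest.raises(ValueError):
            log_likelihood_step([0.5, 0, 1], state, params)


class TestAdvance:
    def test_zero_history_is_a_fixed_point(self):
        state = init_state(fixtures.random_structure(3, rng=np.random.default_rng(0)))
        for _ in range(10):
            advance_state(state, [0, 0, 0])
        assert not state.synaptic_trace.any() and not state.neural_trace.any()
        assert not beta_tensor(state).any()
        assert state.clock == 10

    def test_value_semantics(self):
        structure, params, state, _ = random_instance(np.random.default_rng(1))
        snapshot = state.copy()
        spike_probabilities(state, params, tau=1.0)
        log_likelihood_step(np.zeros(3, dtype=int), state, params)
        energy_total(np.zeros(3, dtype=int), state, params)
        assert state == snapshot
        advance_state(state.copy(), [1, 1, 1])   # advancing a copy
        assert state == snapshot                  # ... leaves the original intact

    def test_rejects_bad_input(self):
        state = init_state(uniform_structure(2, 2))
        with pytest.raises(ValueError):
            advance_state(state, [1, 0, 1])
        with pytest.raises(ValueError):
            advance_state(state, [2, 0])


class TestGeneration:
    def test_zero_parameters_emit_nothing(self):
        # probability exactly 0.5 is not > 0.5: the tie emits 0
        structure = uniform_structure(3, 2)
        seq = generate_deterministic(init_state(structure), Parameters.zeros(structure), 8)
        assert not seq.values.any()

    def test_large_bias_emits_every_step(self):
        s = uniform_structure(2, 3)
        params = Parameters(np.array([10.0, -10.0]), np.zeros((2, 2, 3)), np.zeros((2, 2, 3)))
        seq = generate_deterministic(init_state(s), params, 6)
        assert seq.values[:, 0].all() and not seq.values[:, 1].any()

    def test_deterministic_replay(self):
        structure, params, state, _ = random_instance(np.random.default_rng(2))
        a = generate_deterministic(state.copy(), params, 25)
        b = generate_deterministic(state.copy(), params, 25)
        assert np.array_equal(a.values, b.values)


class TestSampling:
    def test_seeded_reproducibility(self):
        structure, params, state, _ = random_instance(np.random.default_rng(3))
        a = sample_step(state, params, 1.0, np.random.default_rng(42))
        b = sample_step(state, params, 1.0, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_frequencies_match_probabilities(self):
        s = uniform_structure(2, 1)
        params = Parameters(np.array([0.0, 1.0]), np.zeros((2, 2, 3)), np.zeros((2, 2, 3)))
        state = init_state(s)
        rng = np.random.default_rng(7)
        draws = np.array([sample_step(state, params, 1.0, rng) for _ in range(10_000)])
        freq = draws.mean(axis=0)
        assert freq[0] == pytest.approx(0.5, abs=0.02)
        p1 = np.e / (1 + np.e)
        se = np.sqrt(p1 * (1 - p1) / 10_000)
        assert abs(freq[1] - p1) < 3 * se


class TestPatternSequence:
    def test_rejects_non_binary_and_bad_period(self):
        with pytest.raises(ValueError):
            PatternSequence(np.array([[0, 2]]))
        with pytest.raises(ValueError):
            PatternSequence(np.zeros((5, 2), dtype=int), period=3)

    def test_period_divides_length(self):
        seq = PatternSequence(np.zeros((6, 2), dtype=int), period=3)
        assert seq.period == 3 and len(seq) == 6
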