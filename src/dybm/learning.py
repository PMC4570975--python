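"""Exact online learning rule: STDP-like gradient ascent with AdaGrad.

Presenting pattern ``x[t]`` yields the exact gradient of the one-step
conditional log-likelihood with respect to every learnable parameter, using
only quantities local to each neuron/synapse:

* bias:        ``x_j - <X_j>``                    (homeostatic: expectation-subtracted)
* LTP weight:  ``(x_j - <X_j>) * alpha[i, j, k]``
* LTD weight, in-transit component:  ``(<X_j> - x_j) * beta[i, j, l]``
* LTD weight, reverse component:     ``(<X_i> - x_i) * gamma[j, l]``

where ``<X_j>`` is the model's spike expectation at temperature 1.  The two
LTD components update the same weight ``v[i, j, l]`` sequentially, each with
its own AdaGrad accumulator.  Ascent with these gradients increases the
likelihood of the presented sequence without approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DynamicState,
    ModelStructure,
    Parameters,
    PatternSequence,
    advance_state,
    beta_tensor,
    generate_deterministic,
    init_state,
    log_likelihood_step,
    spike_probabilities,
    spike_probability,
)
from . import _kernels

__all__ = [
    "AdaGradState",
    "TrainingConfig",
    "GradientReport",
    "MemorizationResult",
    "AlternatingResult",
    "expectation",
    "compute_gradients",
    "apply_update",
    "train_step",
    "train_until_memorized",
    "train_alternating",
    "retrieve_with_cue",
]


@dataclass
class AdaGradState:
    """Per-parameter squared-gradient accumulators.

    The very first update of any scalar parameter uses the base rate ``eta_0``
    (its accumulator is still zero); thereafter the rate is
    ``eta_0 / sqrt(epsilon + sum of squared past gradients)``, where
    ``epsilon`` merely guards the division.  The two LTD gradient components
    keep independent accumulators.
    """

    accum_bias: np.ndarray
    accum_ltp: np.ndarray
    accum_ltd_a: np.ndarray
    accum_ltd_b: np.ndarray
    base_rate: float = 1.0
    epsilon: float = 1e-12

    @classmethod
    def zeros(cls, structure: ModelStructure, base_rate: float = 1.0,
              epsilon: float = 1e-12) -> "AdaGradState":
        n, k, l = structure.n_neurons, structure.n_synaptic_traces, structure.n_neural_traces
        return cls(np.zeros(n), np.zeros((n, n, k)), np.zeros((n, n, l)),
                   np.zeros((n, n, l)), base_rate, epsilon)

    def copy(self) -> "AdaGradState":
        return AdaGradState(self.accum_bias.copy(), self.accum_ltp.copy(),
                            self.accum_ltd_a.copy(), self.accum_ltd_b.copy(),
                            self.base_rate, self.epsilon)


@dataclass
class TrainingConfig:
    """Protocol knobs for the training loops.

    max_periods      — period budget per call to a training loop
    check_every      — periods between convergence / retrieval checks
    eval_horizon     — steps generated per convergence check (None: 2 periods)
    adagrad_epsilon  — division guard in the AdaGrad rate
    seed             — master seed recorded with results
    temperature_train — fixed at 1 during training
    """

    max_periods: int = 130_000
    check_every: int = 10
    eval_horizon: int | None = None
    adagrad_epsilon: float = 1e-12
    seed: int | None = None
    temperature_train: float = 1.0

    def __post_init__(self):
        if self.max_periods < 1:
            raise ValueError("max_periods must be >= 1")
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")
        if self.adagrad_epsilon < 0:
            raise ValueError("adagrad_epsilon must be >= 0")
        if self.temperature_train != 1.0:
            raise ValueError("training runs at temperature 1")


@dataclass
class GradientReport:
    """One-step log-likelihood gradient, split by parameter and LTD component."""

    d_bias: np.ndarray
    d_ltp: np.ndarray
    d_ltd_a: np.ndarray
    d_ltd_b: np.ndarray
    loglik: float


def expectation(j: int, state: DynamicState, params: Parameters) -> float:
    """Expected value of neuron ``j`` at the next step (temperature 1)."""
    return spike_probability(j, state, params, tau=1.0)


def compute_gradients(x_t, state: DynamicState, params: Parameters) -> GradientReport:
    """Exact gradient of ``log P(x_t | history)`` at temperature 1.

    ``state`` must be the pre-presentation state (traces and queues reflect
    the history strictly before ``x_t``); it is not modified.
    """
    n = state.structure.n_neurons
    x = np.asarray(x_t, dtype=np.float64)
    p = spike_probabilities(state, params, tau=1.0)
    e = x - p  # presented minus expected, per neuron
    beta = beta_tensor(state)
    d_bias = e
    d_ltp = e[None, :, None] * state.synaptic_trace       # (N,N,K), post index j
    d_ltd_a = -e[None, :, None] * beta                    # (N,N,L), post index j
    d_ltd_b = -e[:, None, None] * state.neural_trace[None, :, :]  # pre index i
    ll = log_likelihood_step(x_t, state, params, tau=1.0)
    return GradientReport(d_bias, d_ltp, d_ltd_a, d_ltd_b, ll)


def apply_update(params: Parameters, grads: GradientReport,
                 ada: AdaGradState | None, rate: float | None = None) -> None:
    """Ascend along ``grads``, in place.

    With ``ada`` given, each scalar uses its own AdaGrad rate and the
    accumulators absorb the squared gradients; the two LTD components are
    applied sequentially with independent rates.  With ``ada=None`` a plain
    fixed ``rate`` is used (no accumulation).
    """
    if ada is None:
        if rate is None:
            raise ValueError("provide either an AdaGradState or a fixed rate")
        params.bias += rate * grads.d_bias
        params.ltp_weight += rate * grads.d_ltp
        params.ltd_weight += rate * (grads.d_ltd_a + grads.d_ltd_b)
        return

    def _step(target: np.ndarray, grad: np.ndarray, acc: np.ndarray) -> None:
        # accumulate first: the rate divides by all squared gradients seen so
        # far *including* the current one, which bounds every step by eta_0;
        # a scalar's very first update uses the base rate itself
        first = acc == 0.0
        acc += grad ** 2
        rate = np.where(first, ada.base_rate,
                        ada.base_rate / np.sqrt(ada.epsilon + acc))
        target += rate * grad

    _step(params.bias, grads.d_bias, ada.accum_bias)
    _step(params.ltp_weight, grads.d_ltp, ada.accum_ltp)
    _step(params.ltd_weight, grads.d_ltd_a, ada.accum_ltd_a)
    _step(params.ltd_weight, grads.d_ltd_b, ada.accum_ltd_b)


def train_step(x_t, state: DynamicState, params: Parameters,
               ada: AdaGradState | None, rate: float | None = None):
    """One online step: gradients from the pre-update parameters and
    pre-advance state, parameter update, then state advance with ``x_t``.

    Returns ``(params, ada, state, loglik)`` where ``loglik`` is the step
    log-likelihood evaluated before the update (monitoring signal).
    """
    grads = compute_gradients(x_t, state, params)
    apply_update(params, grads, ada, rate)
    advance_state(state, x_t)
    return params, ada, state, grads.loglik


# ---------------------------------------------------------------------------
# training protocols


@dataclass
class MemorizationResult:
    params: Parameters
    state: DynamicState
    ada: AdaGradState
    periods_used: int
    converged: bool
    loglik_per_period: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class AlternatingResult:
    params: Parameters
    state: DynamicState
    ada: AdaGradState
    periods_per_iteration: list
    iterations_used: int
    converged: bool


def _init_params(structure: ModelStructure, rng: np.random.Generator,
                 mean: float = 0.0, sd: float = 0.1) -> Parameters:
    n, k, l = structure.n_neurons, structure.n_synaptic_traces, structure.n_neural_traces
    return Parameters(rng.normal(mean, sd, n),
                      rng.normal(mean, sd, (n, n, k)),
                      rng.normal(mean, sd, (n, n, l)))


def _train_periods_fast(seq: np.ndarray, n_periods: int, phase: int,
                        params: Parameters, state: DynamicState,
                        ada: AdaGradState) -> np.ndarray:
    """Run ``n_periods`` full presentations of ``seq`` starting at column
    ``phase``, updating everything in place; returns per-period log-likelihood."""
    s = state.structure
    ll = _kernels.train_steps(
        seq, phase, n_periods,
        params.bias, params.ltp_weight, params.ltd_weight,
        state.synaptic_trace, state.neural_trace,
        state.history, np.int64(state.history_pos),
        ada.accum_bias, ada.accum_ltp, ada.accum_ltd_a, ada.accum_ltd_b,
        s.delays, s.synaptic_decay, s.neural_decay,
        ada.base_rate, ada.epsilon,
    )
    steps = n_periods * seq.shape[0]
    state.history_pos = (state.history_pos + steps) % s.history_depth
    state.clock += steps
    return ll


def _generate_fast(state: DynamicState, params: Parameters, n_steps: int) -> np.ndarray:
    """Deterministic closed-loop generation on a throwaway copy of ``state``."""
    s = state.structure
    st = state.copy()
    out = np.empty((n_steps, s.n_neurons), dtype=np.uint8)
    _kernels.generate_steps(
        out, params.bias, params.ltp_weight, params.ltd_weight,
        st.synaptic_trace, st.neural_trace, st.history, np.int64(st.history_pos),
        s.delays, s.synaptic_decay, s.neural_decay,
    )
    return out


def _memorized(target: PatternSequence, state: DynamicState, params: Parameters,
               horizon: int | None) -> bool:
    """Does closed-loop generation from a copy of the live state reproduce the
    target, aligned to the phase following the last presented column?"""
    p = target.period
    h = 2 * p if horizon is None else horizon
    gen = _generate_fast(state, params, h)
    phase = state.clock % p
    want = target.values[(phase + np.arange(h)) % p]
    return np.array_equal(gen, want)


def train_until_memorized(target: PatternSequence, structure: ModelStructure,
                          config: TrainingConfig, rng: np.random.Generator,
                          params: Parameters | None = None,
                          state: DynamicState | None = None,
                          ada: AdaGradState | None = None) -> MemorizationResult:
    """Online training on a periodic target until closed-loop generation
    reproduces it bit-for-bit.

    One training period presents one period of the target.  Every
    ``config.check_every`` periods the live state is cloned and two periods
    are generated deterministically; convergence means an exact match with
    the correspondingly phased target.  Budget exhaustion returns
    ``converged=False`` rather than raising.
    """
    if target.period is None:
        raise ValueError("target must declare a period")
    if params is None:
        params = _init_params(structure, rng)
    params.check_compatible(structure)
    if state is None:
        state = init_state(structure)
    if ada is None:
        ada = AdaGradState.zeros(structure, epsilon=config.adagrad_epsilon)

    seq = target.values[: target.period].astype(np.float64)
    ll_chunks = []
    periods = 0
    converged = _memorized(target, state, params, config.eval_horizon)
    while not converged and periods < config.max_periods:
        block = min(config.check_every, config.max_periods - periods)
        phase = state.clock % target.period
        ll_chunks.append(_train_periods_fast(seq, block, phase, params, state, ada))
        periods += block
        converged = _memorized(target, state, params, config.eval_horizon)
    ll = np.concatenate(ll_chunks) if ll_chunks else np.empty(0)
    return MemorizationResult(params, state, ada, periods, converged, ll)


def retrieve_with_cue(params: Parameters, structure: ModelStructure,
                      cue: PatternSequence, n_steps: int) -> PatternSequence:
    """Associative retrieval: zero the dynamic state, present the cue without
    learning, then generate ``n_steps`` deterministically; returns the
    generated continuation only."""
    if len(cue) == 0:
        raise ValueError("cue must be non-empty")
    state = init_state(structure)
    for t in range(len(cue)):
        advance_state(state, cue.values[t])
    return PatternSequence(_generate_fast(state, params, n_steps))


def _retrieves(params: Parameters, structure: ModelStructure,
               seq: PatternSequence, cue: PatternSequence) -> bool:
    """Exact bit match over one full period following the cue."""
    p = seq.period if seq.period is not None else len(seq)
    got = retrieve_with_cue(params, structure, cue, p)
    want = seq.values[(len(cue) + np.arange(p)) % p]
    return np.array_equal(got.values, want)


def train_alternating(seq_a: PatternSequence, seq_b: PatternSequence,
                      cue_a: PatternSequence, cue_b: PatternSequence,
                      structure: ModelStructure, config: TrainingConfig,
                      rng: np.random.Generator,
                      max_iterations: int = 10_000,
                      params: Parameters | None = None,
                      state: DynamicState | None = None,
                      ada: AdaGradState | None = None,
                      periods_so_far: list | None = None,
                      on_iteration=None) -> AlternatingResult:
    """Dual-sequence training: sequence A in odd iterations, B in even ones.

    Each iteration is a fresh training session: the dynamic state starts
    blank (parameters and optimiser accumulators persist) and the scheduled
    sequence is presented repeatedly until the matching cue, presented after
    a state reset, retrieves one exact period of that sequence; the
    per-iteration period counts trace the relearning-speed curve.  The run
    terminates when, at the end of an iteration, *both* cues retrieve their
    sequences — the model has learned one without losing the other — or on
    the iteration budget.
    """
    if seq_a.n_neurons != seq_b.n_neurons:
        raise ValueError("sequences must share the neuron count")
    if len(cue_a) == 0 or len(cue_b) == 0:
        raise ValueError("cues must be non-empty")
    if params is None:
        params = _init_params(structure, rng)
    if state is None:
        state = init_state(structure)
    if ada is None:
        ada = AdaGradState.zeros(structure, epsilon=config.adagrad_epsilon)

    periods_per_iteration = list(periods_so_far) if periods_so_far else []
    converged = False
    iteration = len(periods_per_iteration)  # resume after completed iterations
    while iteration < max_iterations and not converged:
        iteration += 1
        seq, cue = (seq_a, cue_a) if iteration % 2 == 1 else (seq_b, cue_b)
        state = init_state(structure)  # blank interlude between sessions
        p = seq.period if seq.period is not None else len(seq)
        block = seq.values[:p].astype(np.float64)
        periods = 0
        while not _retrieves(params, structure, seq, cue):
            if periods >= config.max_periods:
                return AlternatingResult(params, state, ada, periods_per_iteration,
                                         iteration, False)
            n = min(config.check_every, config.max_periods - periods)
            phase = state.clock % p
            _train_periods_fast(block, n, phase, params, state, ada)
            periods += n
        periods_per_iteration.append(periods)
        converged = (_retrieves(params, structure, seq_a, cue_a)
                     and _retrieves(params, structure, seq_b, cue_b))
        if on_iteration is not None:
            on_iteration(iteration, periods, params, state, ada,
                         periods_per_iteration, converged)
    return AlternatingResult(params, state, ada, periods_per_iteration,
                             iteration, converged)
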