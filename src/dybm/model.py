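"""Core model: architecture, dynamic state, energy, and spike probabilities.

A dynamic Boltzmann machine (DyBM) is a network of ``N`` binary stochastic
neurons in discrete time.  A spike emitted by pre-synaptic neuron ``i`` reaches
post-synaptic neuron ``j`` only after a fixed integer conduction delay
``d[i, j] >= 1``, realised as a FIFO queue of length ``d[i, j] - 1``.  Each
neuron and each synapse additionally aggregates its past through exponentially
decaying eligibility traces, so the conditional distribution of the next
pattern depends on the whole history only through a bounded set of summary
variables.

Conventions used throughout (state "at clock t" summarises the history
``x[0], ..., x[t-1]`` and is the state in force when pattern ``x[t]`` is
scored or generated):

* neural trace      ``gamma[j, l] = sum_{s<t} mu_l**(t - s) * x[s, j]``
* synaptic trace    ``alpha[i, j, k] = sum_{s<=t-d} lambda_k**(t - s - d) * x[s, i]``
  with ``d = d[i, j]``; only spikes that have already traversed the queue
  contribute, and the most recently arrived spike carries weight 1
* queue ``(i, j)`` holds ``x[t-1, i]`` (tail) through ``x[t-d+1, i]`` (head)
* in-transit summary ``beta[i, j, l] = sum_{lag=1}^{d-1} mu_l**(d - lag) * x[t-lag, i]``,
  so spikes closer to the queue head (older, about to arrive) weigh more

The energy of neuron ``j`` for candidate value ``x_j`` is

    E_j(x_j) = -x_j * ( b_j
                        + sum_{i,k} u[i,j,k] * alpha[i,j,k]
                        - sum_{i,l} v[i,j,l] * beta[i,j,l]
                        - sum_{i,l} v[j,i,l] * gamma[i,l] )

where ``b`` is the bias, ``u`` the LTP weight (potentiation: arrived spikes
promote firing) and ``v`` the LTD weight, which depresses firing both through
spikes still in transit toward ``j`` (third term) and, with pre/post roles
swapped, through the recent activity of the neurons that ``j`` projects to
(fourth term).  Given the history, neurons are conditionally independent and
spike with probability ``sigmoid((E_j(0) - E_j(1)) / tau)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "ModelStructure",
    "Parameters",
    "DynamicState",
    "PatternSequence",
    "init_state",
    "compute_beta",
    "beta_tensor",
    "activation",
    "energy_neuron",
    "energy_total",
    "spike_probability",
    "spike_probabilities",
    "log_likelihood_step",
    "advance_state",
    "generate_deterministic",
    "sample_step",
]


def _binary_vector(x, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (n,):
        raise ValueError(f"expected a length-{n} vector, got shape {x.shape}")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("pattern entries must be 0 or 1")
    return x.astype(np.float64)


@dataclass(frozen=True, eq=False)
class ModelStructure:
    """Immutable architecture: neuron count, delays, decay rates, temperature.

    Parameters
    ----------
    n_neurons : int
        Number of binary neurons ``N``.
    delays : (N, N) int array
        Conduction delay ``d[i, j] >= 1`` from pre-synaptic ``i`` to
        post-synaptic ``j``; self-connections are ordinary synapses.
    synaptic_decay : (K,) float array
        Decay rates ``lambda_k`` in ``[0, 1)`` of the synaptic traces.
    neural_decay : (L,) float array
        Decay rates ``mu_l`` in ``[0, 1)`` of the neural traces; the same
        rates weight the in-transit (queue) summaries.
    temperature : float
        Default temperature ``tau >= 0``; 0 denotes the deterministic limit.
    """

    n_neurons: int
    delays: np.ndarray
    synaptic_decay: np.ndarray
    neural_decay: np.ndarray
    temperature: float = 1.0

    def __post_init__(self):
        n = int(self.n_neurons)
        if n < 1:
            raise ValueError("n_neurons must be >= 1")
        delays = np.asarray(self.delays, dtype=np.int64)
        if delays.shape != (n, n):
            raise ValueError(f"delays must have shape ({n}, {n})")
        if (delays < 1).any():
            raise ValueError("all conduction delays must be >= 1")
        lam = np.asarray(self.synaptic_decay, dtype=np.float64)
        mu = np.asarray(self.neural_decay, dtype=np.float64)
        for name, rates in (("synaptic_decay", lam), ("neural_decay", mu)):
            if rates.ndim != 1 or rates.size < 1:
                raise ValueError(f"{name} must be a non-empty 1-d sequence")
            if ((rates < 0) | (rates >= 1)).any():
                raise ValueError(f"{name} rates must lie in [0, 1)")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        for arr in (delays, lam, mu):
            arr.flags.writeable = False
        object.__setattr__(self, "n_neurons", n)
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "synaptic_decay", lam)
        object.__setattr__(self, "neural_decay", mu)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelStructure):
            return NotImplemented
        return (
            self.n_neurons == other.n_neurons
            and self.temperature == other.temperature
            and np.array_equal(self.delays, other.delays)
            and np.array_equal(self.synaptic_decay, other.synaptic_decay)
            and np.array_equal(self.neural_decay, other.neural_decay)
        )

    __hash__ = None

    @property
    def n_synaptic_traces(self) -> int:
        return self.synaptic_decay.size

    @property
    def n_neural_traces(self) -> int:
        return self.neural_decay.size

    @property
    def max_delay(self) -> int:
        return int(self.delays.max())

    @cached_property
    def history_depth(self) -> int:
        """Rows of past input kept in the state's ring buffer (>= 1)."""
        return max(1, self.max_delay - 1)

    @cached_property
    def queue_weight(self) -> np.ndarray:
        """(R, N, N, L) tensor W[r, i, j, l] = mu_l**(d[i,j] - (r+1)) for
        lag r+1 < d[i,j], else 0 — contracting it with the lag-ordered input
        history yields the beta tensor in one step."""
        r_max = self.history_depth
        d = self.delays[None, :, :, None]
        lag = (np.arange(r_max) + 1)[:, None, None, None]
        mu = self.neural_decay[None, None, None, :]
        with np.errstate(divide="ignore"):
            w = np.where(lag < d, mu ** np.maximum(d - lag, 0), 0.0)
        w.flags.writeable = False
        return w


@dataclass
class Parameters:
    """Learnable parameters: bias ``b`` (N,), LTP weight ``u`` (N, N, K),
    LTD weight ``v`` (N, N, L)."""

    bias: np.ndarray
    ltp_weight: np.ndarray
    ltd_weight: np.ndarray

    def __post_init__(self):
        self.bias = np.asarray(self.bias, dtype=np.float64)
        self.ltp_weight = np.asarray(self.ltp_weight, dtype=np.float64)
        self.ltd_weight = np.asarray(self.ltd_weight, dtype=np.float64)
        n = self.bias.shape[0]
        if self.bias.ndim != 1:
            raise ValueError("bias must be a vector")
        if self.ltp_weight.ndim != 3 or self.ltp_weight.shape[:2] != (n, n):
            raise ValueError("ltp_weight must have shape (N, N, K)")
        if self.ltd_weight.ndim != 3 or self.ltd_weight.shape[:2] != (n, n):
            raise ValueError("ltd_weight must have shape (N, N, L)")
        for arr in (self.bias, self.ltp_weight, self.ltd_weight):
            if not np.isfinite(arr).all():
                raise ValueError("parameters must be finite")

    @classmethod
    def zeros(cls, structure: ModelStructure) -> "Parameters":
        n, k, l = structure.n_neurons, structure.n_synaptic_traces, structure.n_neural_traces
        return cls(np.zeros(n), np.zeros((n, n, k)), np.zeros((n, n, l)))

    def copy(self) -> "Parameters":
        return Parameters(self.bias.copy(), self.ltp_weight.copy(), self.ltd_weight.copy())

    def check_compatible(self, structure: ModelStructure) -> None:
        n, k, l = structure.n_neurons, structure.n_synaptic_traces, structure.n_neural_traces
        if self.bias.shape != (n,) or self.ltp_weight.shape != (n, n, k) \
                or self.ltd_weight.shape != (n, n, l):
            raise ValueError("parameter shapes inconsistent with model structure")


@dataclass
class DynamicState:
    """Value-semantic dynamic state: FIFO queues plus eligibility traces.

    The queues for all synapses are backed by one shared ring buffer of the
    last ``structure.history_depth`` presented patterns; queue ``(i, j)``
    is the view of neuron ``i``'s column at lags ``1 .. d[i,j]-1``.
    """

    structure: ModelStructure
    synaptic_trace: np.ndarray  # alpha, (N, N, K)
    neural_trace: np.ndarray    # gamma, (N, L)
    history: np.ndarray         # ring buffer, (R, N)
    history_pos: int            # row index of the most recent pattern
    clock: int = 0

    def copy(self) -> "DynamicState":
        return DynamicState(
            self.structure,
            self.synaptic_trace.copy(),
            self.neural_trace.copy(),
            self.history.copy(),
            self.history_pos,
            self.clock,
        )

    def past_matrix(self) -> np.ndarray:
        """(R, N) matrix whose row ``r`` is the pattern presented ``r + 1``
        steps ago (zeros for steps before the initial state)."""
        r_max = self.structure.history_depth
        idx = (self.history_pos - np.arange(r_max)) % r_max
        return self.history[idx]

    def queue(self, i: int, j: int) -> np.ndarray:
        """Contents of the FIFO queue from ``i`` to ``j``, ordered tail
        (most recent) to head (about to arrive); length ``d[i,j] - 1``."""
        d = int(self.structure.delays[i, j])
        return self.past_matrix()[: d - 1, i].copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, DynamicState):
            return NotImplemented
        return (
            self.structure == other.structure
            and self.clock == other.clock
            and np.array_equal(self.synaptic_trace, other.synaptic_trace)
            and np.array_equal(self.neural_trace, other.neural_trace)
            and np.array_equal(self.past_matrix(), other.past_matrix())
        )


@dataclass
class PatternSequence:
    """A T x N binary pattern sequence, optionally periodic with period p."""

    values: np.ndarray
    period: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("sequence entries must be 0 or 1")
        self.values = v.astype(np.uint8)
        if self.period is not None:
            p = int(self.period)
            if p < 1:
                raise ValueError("period must be a positive integer")
            if len(self) % p != 0:
                raise ValueError("sequence length must be a multiple of its period")
            self.period = p

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PatternSequence):
            return NotImplemented
        return np.array_equal(self.values, other.values) and self.period == other.period


def init_state(structure: ModelStructure) -> DynamicState:
    """Blank state: zero traces, zero-filled queues, clock 0 — equivalent to
    having presented all-zero patterns for arbitrarily long."""
    n = structure.n_neurons
    return DynamicState(
        structure,
        np.zeros((n, n, structure.n_synaptic_traces)),
        np.zeros((n, structure.n_neural_traces)),
        np.zeros((structure.history_depth, n)),
        history_pos=0,
        clock=0,
    )


def beta_tensor(state: DynamicState) -> np.ndarray:
    """(N, N, L) in-transit summaries of all queues at the current clock."""
    w = state.structure.queue_weight  # (R, N, N, L)
    past = state.past_matrix()        # (R, N)
    return np.einsum("rijl,ri->ijl", w, past)


def compute_beta(state: DynamicState, i: int, j: int, l: int) -> float:
    """Weighted count of spikes still inside queue ``(i, j)``: a spike
    presented ``lag`` steps ago contributes ``mu_l**(d[i,j] - lag)``, so
    head-proximal spikes weigh more; exactly 0 for a spike-free queue."""
    s = state.structure
    n = s.n_neurons
    if not (0 <= i < n and 0 <= j < n and 0 <= l < s.n_neural_traces):
        raise IndexError("neuron or trace index out of range")
    d = int(s.delays[i, j])
    mu = s.neural_decay[l]
    q = state.queue(i, j)  # tail -> head, lags 1..d-1
    return float(sum(mu ** (d - lag) * q[lag - 1] for lag in range(1, d)))


def activation(state: DynamicState, params: Parameters) -> np.ndarray:
    """Per-neuron activation ``a_j = E_j(0) - E_j(1)``; the spike
    probability is ``sigmoid(a / tau)``."""
    params.check_compatible(state.structure)
    beta = beta_tensor(state)
    a = params.bias.copy()
    a += np.einsum("ijk,ijk->j", params.ltp_weight, state.synaptic_trace)
    a -= np.einsum("ijl,ijl->j", params.ltd_weight, beta)
    a -= np.einsum("jil,il->j", params.ltd_weight, state.neural_trace)
    return a


def energy_neuron(j: int, x_j: int, state: DynamicState, params: Parameters) -> float:
    """Energy contribution of neuron ``j`` taking value ``x_j``; every term
    carries the factor ``x_j``, so the energy of staying silent is 0."""
    if x_j not in (0, 1):
        raise ValueError("x_j must be 0 or 1")
    if not 0 <= j < state.structure.n_neurons:
        raise IndexError("neuron index out of range")
    return float(-x_j * activation(state, params)[j])


def energy_total(x, state: DynamicState, params: Parameters) -> float:
    """Total energy of candidate pattern ``x``: the sum of per-neuron terms."""
    xv = _binary_vector(x, state.structure.n_neurons)
    return float(-(xv @ activation(state, params)))


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if tau <= 0:
        raise ValueError("temperature must be > 0 (the deterministic limit is "
                         "handled by generate_deterministic)")
    return tau


def spike_probabilities(state: DynamicState, params: Parameters, tau: float) -> np.ndarray:
    """Vector of P(x_j = 1 | history) for all neurons, computed through the
    logistic of the energy difference (stable for |E|/tau up to ~1e4)."""
    tau = _check_tau(tau)
    return expit(activation(state, params) / tau)


def spike_probability(j: int, state: DynamicState, params: Parameters, tau: float) -> float:
    if not 0 <= j < state.structure.n_neurons:
        raise IndexError("neuron index out of range")
    return float(spike_probabilities(state, params, tau)[j])


def log_likelihood_step(x_t, state: DynamicState, params: Parameters, tau: float = 1.0) -> float:
    """Log-probability of the pattern ``x_t`` given the history summarised in
    ``state``; the state is not advanced.  Always <= 0."""
    tau = _check_tau(tau)
    xv = _binary_vector(x_t, state.structure.n_neurons)
    z = activation(state, params) / tau
    # log sigmoid(z) where x=1, log sigmoid(-z) where x=0
    return float(np.sum(np.where(xv == 1.0, log_expit(z), log_expit(-z))))


def advance_state(state: DynamicState, x_t) -> DynamicState:
    """Present pattern ``x_t``: pop each queue head into its synaptic trace,
    decay the traces, push ``x_t``, and increment the clock.

    The recursions are ``alpha <- lambda_k * alpha + arriving`` (the arriving
    value is the queue head, i.e. ``x_t`` itself when ``d = 1``) and
    ``gamma <- mu_l * (gamma + x_t)``; after any history they reproduce the
    defining weighted sums exactly.  The state is mutated in place and
    returned.
    """
    s = state.structure
    xv = _binary_vector(x_t, s.n_neurons)
    past = state.past_matrix()  # lag-ordered view of the pre-advance history
    lag = s.delays - 1          # (N, N); arriving value has this lag
    row = np.where(lag > 0, lag - 1, 0)
    arriving = np.where(lag == 0, xv[:, None],
                        past[row, np.arange(s.n_neurons)[:, None]])
    state.synaptic_trace *= s.synaptic_decay
    state.synaptic_trace += arriving[:, :, None]
    state.neural_trace += xv[:, None]
    state.neural_trace *= s.neural_decay
    state.history_pos = (state.history_pos + 1) % s.history_depth
    state.history[state.history_pos] = xv
    state.clock += 1
    return state


def generate_deterministic(state: DynamicState, params: Parameters, n_steps: int) -> PatternSequence:
    """Closed-loop deterministic generation in the zero-temperature limit.

    At each step neuron ``j`` spikes iff its spike probability exceeds 0.5
    strictly (a tie emits 0); the emitted pattern then advances the state, so
    generation continues the dynamics that the state encodes.  The passed
    state is advanced through all ``n_steps``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    n = state.structure.n_neurons
    out = np.empty((n_steps, n), dtype=np.uint8)
    for t in range(n_steps):
        x = (activation(state, params) > 0.0).astype(np.uint8)
        out[t] = x
        advance_state(state, x)
    return PatternSequence(out)


def sample_step(state: DynamicState, params: Parameters, tau: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw one pattern at temperature ``tau``; neurons are conditionally
    independent given the history.  The state is *not* advanced."""
    p = spike_probabilities(state, params, tau)
    return (rng.random(p.shape) < p).astype(np.uint8)
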