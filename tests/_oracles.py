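"""Independent oracles: literal transcriptions of the defining sums and a
finite-difference gradient, kept free of the package's recursions so they can
arbitrate them."""

import numpy as np

from dybm.model import log_likelihood_step


def gamma_sum(history: np.ndarray, mu: float, j: int) -> float:
    """Neural trace as its defining weighted sum: weight mu**(t-s) for the
    spike at step s, with t = len(history)."""
    t = history.shape[0]
    return float(sum(mu ** (t - s) * history[s, j] for s in range(t)))


def alpha_sum(history: np.ndarray, lam: float, d: int, i: int) -> float:
    """Synaptic trace: spikes that have traversed the length-(d-1) queue,
    weight lam**(t-s-d); the most recent arrival carries weight 1."""
    t = history.shape[0]
    return float(sum(lam ** (t - s - d) * history[s, i] for s in range(t - d + 1)))


def beta_sum(history: np.ndarray, mu: float, d: int, i: int) -> float:
    """In-transit queue summary: spike at lag g (1 <= g < d) weighs
    mu**(d-g), so head-proximal (older) spikes weigh more."""
    t = history.shape[0]
    return float(sum(mu ** (d - g) * history[t - g, i]
                     for g in range(1, d) if t - g >= 0))


def energy_sum(j: int, x_j: int, history: np.ndarray, params, structure) -> float:
    """Term-by-term energy of neuron j: bias, LTP (arrived spikes), LTD
    (queued spikes), and reverse-direction LTD (recent activity of the
    neurons j projects to), each computed from the raw history."""
    lam = structure.synaptic_decay
    mu = structure.neural_decay
    d = structure.delays
    n = structure.n_neurons
    e = -params.bias[j] * x_j
    for i in range(n):
        for k in range(lam.size):
            e -= params.ltp_weight[i, j, k] * alpha_sum(history, lam[k], d[i, j], i) * x_j
        for l in range(mu.size):
            e += params.ltd_weight[i, j, l] * beta_sum(history, mu[l], d[i, j], i) * x_j
            e += params.ltd_weight[j, i, l] * gamma_sum(history, mu[l], i) * x_j
    return float(e)


def fd_gradients(x_t, state, params, h: float = 1e-5):
    """Central finite differences of the one-step log-likelihood with respect
    to every learnable scalar; LTD components are reported combined (both act
    on the same weight)."""
    def ll_of(p):
        return log_likelihood_step(x_t, state, p, tau=1.0)

    out = {}
    for name in ("bias", "ltp_weight", "ltd_weight"):
        arr = getattr(params, name)
        grad = np.empty_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            p2 = params.copy()
            getattr(p2, name)[idx] += h
            up = ll_of(p2)
            getattr(p2, name)[idx] -= 2 * h
            dn = ll_of(p2)
            grad[idx] = (up - dn) / (2 * h)
        out[name] = grad
    return out
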