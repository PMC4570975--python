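"""Compiled inner loops for training and closed-loop generation.

These kernels implement exactly the same recursions as the reference
functions in :mod:`dybm.model` / :mod:`dybm.learning` (the tests assert
numerical agreement); they exist because the online protocols present
millions of individual patterns, which is dominated by per-step dispatch
overhead in pure numpy.

Shared conventions: ``hist`` is a ring buffer of the last ``R`` presented
patterns with row ``pos`` the most recent, so the pattern presented ``g``
steps ago is ``hist[(pos - (g - 1)) % R]``.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _activation(b, u, v, alpha, gamma, hist, pos, delays, mu, beta_out, a_out):
    """Fill ``beta_out`` (N,N,L) with the queue summaries and ``a_out`` (N,)
    with the activations a_j = E_j(0) - E_j(1)."""
    n = b.shape[0]
    n_k = u.shape[2]
    n_l = v.shape[2]
    r_max = hist.shape[0]
    for i in range(n):
        for j in range(n):
            d = delays[i, j]
            for l in range(n_l):
                beta_out[i, j, l] = 0.0
            for g in range(1, d):
                xv = hist[(pos - (g - 1)) % r_max, i]
                if xv != 0.0:
                    for l in range(n_l):
                        beta_out[i, j, l] += mu[l] ** (d - g) * xv
    for j in range(n):
        s = b[j]
        for i in range(n):
            for k in range(n_k):
                s += u[i, j, k] * alpha[i, j, k]
            for l in range(n_l):
                s -= v[i, j, l] * beta_out[i, j, l] + v[j, i, l] * gamma[i, l]
        a_out[j] = s


@njit(cache=True)
def _advance(x, alpha, gamma, hist, pos, delays, lam, mu):
    """Present pattern ``x``: alpha <- lam*alpha + arriving (queue head),
    gamma <- mu*(gamma + x), push ``x``; returns the new ring position."""
    n = x.shape[0]
    n_k = alpha.shape[2]
    n_l = gamma.shape[1]
    r_max = hist.shape[0]
    for i in range(n):
        for j in range(n):
            d = delays[i, j]
            if d == 1:
                arr = x[i]
            else:
                arr = hist[(pos - (d - 2)) % r_max, i]
            for k in range(n_k):
                alpha[i, j, k] = lam[k] * alpha[i, j, k] + arr
    for j in range(n):
        for l in range(n_l):
            gamma[j, l] = mu[l] * (gamma[j, l] + x[j])
    pos = (pos + 1) % r_max
    for j in range(n):
        hist[pos, j] = x[j]
    return pos


@njit(cache=True)
def _log_sigmoid(z):
    if z > 0.0:
        return -np.log1p(np.exp(-z))
    return z - np.log1p(np.exp(z))


@njit(cache=True)
def train_steps(seq, phase, n_periods, b, u, v, alpha, gamma, hist, pos,
                acc_b, acc_u, acc_va, acc_vb, delays, lam, mu, eta0, eps):
    """Present ``n_periods`` full periods of ``seq`` starting at column
    ``phase``, applying the exact online gradient update with per-parameter
    AdaGrad after every pattern; all model/optimiser arrays are updated in
    place.  Returns the summed log-likelihood of each period."""
    p, n = seq.shape
    n_k = u.shape[2]
    n_l = v.shape[2]
    beta = np.empty((n, n, n_l))
    a = np.empty(n)
    prob = np.empty(n)
    ll = np.zeros(n_periods)
    for per in range(n_periods):
        for c in range(p):
            x = seq[(phase + per * p + c) % p]
            _activation(b, u, v, alpha, gamma, hist, pos, delays, mu, beta, a)
            step_ll = 0.0
            for j in range(n):
                z = a[j]
                if z >= 0.0:
                    prob[j] = 1.0 / (1.0 + np.exp(-z))
                else:
                    ez = np.exp(z)
                    prob[j] = ez / (1.0 + ez)
                if x[j] == 1.0:
                    step_ll += _log_sigmoid(z)
                else:
                    step_ll += _log_sigmoid(-z)
            ll[per] += step_ll
            # exact gradient ascent; the first update of a scalar uses eta0
            for j in range(n):
                e = x[j] - prob[j]
                first = acc_b[j] <= 0.0
                acc_b[j] += e * e
                r = eta0 if first else eta0 / np.sqrt(eps + acc_b[j])
                b[j] += r * e
            for i in range(n):
                ei = x[i] - prob[i]
                for j in range(n):
                    ej = x[j] - prob[j]
                    for k in range(n_k):
                        g = ej * alpha[i, j, k]
                        first = acc_u[i, j, k] <= 0.0
                        acc_u[i, j, k] += g * g
                        r = eta0 if first else eta0 / np.sqrt(eps + acc_u[i, j, k])
                        u[i, j, k] += r * g
                    for l in range(n_l):
                        ga = -ej * beta[i, j, l]
                        first = acc_va[i, j, l] <= 0.0
                        acc_va[i, j, l] += ga * ga
                        r = eta0 if first else eta0 / np.sqrt(eps + acc_va[i, j, l])
                        v[i, j, l] += r * ga
                        gb = -ei * gamma[j, l]
                        first = acc_vb[i, j, l] <= 0.0
                        acc_vb[i, j, l] += gb * gb
                        r = eta0 if first else eta0 / np.sqrt(eps + acc_vb[i, j, l])
                        v[i, j, l] += r * gb
            pos = _advance(x, alpha, gamma, hist, pos, delays, lam, mu)
    return ll


@njit(cache=True)
def generate_steps(out, b, u, v, alpha, gamma, hist, pos, delays, lam, mu):
    """Deterministic closed-loop generation: spike iff the activation is
    strictly positive (spike probability > 0.5); writes into ``out`` and
    advances the passed state arrays in place."""
    n_steps, n = out.shape
    n_l = v.shape[2]
    beta = np.empty((n, n, n_l))
    a = np.empty(n)
    x = np.empty(n)
    for t in range(n_steps):
        _activation(b, u, v, alpha, gamma, hist, pos, delays, mu, beta, a)
        for j in range(n):
            if a[j] > 0.0:
                x[j] = 1.0
                out[t, j] = 1
            else:
                x[j] = 0.0
                out[t, j] = 0
        pos = _advance(x, alpha, gamma, hist, pos, delays, lam, mu)
    return pos
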