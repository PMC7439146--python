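"""Numba-compiled inner loops for the HMM recursions.

The forward-backward pass uses Rabiner-style per-step scaling so that a
series of 10^5 minutes stays in the linear domain without underflow; the
emission matrix is pre-scaled by its per-minute maximum outside these
kernels and the removed offsets are added back to the log likelihood by
the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward", "forward_loglik", "viterbi_path"]


@njit(cache=True)
def forward_backward(pi, A, b):
    """Scaled forward-backward pass.

    Parameters
    ----------
    pi : (K,) initial distribution.
    A : (K, K) transition matrix, rows summing to 1.
    b : (T, K) emission likelihoods scaled so each row's maximum is 1.

    Returns
    -------
    ll : log likelihood *excluding* the row-scaling offsets of ``b``.
    gamma : (T, K) posterior state probabilities.
    xi_sum : (K, K) expected transition counts summed over t.
    alpha : (T, K) scaled forward variables (rows sum to 1).
    beta : (T, K) scaled backward variables.
    c : (T,) per-step scaling constants.
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for i in range(K):
        alpha[0, i] = pi[i] * b[0, i]
        s += alpha[0, i]
    c[0] = s
    for i in range(K):
        alpha[0, i] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= b[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.empty((T, K))
    for i in range(K):
        beta[T - 1, i] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            v = 0.0
            for j in range(K):
                v += A[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = v / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (
                    alpha[t, i] * A[i, j] * b[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )

    gamma = alpha * beta
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    return ll, gamma, xi_sum, alpha, beta, c


@njit(cache=True)
def forward_loglik(pi, A, b):
    """Forward pass only; log likelihood excluding row-scaling offsets."""
    T, K = b.shape
    alpha = np.empty(K)
    ll = 0.0
    s = 0.0
    for i in range(K):
        alpha[i] = pi[i] * b[0, i]
        s += alpha[i]
    ll += np.log(s)
    for i in range(K):
        alpha[i] /= s
    nxt = np.empty(K)
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[i] * A[i, j]
            a *= b[t, j]
            nxt[j] = a
            s += a
        ll += np.log(s)
        for j in range(K):
            alpha[j] = nxt[j] / s
    return ll


@njit(cache=True)
def viterbi_path(log_pi, log_A, log_b):
    """Most probable state path; ties resolved toward the lower state index."""
    T, K = log_b.shape
    delta = np.empty((T, K))
    psi = np.empty((T, K), np.int64)
    for i in range(K):
        delta[0, i] = log_pi[i] + log_b[0, i]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    path = np.empty(T, np.int64)
    best = -np.inf
    arg = 0
    for i in range(K):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
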