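"""Numba kernels for Gaussian-emission HMM inference.

Scaled forward-backward recursions and Viterbi decoding; kept free of
Python objects so the per-trace expectation-maximization stays fast
enough to idealize hundreds of traces per scenario.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(b, transmat, startprob):
    """Scaled forward-backward pass.

    ``b`` holds per-frame emission likelihoods (T x K, any positive
    scaling per frame is absorbed by the normalizers).  Returns
    (gamma, xi_sum, loglik) where gamma are posterior state
    probabilities and xi_sum the expected transition counts.
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)

    s = 0.0
    for k in range(K):
        alpha[0, k] = startprob[k] * b[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * transmat[i, j]
            alpha[t, j] = acc * b[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += transmat[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]

    gamma = alpha * beta
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (
                    alpha[t, i] * transmat[i, j] * b[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )

    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return gamma, xi_sum, loglik


@njit(cache=True)
def viterbi(logb, log_transmat, log_startprob):
    """Maximum-a-posteriori state path; ties break to the lower index."""
    T, K = logb.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_startprob[k] + logb[0, k]
    for t in range(1, T):
        for j in range(K):
            best_i = 0
            best = delta[t - 1, 0] + log_transmat[0, j]
            for i in range(1, K):
                v = delta[t - 1, i] + log_transmat[i, j]
                if v > best:  # strict: first (lowest-index) max wins
                    best = v
                    best_i = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = best_i
    path = np.empty(T, dtype=np.int64)
    best_k = 0
    best = delta[T - 1, 0]
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            best_k = k
    path[T - 1] = best_k
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
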