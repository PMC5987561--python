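"""Numba kernels for the heterogeneous HMM recursions.

All kernels work in log space on one chain (one chromosome's unmasked
fragments): ``logpi`` (K,), ``logA`` (n-1, K, K) distance-dependent
transition matrices, ``logB`` (n, K) emission log-densities.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e300


@njit(cache=True)
def _logsumexp_vec(v):
    m = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > m:
            m = v[i]
    if m <= NEG_INF:
        return NEG_INF
    s = 0.0
    for i in range(v.shape[0]):
        s += np.exp(v[i] - m)
    return m + np.log(s)


@njit(cache=True)
def forward_loglik(logpi, logA, logB):
    """Observed-data log-likelihood of one chain (forward recursion)."""
    n, K = logB.shape
    alpha = logpi + logB[0]
    work = np.empty(K)
    new = np.empty(K)
    for t in range(1, n):
        for k in range(K):
            for j in range(K):
                work[j] = alpha[j] + logA[t - 1, j, k]
            new[k] = _logsumexp_vec(work) + logB[t, k]
        alpha[:] = new
    return _logsumexp_vec(alpha)


@njit(cache=True)
def forward_backward(logpi, logA, logB):
    """Posterior state probabilities (gamma) and chain log-likelihood."""
    n, K = logB.shape
    la = np.empty((n, K))
    lb = np.empty((n, K))
    work = np.empty(K)
    la[0] = logpi + logB[0]
    for t in range(1, n):
        for k in range(K):
            for j in range(K):
                work[j] = la[t - 1, j] + logA[t - 1, j, k]
            la[t, k] = _logsumexp_vec(work) + logB[t, k]
    loglik = _logsumexp_vec(la[n - 1])
    lb[n - 1] = 0.0
    for t in range(n - 2, -1, -1):
        for j in range(K):
            for k in range(K):
                work[k] = logA[t, j, k] + logB[t + 1, k] + lb[t + 1, k]
            lb[t, j] = _logsumexp_vec(work)
    gamma = np.empty((n, K))
    for t in range(n):
        for k in range(K):
            gamma[t, k] = la[t, k] + lb[t, k] - loglik
        # normalize in probability space to kill rounding drift
        tot = 0.0
        for k in range(K):
            gamma[t, k] = np.exp(gamma[t, k])
            tot += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= tot
    return gamma, loglik


@njit(cache=True)
def viterbi_path(logpi, logA, logB):
    """Most probable state path; ties resolve to the lower state index."""
    n, K = logB.shape
    delta = np.empty((n, K))
    back = np.zeros((n, K), dtype=np.int64)
    delta[0] = logpi + logB[0]
    for t in range(1, n):
        for k in range(K):
            best = NEG_INF
            arg = 0
            for j in range(K):
                v = delta[t - 1, j] + logA[t - 1, j, k]
                if v > best:  # strict: first (lowest) j wins ties
                    best = v
                    arg = j
            delta[t, k] = best + logB[t, k]
            back[t, k] = arg
    best = NEG_INF
    last = 0
    for k in range(K):
        if delta[n - 1, k] > best:
            best = delta[n - 1, k]
            last = k
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = last
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best
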