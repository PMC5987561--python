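"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths: the
HMM oracles enumerate all 3^n hidden paths explicitly; the region
classifier enumerates label multisets.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm


def kernel_matrix(d: float, pi: np.ndarray, p0: float, L: float) -> np.ndarray:
    """Transition matrix A(d) written out element by element."""
    A = np.empty((3, 3))
    e = math.exp(-d / L)
    for j in range(3):
        A[j, j] = pi[j] + (p0 - pi[j]) * e
        for k in range(3):
            if k != j:
                A[j, k] = (1 - A[j, j]) * pi[k] / (1 - pi[j])
    return A


def _tables(values, dists, params):
    """Per-position emission and per-step transition log tables."""
    logB = norm.logpdf(
        np.asarray(values)[:, None], params.mu[None, :], params.sigma[None, :]
    )
    logA = [np.log(kernel_matrix(d, params.pi, params.p0, params.L)) for d in dists]
    return logB, logA


def _path_logprob(path, values, dists, params) -> float:
    logB, logA = _tables(values, dists, params)
    lp = math.log(params.pi[path[0]]) + logB[0, path[0]]
    for t in range(1, len(path)):
        lp += logA[t - 1][path[t - 1], path[t]] + logB[t, path[t]]
    return lp


def enumerate_paths(values: np.ndarray, dists: np.ndarray, params):
    """All (path, log-probability) pairs over 3^n hidden paths."""
    n = len(values)
    logB, logA = _tables(values, dists, params)
    logpi = np.log(params.pi)
    out = []
    for path in itertools.product(range(3), repeat=n):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, n):
            lp += logA[t - 1][path[t - 1], path[t]] + logB[t, path[t]]
        out.append((path, lp))
    return out

def brute_viterbi(values, dists, params):
    """Best path by exhaustive enumeration (lexicographic tie-break low)."""
    best_lp = -math.inf
    best_path = None
    for path, lp in enumerate_paths(values, dists, params):
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


def brute_loglik(values, dists, params) -> float:
    """Total data log-likelihood by summing all path probabilities."""
    lps = [lp for _, lp in enumerate_paths(values, dists, params)]
    m = max(lps)
    return m + math.log(sum(math.exp(lp - m) for lp in lps))


def brute_posteriors(values, dists, params) -> np.ndarray:
    """Per-position state posteriors by path enumeration."""
    n = len(values)
    post = np.zeros((n, 3))
    pairs = enumerate_paths(values, dists, params)
    m = max(lp for _, lp in pairs)
    for path, lp in pairs:
        w = math.exp(lp - m)
        for t, s in enumerate(path):
            post[t, s] += w
    return post / post.sum(axis=1, keepdims=True)


def brute_classify(labels) -> str:
    """Region class by explicit case enumeration over a label multiset."""
    s = set(labels)
    if not labels:
        return "no_data"
    if "gain" in s and "loss" in s:
        return "mixed"
    if s == {"gain"} or s == {"gain", "no_change"}:
        return "gain"
    if s == {"loss"} or s == {"loss", "no_change"}:
        return "loss"
    return "no_change"
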