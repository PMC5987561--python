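"""Three-state heterogeneous HMM over unevenly spaced GATC fragments.

DamID binding profiles live on GATC fragments of very uneven length, so a
homogeneous chain (one transition matrix for every pair of neighbours) is
wrong: fragments whose midpoints are 100 bp apart are far more likely to
share a binding state than fragments 10 kb apart.  Following the
heterogeneous-HMM idea used for array-CGH segmentation, the transition
matrix here is a function of the physical distance ``d`` between adjacent
fragment midpoints, relaxing exponentially from a configurable
zero-distance self-transition ``p0`` to the stationary distribution ``pi``
with decay length ``L``:

    A(d)_jj = pi_j + (p0 - pi_j) * exp(-d / L)
    A(d)_jk = (1 - A(d)_jj) * pi_k / (1 - pi_j)   for k != j

``A(0)`` has self-transition ``p0`` on the diagonal and ``A(inf)`` has every
row equal to ``pi``, so nearby fragments are correlated and distant ones
independent — the two properties the segmentation relies on.

Emissions are Gaussian in log2-ratio units, one (mu, sigma) per state,
states ordered ascending by mu: 0 = depleted, 1 = intermediate,
2 = enriched.  Fitting is Baum–Welch: emissions by the exact M-step;
``pi``, ``p0`` and ``L`` by direct likelihood ascent (bounded scalar search,
accepted only when the observed log-likelihood improves), so the
log-likelihood trace is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ._hmm_core import forward_backward, forward_loglik, viterbi_path
from .errors import ConfigError, OrderingError, TooFewFragmentsError
from .normalize import NormalizedProfile

N_STATES = 3
STATE_NAMES = ("depleted", "intermediate", "enriched")
#: serialization encoding (WIG): enriched = 1, intermediate = 0, depleted = -1
STATE_ENCODING = {0: -1, 1: 0, 2: 1}
STATE_DECODING = {v: k for k, v in STATE_ENCODING.items()}


@dataclass
class HMMParams:
    """Parameters of the three-state heterogeneous HMM."""

    mu: np.ndarray  # emission means, log2 units, strictly ascending
    sigma: np.ndarray  # emission sds, >= variance floor
    pi: np.ndarray  # stationary/initial distribution
    p0: float  # self-transition probability at zero distance
    L: float  # transition decay length, bases

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.mu.shape != (N_STATES,) or self.sigma.shape != (N_STATES,):
            raise ConfigError("mu and sigma must have 3 entries")
        if self.pi.shape != (N_STATES,):
            raise ConfigError("pi must have 3 entries")
        if not np.all(np.diff(self.mu) > 0):
            raise ConfigError("state means must be strictly ascending")
        if np.any(self.sigma <= 0):
            raise ConfigError("sigma must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-9 or np.any(self.pi <= 0) or np.any(self.pi >= 1):
            raise ConfigError("pi must be a probability vector with entries in (0,1)")
        if not 0.0 <= self.p0 <= 1.0:
            raise ConfigError("p0 must lie in [0, 1]")
        if self.L <= 0:
            raise ConfigError("decay length L must be positive")


@dataclass
class StateCall:
    """Per-fragment binding-state labels aligned to a fragment index.

    ``states[i]`` in {0 depleted, 1 intermediate, 2 enriched}; fragments
    masked during normalization have ``missing[i]`` True and an undefined
    state entry.
    """

    states: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.states.shape != self.missing.shape:
            raise ValueError("states and missing must share shape")
        valid = self.states[~self.missing]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise ValueError("states must be in {0, 1, 2}")

    def encoded(self) -> np.ndarray:
        """States in the published WIG encoding (1/0/-1), NaN where missing."""
        out = np.full(self.states.shape, np.nan)
        enc = np.array([-1, 0, 1], dtype=float)
        out[~self.missing] = enc[self.states[~self.missing]]
        return out

    def names(self) -> np.ndarray:
        out = np.full(self.states.shape, None, dtype=object)
        nm = np.array(STATE_NAMES, dtype=object)
        out[~self.missing] = nm[self.states[~self.missing]]
        return out


@dataclass
class HMMFit:
    params: HMMParams
    viterbi: StateCall
    posteriors: np.ndarray  # (n_fragments, 3); NaN rows where missing
    loglik_trace: list[float]
    converged: bool
    degenerate: bool = False


def transition_matrix(d: float, params: HMMParams) -> np.ndarray:
    """Distance-dependent 3x3 row-stochastic transition matrix A(d)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return _transition_stack(np.array([float(d)]), params.pi, params.p0, params.L)[0]


def _transition_stack(d: np.ndarray, pi: np.ndarray, p0: float, L: float) -> np.ndarray:
    """A(d) for an array of distances; shape (len(d), 3, 3)."""
    decay = np.exp(-np.asarray(d, dtype=float) / L)  # (m,)
    diag = pi[None, :] + (p0 - pi[None, :]) * decay[:, None]  # (m, 3)
    off = (1.0 - diag)[:, :, None] * (pi[None, None, :] / (1.0 - pi)[None, :, None])
    A = off
    m = d.shape[0]
    idx = np.arange(N_STATES)
    A[:, idx, idx] = diag
    return A


# ---------------------------------------------------------------------------
# chain assembly


@dataclass
class _Chain:
    values: np.ndarray  # unmasked profile values, genome order
    dists: np.ndarray  # midpoint-to-midpoint distances between neighbours
    frag_idx: np.ndarray  # positions in the full fragment universe


def build_chains(profile: NormalizedProfile, fragments: pd.DataFrame) -> list[_Chain]:
    """Split a profile into per-chromosome chains of unmasked fragments.

    Masked fragments are skipped and the midpoint distance between their
    unmasked neighbours is used (gap-aware), not imputed.
    """
    if len(profile.values) != len(fragments):
        raise ValueError("profile and fragment index differ in length")
    chains: list[_Chain] = []
    fragments = fragments.reset_index(drop=True)
    for _, sub in fragments.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise OrderingError("fragments must be sorted by start within chromosome")
        idx = sub.index.to_numpy()
        keep = ~profile.mask[idx]
        idx = idx[keep]
        if idx.size == 0:
            continue
        mid = (
            fragments.loc[idx, "start"].to_numpy()
            + fragments.loc[idx, "end"].to_numpy()
        ) / 2.0
        chains.append(
            _Chain(
                values=profile.values[idx],
                dists=np.diff(mid),
                frag_idx=idx,
            )
        )
    return chains


def _log_emissions(values: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return norm.logpdf(values[:, None], mu[None, :], sigma[None, :])


def _chains_loglik(chains: Sequence[_Chain], params: HMMParams) -> float:
    logpi = np.log(params.pi)
    total = 0.0
    for ch in chains:
        logB = _log_emissions(ch.values, params.mu, params.sigma)
        logA = np.log(_transition_stack(ch.dists, params.pi, params.p0, params.L))
        total += forward_loglik(logpi, logA, logB)
    return total


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    tol: float = 1e-6
    max_iter: int = 500
    var_floor: float = 1e-3  # (log2 units)^2
    seed: int | None = None


def default_init(profile: NormalizedProfile, fragments: pd.DataFrame) -> HMMParams:
    """Deterministic initialization from profile quantiles and spacing."""
    vals = profile.values[~profile.mask]
    mu = np.percentile(vals, [10, 50, 90])
    if not np.all(np.diff(mu) > 0):  # near-constant input: force separation
        mu = mu + np.array([-1e-2, 0.0, 1e-2])
    sd = max(float(np.std(vals)) / 2.0, 0.05)
    chains = build_chains(profile, fragments)
    all_d = np.concatenate([c.dists for c in chains]) if chains else np.array([1.0])
    L = float(np.median(all_d)) if all_d.size else 1000.0
    L = max(L, 1.0)
    return HMMParams(
        mu=mu,
        sigma=np.full(N_STATES, sd),
        pi=np.full(N_STATES, 1.0 / N_STATES),
        p0=0.9,
        L=L,
    )


def fit_em(
    profile: NormalizedProfile,
    fragments: pd.DataFrame,
    init: HMMParams | None = None,
    config: FitConfig | None = None,
) -> HMMFit:
    """Fit the heterogeneous HMM by Baum–Welch and decode states.

    Emission means/sds are updated by the exact M-step from the posterior
    weights; pi, p0 and L are updated by bounded numeric maximization of the
    observed log-likelihood, each update accepted only if it improves the
    likelihood.  Stops when the relative log-likelihood change drops below
    ``config.tol`` or after ``config.max_iter`` iterations.  States are
    relabelled ascending in mu before return.
    """
    config = config or FitConfig()
    if not np.isfinite(profile.values[~profile.mask]).all():
        raise ValueError("profile contains non-finite unmasked values")
    if profile.n_unmasked < 30:
        raise TooFewFragmentsError(
            f"need >= 30 unmasked fragments, got {profile.n_unmasked}"
        )
    chains = build_chains(profile, fragments)
    params = init or default_init(profile, fragments)
    sd_floor = float(np.sqrt(config.var_floor))
    params = replace(params, sigma=np.maximum(params.sigma, sd_floor))

    trace: list[float] = [_chains_loglik(chains, params)]
    converged = False
    for _ in range(config.max_iter):
        # E-step
        logpi = np.log(params.pi)
        gammas = []
        for ch in chains:
            logB = _log_emissions(ch.values, params.mu, params.sigma)
            logA = np.log(_transition_stack(ch.dists, params.pi, params.p0, params.L))
            g, _ = forward_backward(logpi, logA, logB)
            gammas.append(g)
        gamma_all = np.vstack(gammas)
        vals_all = np.concatenate([c.values for c in chains])

        # exact M-step for emissions (monotone by the EM inequality)
        w = gamma_all.sum(axis=0)
        w = np.maximum(w, 1e-12)
        mu_new = gamma_all.T @ vals_all / w
        var_new = (gamma_all * (vals_all[:, None] - mu_new[None, :]) ** 2).sum(0) / w
        sigma_new = np.sqrt(np.maximum(var_new, config.var_floor))
        order = np.argsort(mu_new)
        if np.any(np.diff(mu_new[order]) <= 0):  # exact ties: nudge apart
            mu_new[order] += np.array([-1e-9, 0.0, 1e-9])
        params = replace(
            params,
            mu=mu_new[order],
            sigma=sigma_new[order],
            pi=_renorm(params.pi[order]),
        )
        ll = _chains_loglik(chains, params)

        # direct likelihood ascent for pi, p0, L (accept-if-better)
        pi_cand = _renorm(np.maximum(gamma_all.mean(axis=0)[order], 1e-6))
        cand = replace(params, pi=pi_cand)
        ll_cand = _chains_loglik(chains, cand)
        if ll_cand > ll:
            params, ll = cand, ll_cand

        res = minimize_scalar(
            lambda p: -_chains_loglik(chains, replace(params, p0=p)),
            bounds=(1e-6, 1.0 - 1e-6),
            method="bounded",
            options={"maxiter": 20, "xatol": 1e-4},
        )
        if -res.fun > ll:
            params, ll = replace(params, p0=float(res.x)), float(-res.fun)

        res = minimize_scalar(
            lambda x: -_chains_loglik(chains, replace(params, L=10.0**x)),
            bounds=(0.0, 7.0),
            method="bounded",
            options={"maxiter": 20, "xatol": 1e-3},
        )
        if -res.fun > ll:
            params, ll = replace(params, L=float(10.0 ** res.x)), float(-res.fun)

        trace.append(ll)
        prev = trace[-2]
        if abs(ll - prev) / (abs(prev) + 1e-12) < config.tol:
            converged = True
            break

    degenerate = bool(np.min(np.diff(params.mu)) < 1e-3)
    call = viterbi_decode(profile, fragments, params)
    post = posterior_decode(profile, fragments, params)
    return HMMFit(
        params=params,
        viterbi=call,
        posteriors=post,
        loglik_trace=trace,
        converged=converged,
        degenerate=degenerate,
    )


def _renorm(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-9, None)
    return p / p.sum()


def viterbi_decode(
    profile: NormalizedProfile, fragments: pd.DataFrame, params: HMMParams
) -> StateCall:
    """Most probable state path per chromosome; ties favour 'depleted'."""
    n = len(profile.values)
    states = np.zeros(n, dtype=np.int8)
    missing = profile.mask.copy()
    logpi = np.log(params.pi)
    for ch in build_chains(profile, fragments):
        logB = _log_emissions(ch.values, params.mu, params.sigma)
        logA = np.log(_transition_stack(ch.dists, params.pi, params.p0, params.L))
        path, _ = viterbi_path(logpi, logA, logB)
        states[ch.frag_idx] = path.astype(np.int8)
    return StateCall(states, missing)


def posterior_decode(
    profile: NormalizedProfile, fragments: pd.DataFrame, params: HMMParams
) -> np.ndarray:
    """Forward–backward posteriors, (n_fragments, 3); NaN rows where masked."""
    n = len(profile.values)
    post = np.full((n, N_STATES), np.nan)
    logpi = np.log(params.pi)
    for ch in build_chains(profile, fragments):
        logB = _log_emissions(ch.values, params.mu, params.sigma)
        logA = np.log(_transition_stack(ch.dists, params.pi, params.p0, params.L))
        g, _ = forward_backward(logpi, logA, logB)
        post[ch.frag_idx] = g
    return post
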