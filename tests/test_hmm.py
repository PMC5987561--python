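"""Heterogeneous HMM: kernel, decoding vs enumeration, EM fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fragments, profile_from, tiling_fragments
from oracles import brute_loglik, brute_posteriors, brute_viterbi, kernel_matrix
from polydam.hmm import (
    FitConfig,
    HMMParams,
    fit_em,
    posterior_decode,
    transition_matrix,
    viterbi_decode,
)
from polydam.simulate import SimConfig, simulate_emissions, simulate_states


class TestTransitionKernel:
    def test_identity_at_zero_distance_with_p0_one(self, simple_params):
        p = HMMParams(simple_params.mu, simple_params.sigma, simple_params.pi, 1.0, 2000.0)
        assert np.allclose(transition_matrix(0.0, p), np.eye(3))

    def test_rows_equal_stationary_at_large_distance(self, simple_params):
        A = transition_matrix(1e12, simple_params)
        assert np.allclose(A, np.tile(simple_params.pi, (3, 1)), atol=1e-12)

    def test_value_at_one_decay_length(self):
        # A_jj = 1/3 + (0.9 - 1/3) e^{-1} for uniform pi
        p = HMMParams(
            np.array([-1.0, 0.0, 1.0]), np.ones(3), np.full(3, 1 / 3), 0.9, 1000.0
        )
        A = transition_matrix(1000.0, p)
        expected = 1 / 3 + (0.9 - 1 / 3) * np.exp(-1.0)
        assert np.allclose(np.diag(A), expected)
        assert expected == pytest.approx(0.5417, abs=2e-4)

    def test_negative_distance_rejected(self, simple_params):
        with pytest.raises(ValueError):
            transition_matrix(-1.0, simple_params)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        d=st.floats(0, 1e6),
        p0=st.floats(0.0, 1.0),
        L=st.floats(1.0, 1e5),
        w=st.tuples(*[st.floats(0.05, 1.0)] * 3),
    )
    def test_row_stochastic_for_random_params(self, d, p0, L, w):
        pi = np.array(w) / np.sum(w)
        p = HMMParams(np.array([-1.0, 0.0, 1.0]), np.ones(3), pi, p0, L)
        A = transition_matrix(d, p)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)
        assert (A >= -1e-15).all()
        assert np.allclose(A, kernel_matrix(d, pi, p0, L), atol=1e-12)


class TestDecodingAgainstEnumeration:
    @pytest.mark.parametrize("n,seed", [(4, 0), (7, 1), (10, 2)])
    def test_viterbi_matches_exhaustive_enumeration(self, n, seed, simple_params):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1.5, n)
        starts = np.cumsum(rng.integers(100, 3000, n)) - 100
        frags = make_fragments(starts, starts + 100)
        mids = starts + 50.0
        path_bf, lp_bf = brute_viterbi(values, np.diff(mids), simple_params)
        call = viterbi_decode(profile_from(values), frags, simple_params)
        assert (call.states == path_bf).all()
        # and the path log-probability agrees
        from oracles import _path_logprob

        assert _path_logprob(tuple(call.states), values, np.diff(mids), simple_params) == pytest.approx(lp_bf, abs=1e-8)

    @pytest.mark.parametrize("n,seed", [(3, 3), (6, 4), (9, 5)])
    def test_posteriors_match_path_sum(self, n, seed, simple_params):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1.5, n)
        starts = np.cumsum(rng.integers(100, 3000, n)) - 100
        frags = make_fragments(starts, starts + 100)
        post = posterior_decode(profile_from(values), frags, simple_params)
        bf = brute_posteriors(values, np.diff(starts + 50.0), simple_params)
        assert np.allclose(post, bf, atol=1e-8)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-8)

    def test_single_fragment_is_prior_times_likelihood(self, simple_params):
        from scipy.stats import norm

        frags = tiling_fragments(1)
        value = 0.7
        call = viterbi_decode(profile_from([value]), frags, simple_params)
        weights = simple_params.pi * norm.pdf(
            value, simple_params.mu, simple_params.sigma
        )
        assert call.states[0] == np.argmax(weights)

    def test_two_identical_chromosomes_decode_identically(self, simple_params):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1.5, 8)
        frags = make_fragments(
            list(range(0, 800, 100)) * 2,
            list(range(100, 900, 100)) * 2,
            chrom=["chr1"] * 8 + ["chr2"] * 8,
        )
        both = np.concatenate([values, values])
        call = viterbi_decode(profile_from(both), frags, simple_params)
        assert (call.states[:8] == call.states[8:]).all()

    def test_uniform_prior_equal_means_gives_uniform_posteriors(self):
        p = HMMParams(
            np.array([-1e-9, 0.0, 1e-9]), np.ones(3), np.full(3, 1 / 3), 0.5, 1000.0
        )
        frags = tiling_fragments(5)
        post = posterior_decode(profile_from(np.zeros(5)), frags, p)
        assert np.allclose(post, 1 / 3, atol=1e-6)

    def test_masked_fragments_are_skipped_gap_aware(self, simple_params):
        # masking the middle fragment must equal decoding the 2-fragment
        # chain with the combined midpoint distance
        values = np.array([1.4, 99.0, -1.6])
        frags = tiling_fragments(3, size=1000)
        mask = np.array([False, True, False])
        call = viterbi_decode(profile_from(values, mask), frags, simple_params)
        assert call.missing[1]
        bf_path, _ = brute_viterbi(
            values[[0, 2]], np.array([2000.0]), simple_params
        )
        assert (call.states[[0, 2]] == bf_path).all()


class TestForwardLikelihood:
    @pytest.mark.parametrize("n,seed", [(5, 10), (8, 11)])
    def test_loglik_matches_enumeration(self, n, seed, simple_params):
        from polydam.hmm import build_chains, _chains_loglik

        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1.2, n)
        starts = np.cumsum(rng.integers(50, 4000, n))
        frags = make_fragments(starts, starts + 50)
        ll = _chains_loglik(
            build_chains(profile_from(values), frags), simple_params
        )
        assert ll == pytest.approx(
            brute_loglik(values, np.diff(starts + 25.0), simple_params), abs=1e-8
        )

    def test_matches_hmmlearn_on_constant_spacing(self, simple_params):
        # with equal spacing the chain is homogeneous: cross-check against
        # an independent HMM implementation
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(12)
        n = 200
        values = rng.normal(0, 1.5, n)
        frags = tiling_fragments(n, size=500)
        from polydam.hmm import build_chains, _chains_loglik

        ll = _chains_loglik(build_chains(profile_from(values), frags), simple_params)
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        model.startprob_ = simple_params.pi
        model.transmat_ = transition_matrix(500.0, simple_params)
        model.means_ = simple_params.mu.reshape(-1, 1)
        model.covars_ = (simple_params.sigma**2).reshape(-1, 1)
        assert ll == pytest.approx(model.score(values.reshape(-1, 1)), abs=1e-6)
        call = viterbi_decode(profile_from(values), frags, simple_params)
        assert (call.states == model.predict(values.reshape(-1, 1))).all()


class TestFitEM:
    def test_parameter_and_state_recovery_on_simulated_chain(self):
        cfg = SimConfig(seed=7, n_chroms=1, chrom_length=680_000)
        from polydam.fragments import find_gatc_fragments
        from polydam.simulate import simulate_genome

        frags = find_gatc_fragments(simulate_genome(cfg))
        assert len(frags) >= 5000
        frags = frags.iloc[:5000].reset_index(drop=True)
        states = simulate_states(frags, cfg)[:5000]
        profile = simulate_emissions(frags, states, cfg)
        fit = fit_em(profile, frags)
        assert np.abs(fit.params.mu - np.array([-1.5, 0.0, 1.5])).max() <= 0.1
        accuracy = (fit.viterbi.states == states).mean()
        assert accuracy >= 0.95
        # posterior argmax largely agrees with Viterbi at high SNR
        agree = (np.nanargmax(fit.posteriors, axis=1) == fit.viterbi.states).mean()
        assert agree >= 0.90

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(21)
        n = 300
        values = rng.normal(0, 1.0, n)  # pure noise: hard case for EM
        frags = tiling_fragments(n, size=200)
        fit = fit_em(profile_from(values), frags, config=FitConfig(max_iter=40))
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-6).all()

    def test_constant_input_hits_variance_floor_and_flags_degenerate(self):
        frags = tiling_fragments(100)
        fit = fit_em(profile_from(np.zeros(100)), frags, config=FitConfig(max_iter=20))
        assert fit.degenerate
        assert (fit.params.sigma >= np.sqrt(1e-3) - 1e-12).all()

    def test_states_relabelled_ascending_regardless_of_init(self, simple_params):
        rng = np.random.default_rng(22)
        states = rng.integers(0, 3, 400)
        values = np.array([-2.0, 0.0, 2.0])[states] + rng.normal(0, 0.3, 400)
        frags = tiling_fragments(400, size=2000)
        bad_init = HMMParams(
            np.array([-0.1, 0.0, 0.1]), np.full(3, 2.0), np.full(3, 1 / 3), 0.5, 100.0
        )
        fit = fit_em(profile_from(values), frags, init=bad_init)
        assert (np.diff(fit.params.mu) > 0).all()

    def test_too_few_fragments_rejected(self):
        frags = tiling_fragments(10)
        with pytest.raises(Exception, match="30"):
            fit_em(profile_from(np.zeros(10)), frags)

    def test_non_finite_profile_rejected(self):
        frags = tiling_fragments(50)
        vals = np.zeros(50)
        vals[3] = np.inf
        with pytest.raises(ValueError):
            fit_em(profile_from(vals), frags)
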