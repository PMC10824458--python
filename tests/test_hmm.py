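"""HMM estimation and decoding, checked against exhaustive enumeration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sleephmm as sh
from sleephmm.errors import ValidationError


def enumerate_paths(pi, A, lik):
    """Independent oracle: joint probability over every K^T path.

    Returns (argmax path, exact marginals). Computed by explicit tensor
    expansion, touching none of the package's recursions.
    """
    pi, A, lik = np.asarray(pi, float), np.asarray(A, float), np.asarray(lik, float)
    T, K = lik.shape
    P = pi * lik[0]
    for t in range(1, T):
        P = P[..., :, None] * (A * lik[t][None, :])
    total = P.sum()
    path = np.array(np.unravel_index(np.argmax(P), P.shape))
    marginals = np.stack(
        [P.sum(axis=tuple(ax for ax in range(T) if ax != t)) for t in range(T)]
    )
    return path, marginals / total


def random_instance(rng, K=3, T_max=8):
    T = int(rng.integers(2, T_max + 1))
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    lik = rng.random((T, K)) + 1e-3
    return pi, A, lik


class TestDecodingOracles:
    def test_viterbi_prefers_contextually_consistent_path(self):
        """Context can override the per-epoch argmax."""
        pi = np.log([0.5, 0.5])
        A = np.log([[0.9, 0.1], [0.1, 0.9]])
        lik = np.array([[0.8, 0.2], [0.2, 0.8], [0.8, 0.2]])
        path = sh.viterbi_from_loglik(pi, A, np.log(lik))
        assert list(path) == [0, 0, 0]  # per-epoch argmax would be (0, 1, 0)
        oracle_path, _ = enumerate_paths(np.exp(pi), np.exp(A), lik)
        assert list(oracle_path) == [0, 0, 0]
        # winning joint probability, by hand: .5*.8 * .9*.2 * .9*.8
        assert 0.5 * 0.8 * 0.9 * 0.2 * 0.9 * 0.8 == pytest.approx(0.05184)

    def test_identity_transitions_lock_the_initial_state(self):
        pi = np.array([1.0, 0.0])
        A = np.eye(2)
        lik = np.array([[0.1, 0.9]] * 5)
        with np.errstate(divide="ignore"):
            path = sh.viterbi_from_loglik(np.log(pi), np.log(A), np.log(lik))
        assert list(path) == [0] * 5

    def test_viterbi_and_marginals_match_enumeration_on_random_models(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            pi, A, lik = random_instance(rng)
            with np.errstate(divide="ignore"):
                log_pi, log_A, loglik = np.log(pi), np.log(A), np.log(lik)
            oracle_path, oracle_marg = enumerate_paths(pi, A, lik)
            assert np.array_equal(sh.viterbi_from_loglik(log_pi, log_A, loglik), oracle_path)
            gamma, _ = sh.forward_backward_from_loglik(log_pi, log_A, loglik)
            np.testing.assert_allclose(gamma, oracle_marg, atol=1e-9)

    def test_single_epoch_posterior_is_normalized_likelihood(self):
        gamma, _ = sh.forward_backward_from_loglik(
            np.log([0.5, 0.5]), np.log(np.full((2, 2), 0.5)), np.log([[0.8, 0.2]])
        )
        np.testing.assert_allclose(gamma, [[0.8, 0.2]], atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_posterior_rows_are_simplex_points(self, seed):
        rng = np.random.default_rng(seed)
        pi, A, lik = random_instance(rng, T_max=20)
        with np.errstate(divide="ignore"):
            gamma, _ = sh.forward_backward_from_loglik(np.log(pi), np.log(A), np.log(lik))
        assert np.all(gamma >= 0)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_long_sequence_decoding_stays_finite(self):
        """Log-domain / scaled recursions survive 10^5 epochs without underflow."""
        rng = np.random.default_rng(0)
        states = ("awake", "NREM", "REM")
        means = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        covs = np.stack([np.eye(2)] * 3)
        emis = sh.GaussianEmission(states=states, means=means, covariances=covs)
        trans = sh.TransitionModel(
            states=states,
            initial=np.array([0.5, 0.3, 0.2]),
            matrix=np.array([[0.98, 0.01, 0.01], [0.01, 0.98, 0.01], [0.01, 0.01, 0.98]]),
        )
        X = rng.standard_normal((100_000, 2)) + 2.0
        post = sh.posterior_probabilities(trans, emis, X)
        assert np.isfinite(post.probabilities).all()
        np.testing.assert_allclose(post.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_agrees_with_hmmlearn_reference(self):
        """Cross-check against an established HMM library."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        states = ("awake", "NREM", "REM")
        means = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        covs = np.stack([np.eye(2) * s for s in (1.0, 0.5, 2.0)])
        pi = np.array([0.6, 0.3, 0.1])
        A = np.array([[0.9, 0.08, 0.02], [0.1, 0.85, 0.05], [0.15, 0.05, 0.8]])
        X = np.vstack(
            [rng.multivariate_normal(m, c, size=50) for m, c in zip(means, covs)]
        )
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_, ref.transmat_, ref.means_, ref.covars_ = pi, A, means, covs
        emis = sh.GaussianEmission(states=states, means=means, covariances=covs)
        trans = sh.TransitionModel(states=states, initial=pi, matrix=A)
        path = sh.viterbi_decode(trans, emis, X)
        post = sh.posterior_probabilities(trans, emis, X)
        ref_path = ref.predict(X)
        np.testing.assert_array_equal(
            path, np.array(states, dtype=object)[ref_path]
        )
        np.testing.assert_allclose(post.probabilities, ref.predict_proba(X), atol=1e-8)


class TestEstimation:
    def test_emission_mean_of_two_points(self):
        emis = sh.estimate_emissions(
            np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0], [5.0, 6.0]]),
            ["awake", "awake", "NREM", "NREM"],
            states=("awake", "NREM"),
        )
        np.testing.assert_allclose(emis.means[0], [1.0, 1.0])

    def test_emission_recovery_from_gaussian_samples(self):
        rng = np.random.default_rng(123)
        X = rng.multivariate_normal([3.0, -1.0], np.eye(2), size=10_000)
        emis = sh.estimate_emissions(X, ["awake"] * 10_000, states=("awake",))
        assert np.all(np.abs(emis.means[0] - [3.0, -1.0]) < 0.05)

    def test_degenerate_state_gets_jitter_and_finite_density(self):
        X = np.tile([1.0, 2.0], (10, 1))
        emis = sh.estimate_emissions(X, ["awake"] * 10, states=("awake",))
        ll = emis.log_likelihood(np.array([[1.0, 2.0]]))
        assert np.isfinite(ll).all()

    def test_absent_state_named_in_error(self):
        with pytest.raises(ValidationError, match="REM"):
            sh.estimate_emissions(
                np.zeros((4, 2)), ["awake"] * 4, states=("awake", "REM")
            )

    def test_transition_mle_by_hand_count(self):
        model = sh.estimate_transitions(
            np.array(["awake", "awake", "NREM", "NREM", "NREM", "awake"], dtype=object)
        )
        np.testing.assert_allclose(model.matrix[0], [0.5, 0.5])
        np.testing.assert_allclose(model.matrix[1], [1 / 3, 2 / 3])
        np.testing.assert_allclose(model.initial, [0.5, 0.5])

    def test_single_state_requires_explicit_state_set(self):
        y = np.array(["awake"] * 10, dtype=object)
        with pytest.raises(ValidationError, match="one state"):
            sh.estimate_transitions(y)
        model = sh.estimate_transitions(y, states=("awake",))
        assert model.matrix[0, 0] == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            sh.estimate_transitions(np.array([], dtype=object))

    def test_pruning_zeroes_rare_transitions_and_renormalizes(self):
        row = np.array(
            [[0.99996, 0.00003, 0.00001], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]
        )
        pruned = sh.prune_transition_matrix(row, epoch_s=1.0, prune_per_s=1e-4)
        np.testing.assert_allclose(pruned[0], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(pruned.sum(axis=1), 1.0, atol=1e-12)

    def test_pruning_preserves_row_stochasticity_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            A = rng.dirichlet(np.full(4, 0.05), size=4)  # sparse-ish rows
            pruned = sh.prune_transition_matrix(A, prune_per_s=1e-2)
            np.testing.assert_allclose(pruned.sum(axis=1), 1.0, atol=1e-9)


class TestNaiveBayes:
    def _emissions(self):
        return sh.GaussianEmission(
            states=("awake", "NREM"),
            means=np.array([[0.0], [4.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
        )

    def test_prior_weighting_flips_the_argmax(self):
        # at x=2.2 the likelihood slightly favours NREM; a 0.9 awake prior wins
        emis = self._emissions()
        assert sh.naive_bayes_decode(emis, [0.5, 0.5], np.array([[2.2]]))[0] == "NREM"
        assert sh.naive_bayes_decode(emis, [0.9, 0.1], np.array([[2.2]]))[0] == "awake"

    def test_uniform_priors_reduce_to_maximum_likelihood(self):
        emis = self._emissions()
        X = np.random.default_rng(0).standard_normal((100, 1)) * 3
        ml = np.array(["awake", "NREM"], dtype=object)[
            np.argmax(emis.log_likelihood(X), axis=1)
        ]
        assert np.array_equal(sh.naive_bayes_decode(emis, [0.5, 0.5], X), ml)

    def test_zero_prior_state_never_predicted(self):
        emis = self._emissions()
        X = np.full((50, 1), 4.0)  # squarely NREM territory
        labels = sh.naive_bayes_decode(emis, [1.0, 0.0], X)
        assert np.all(labels == "awake")

    def test_uniform_transitions_make_viterbi_equal_naive_bayes(self):
        rng = np.random.default_rng(9)
        states = ("awake", "NREM", "REM")
        means = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        covs = np.stack([np.eye(2)] * 3)
        emis = sh.GaussianEmission(states=states, means=means, covariances=covs)
        priors = np.array([0.5, 0.3, 0.2])
        trans = sh.TransitionModel(
            states=states, initial=priors, matrix=np.tile(priors, (3, 1))
        )
        X = rng.standard_normal((500, 2)) * 2
        assert np.array_equal(
            sh.viterbi_decode(trans, emis, X), sh.naive_bayes_decode(emis, priors, X)
        )
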