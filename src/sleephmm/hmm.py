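"""Supervised Gaussian-emission hidden Markov model.

The model is trained fully supervised: per-state multivariate Gaussian
emissions are maximum-likelihood fits to the labelled component-space
features, and the epoch-resolution transition matrix is the count-normalized
empirical transition frequency, optionally pruned of biologically spurious
entries (off-diagonal probabilities below a per-second threshold, 0.0001/s
by default — e.g. direct awake→REM transitions in wild-type mice).

Decoding uses the Viterbi algorithm for the jointly most probable state
sequence and forward–backward smoothing for the per-epoch marginal state
probabilities; the marginal probability of the decoded state serves as the
per-epoch certainty. Both passes run in the log domain (Viterbi) or with
per-step scaling (forward–backward) so that arbitrarily long recordings
decode without underflow. The naive Bayes decoder — per-epoch argmax of
likelihood × state frequency, with no temporal context — is retained as a
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .errors import ValidationError
from .preprocess import FeatureMatrix
from .states import (
    EXCLUDED_LABELS,
    STATES,
    as_label_array,
    indices_to_labels,
    labels_to_indices,
)

#: Default pruning threshold: transition probability per second.
DEFAULT_PRUNE_PER_S = 1e-4

_COV_JITTER_FACTOR = 1e-6


@dataclass
class GaussianEmission:
    """Per-state multivariate Gaussian emission parameters."""

    states: tuple[str, ...]
    means: np.ndarray  # [K x d]
    covariances: np.ndarray  # [K x d x d]

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        K, d = self.means.shape
        if len(self.states) != K:
            raise ValidationError("one emission distribution per state required")
        if self.covariances.shape != (K, d, d):
            raise ValidationError("covariance stack must be [K x d x d]")

    @property
    def ndim(self) -> int:
        return self.means.shape[1]

    def log_likelihood(self, X) -> np.ndarray:
        """Per-epoch log density under each state's Gaussian: [T x K]."""
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        values = np.atleast_2d(values)
        if not np.isfinite(values).all():
            raise ValidationError("features contain non-finite values")
        out = np.empty((values.shape[0], len(self.states)))
        for k in range(len(self.states)):
            out[:, k] = multivariate_normal.logpdf(
                values, mean=self.means[k], cov=self.covariances[k]
            )
        return out

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianEmission":
        return cls(
            states=tuple(d["states"]),
            means=np.array(d["means"], dtype=float),
            covariances=np.array(d["covariances"], dtype=float),
        )


@dataclass
class TransitionModel:
    """State set, initial distribution and row-stochastic transition matrix."""

    states: tuple[str, ...]
    initial: np.ndarray
    matrix: np.ndarray
    prune_threshold_per_s: float = DEFAULT_PRUNE_PER_S
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float).ravel()
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        K = len(self.states)
        if self.initial.shape != (K,) or self.matrix.shape != (K, K):
            raise ValidationError("initial/matrix shapes must match the state set")
        if (self.initial < 0).any() or (self.matrix < 0).any():
            raise ValidationError("probabilities must be non-negative")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValidationError("initial distribution must sum to 1")
        if np.abs(self.matrix.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValidationError("transition matrix rows must sum to 1")

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "initial": self.initial.tolist(),
            "matrix": self.matrix.tolist(),
            "prune_threshold_per_s": self.prune_threshold_per_s,
            "epoch_s": self.epoch_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        return cls(
            states=tuple(d["states"]),
            initial=np.array(d["initial"], dtype=float),
            matrix=np.array(d["matrix"], dtype=float),
            prune_threshold_per_s=float(d["prune_threshold_per_s"]),
            epoch_s=float(d["epoch_s"]),
        )


@dataclass
class PosteriorSequence:
    """Marginal state probabilities plus the Viterbi path.

    ``probabilities`` rows lie on the probability simplex; ``viterbi_path``
    is the jointly most probable label sequence. The certainty of an epoch
    is the marginal probability of its decoded state.
    """

    probabilities: np.ndarray  # [T x K]
    viterbi_path: np.ndarray  # [T] labels
    states: tuple[str, ...]
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        self.probabilities = np.atleast_2d(np.asarray(self.probabilities, dtype=float))
        self.viterbi_path = as_label_array(self.viterbi_path)
        T, K = self.probabilities.shape
        if K != len(self.states):
            raise ValidationError("probability columns must match the state set")
        if len(self.viterbi_path) != T:
            raise ValidationError("viterbi path length must match probability rows")
        if (self.probabilities < -1e-12).any() or (self.probabilities > 1 + 1e-9).any():
            raise ValidationError("probabilities must lie in [0, 1]")
        if np.abs(self.probabilities.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValidationError("probability rows must sum to 1")

    @property
    def n_epochs(self) -> int:
        return self.probabilities.shape[0]

    def certainty(self) -> np.ndarray:
        """Posterior probability of the decoded (Viterbi) state, per epoch."""
        idx = labels_to_indices(self.viterbi_path, self.states)
        return self.probabilities[np.arange(self.n_epochs), idx]


# ---------------------------------------------------------------------------
# Supervised parameter estimation
# ---------------------------------------------------------------------------


def estimate_emissions(
    X2: FeatureMatrix | np.ndarray,
    y,
    states: tuple[str, ...] = STATES,
) -> GaussianEmission:
    """Per-state sample mean and regularized sample covariance.

    Covariances receive a jitter of ``1e-6 x mean diagonal`` on the diagonal
    so degenerate states (e.g. all samples identical) keep a finite,
    evaluable log-density.
    """
    values = X2.values if isinstance(X2, FeatureMatrix) else np.atleast_2d(np.asarray(X2, float))
    y = as_label_array(y)
    if len(y) != values.shape[0]:
        raise ValidationError("label count does not match epoch count")
    d = values.shape[1]
    means = np.zeros((len(states), d))
    covs = np.zeros((len(states), d, d))
    for k, s in enumerate(states):
        sel = y == s
        if not sel.any():
            raise ValidationError(f"state {s!r} absent from training labels")
        xs = values[sel]
        means[k] = xs.mean(axis=0)
        if xs.shape[0] > 1:
            cov = np.cov(xs, rowvar=False, ddof=1).reshape(d, d)
        else:
            cov = np.zeros((d, d))
        jitter = _COV_JITTER_FACTOR * (np.trace(cov) / d if np.trace(cov) > 0 else 1.0)
        covs[k] = cov + jitter * np.eye(d)
    return GaussianEmission(states=tuple(states), means=means, covariances=covs)


def estimate_transitions(
    y,
    epoch_s: float = 1.0,
    prune_per_s: float = DEFAULT_PRUNE_PER_S,
    states: tuple[str, ...] | None = None,
) -> TransitionModel:
    """Count-and-normalize transition MLE with pruning and renormalization.

    ``y`` may be a single dense label sequence or a list of sequences
    (counts are pooled; no transition is counted across sequence
    boundaries). Labels outside the state set (ambiguous/artefact epochs)
    break the chain: pairs involving them are skipped. After the MLE,
    off-diagonal entries whose per-second probability falls below
    ``prune_per_s`` are zeroed and rows renormalized. The initial
    distribution is the empirical state occupancy.
    """
    if epoch_s <= 0:
        raise ValidationError("epoch_s must be positive")
    seqs = [as_label_array(s) for s in y] if isinstance(y, (list, tuple)) else [as_label_array(y)]
    if sum(len(s) for s in seqs) == 0:
        raise ValidationError("empty label sequence")

    if states is None:
        present: set[str] = set()
        for s in seqs:
            present.update(s.tolist())
        present -= set(EXCLUDED_LABELS)
        inferred = tuple(lbl for lbl in STATES if lbl in present)
        inferred += tuple(sorted(present - set(STATES)))
        states = inferred
        if len(states) < 2:
            raise ValidationError(
                f"only one state ({states}) observed; pass an explicit state set "
                "to allow a single-state model"
            )
    K = len(states)

    counts = np.zeros((K, K))
    occupancy = np.zeros(K)
    for s in seqs:
        idx = labels_to_indices(s, states)
        valid = idx >= 0
        for i in idx[valid]:
            occupancy[i] += 1
        pair_ok = valid[:-1] & valid[1:]
        np.add.at(counts, (idx[:-1][pair_ok], idx[1:][pair_ok]), 1)

    row_totals = counts.sum(axis=1)
    if occupancy.sum() == 0:
        raise ValidationError("no epochs with labels in the state set")
    for k, s in enumerate(states):
        if row_totals[k] == 0:
            raise ValidationError(f"state {s!r} has no observed outgoing transitions")

    A = counts / row_totals[:, None]
    A = prune_transition_matrix(A, epoch_s=epoch_s, prune_per_s=prune_per_s)
    pi = occupancy / occupancy.sum()
    return TransitionModel(
        states=tuple(states),
        initial=pi,
        matrix=A,
        prune_threshold_per_s=prune_per_s,
        epoch_s=epoch_s,
    )


def prune_transition_matrix(
    A: np.ndarray, epoch_s: float = 1.0, prune_per_s: float = DEFAULT_PRUNE_PER_S
) -> np.ndarray:
    """Zero off-diagonal entries below ``prune_per_s`` (per second), renormalize rows.

    A row left with only its diagonal is valid. Row-stochasticity is
    preserved exactly.
    """
    A = np.array(A, dtype=float)
    threshold = prune_per_s * epoch_s
    off = ~np.eye(A.shape[0], dtype=bool)
    A[off & (A < threshold)] = 0.0
    sums = A.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValidationError("pruning removed every entry from a row")
    return A / sums


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def viterbi_from_loglik(log_pi, log_A, loglik) -> np.ndarray:
    """Most probable state index sequence given per-epoch log-likelihoods.

    Runs entirely in the log domain; ties break to the lowest state index
    (i.e. the fixed state order).
    """
    log_pi = np.asarray(log_pi, dtype=float).ravel()
    log_A = np.atleast_2d(np.asarray(log_A, dtype=float))
    loglik = np.atleast_2d(np.asarray(loglik, dtype=float))
    T, K = loglik.shape
    delta = log_pi + loglik[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + log_A  # [from x to]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + loglik[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def forward_backward_from_loglik(log_pi, log_A, loglik) -> tuple[np.ndarray, float]:
    """Per-epoch marginal state probabilities and total log-likelihood.

    Scaled (normalized) forward–backward recursions: emission likelihoods
    are exponentiated after subtracting their per-epoch maximum, and the
    forward variables renormalized at every step, so no intermediate value
    under- or overflows regardless of sequence length.
    """
    log_pi = np.asarray(log_pi, dtype=float).ravel()
    log_A = np.atleast_2d(np.asarray(log_A, dtype=float))
    loglik = np.atleast_2d(np.asarray(loglik, dtype=float))
    T, K = loglik.shape
    with np.errstate(under="ignore"):
        A = np.exp(log_A)
        pi = np.exp(log_pi)
        shift = loglik.max(axis=1)
        B = np.exp(loglik - shift[:, None])  # scaled likelihoods, max 1 per row

        alpha = np.empty((T, K))
        c = np.empty(T)  # per-step normalizers
        a = pi * B[0]
        c[0] = a.sum()
        if c[0] == 0:
            raise ValidationError("zero total likelihood at epoch 0")
        alpha[0] = a / c[0]
        for t in range(1, T):
            a = (alpha[t - 1] @ A) * B[t]
            c[t] = a.sum()
            if c[t] == 0:
                raise ValidationError(f"zero total likelihood at epoch {t}")
            alpha[t] = a / c[t]

        beta = np.empty((T, K))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
    total_loglik = float(np.log(c).sum() + shift.sum())
    return gamma, total_loglik


def _log_params(transitions: TransitionModel) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        return np.log(transitions.initial), np.log(transitions.matrix)


def viterbi_decode(
    transitions: TransitionModel,
    emissions: GaussianEmission,
    X2: FeatureMatrix | np.ndarray,
) -> np.ndarray:
    """Jointly most probable label sequence for component-space features."""
    if transitions.states != emissions.states:
        raise ValidationError("transition and emission state sets differ")
    loglik = emissions.log_likelihood(X2)
    log_pi, log_A = _log_params(transitions)
    path = viterbi_from_loglik(log_pi, log_A, loglik)
    return indices_to_labels(path, transitions.states)


def posterior_probabilities(
    transitions: TransitionModel,
    emissions: GaussianEmission,
    X2: FeatureMatrix | np.ndarray,
) -> PosteriorSequence:
    """Forward–backward marginals plus the Viterbi path."""
    if transitions.states != emissions.states:
        raise ValidationError("transition and emission state sets differ")
    loglik = emissions.log_likelihood(X2)
    log_pi, log_A = _log_params(transitions)
    gamma, _ = forward_backward_from_loglik(log_pi, log_A, loglik)
    path = viterbi_from_loglik(log_pi, log_A, loglik)
    epoch_s = X2.epoch_s if isinstance(X2, FeatureMatrix) else transitions.epoch_s
    return PosteriorSequence(
        probabilities=gamma,
        viterbi_path=indices_to_labels(path, transitions.states),
        states=transitions.states,
        epoch_s=epoch_s,
    )


def naive_bayes_decode(
    emissions: GaussianEmission,
    priors,
    X2: FeatureMatrix | np.ndarray,
) -> np.ndarray:
    """Context-free decode: argmax over states of likelihood x prior."""
    priors = np.asarray(priors, dtype=float).ravel()
    if priors.shape != (len(emissions.states),):
        raise ValidationError("one prior per state required")
    if (priors < 0).any() or abs(priors.sum() - 1.0) > 1e-9:
        raise ValidationError("priors must be non-negative and sum to 1")
    loglik = emissions.log_likelihood(X2)
    with np.errstate(divide="ignore"):
        scores = loglik + np.log(priors)[None, :]
    if np.isneginf(scores).all(axis=1).any():
        raise ValidationError("all states have zero posterior for some epoch")
    return indices_to_labels(np.argmax(scores, axis=1), emissions.states)
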