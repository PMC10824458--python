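"""Certainty thresholding and intermediate-state analysis.

The per-epoch certainty is the posterior probability of the decoded state.
Epochs below a threshold θ (0.995 by default, the change point of the
certainty CDF on the original data; 0.95 as a conservative variant) mark
intermediate states. Maximal runs of such epochs form ambiguous intervals,
which are classified by their context:

* the decoded state differs across the interval -> ``transition_adjacent``
  (uncertainty clustered around a genuine state change);
* the decoded state is the same before, inside and after -> a
  ``failed_transition`` toward the runner-up state whose posterior
  transiently rose;
* intervals touching a recording boundary -> ``boundary_unclassified``.

Failure rates per ordered state pair (failed / (failed + successful)) are
compared between transition types with 2x2 chi-squared contingency tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency

from .errors import ValidationError
from .hmm import PosteriorSequence
from .states import STATES, as_label_array, labels_to_indices

#: Certainty threshold at the CDF change point of the original analysis.
DEFAULT_THRESHOLD = 0.995
#: Conservative variant.
CONSERVATIVE_THRESHOLD = 0.95

TRANSITION_ADJACENT = "transition_adjacent"
FAILED_TRANSITION = "failed_transition"
BOUNDARY_UNCLASSIFIED = "boundary_unclassified"
MIXED_TARGET = "mixed"


@dataclass
class AmbiguousInterval:
    """Maximal run of consecutive epochs with certainty below threshold."""

    start_epoch: int
    end_epoch: int  # half-open
    residual_score: float
    category: str | None = None
    source_state: str | None = None
    target_state: str | None = None

    def __post_init__(self) -> None:
        if self.end_epoch <= self.start_epoch:
            raise ValidationError("interval end must exceed start")
        if self.residual_score <= 0:
            raise ValidationError("residual score must be positive")

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch


@dataclass
class TransitionStats:
    """Counts and failure rates per ordered state pair, plus chi² tests."""

    states: tuple[str, ...]
    successful: np.ndarray  # [K x K] int
    failed: np.ndarray  # [K x K] int
    chi2_tests: list[dict] = field(default_factory=list)

    @property
    def failure_rate(self) -> np.ndarray:
        total = self.successful + self.failed
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(total > 0, self.failed / np.maximum(total, 1), 0.0)
        return rate

    def pair(self, source: str, target: str) -> dict:
        i, j = self.states.index(source), self.states.index(target)
        return {
            "successful": int(self.successful[i, j]),
            "failed": int(self.failed[i, j]),
            "failure_rate": float(self.failure_rate[i, j]),
        }


def select_threshold(post: PosteriorSequence | np.ndarray, mode: str = "fixed") -> float:
    """Choose the certainty threshold.

    ``fixed`` returns 0.995. ``elbow`` locates the knee of the certainty
    CDF as the point of maximum perpendicular distance from the chord
    joining the CDF's endpoints; if all certainties are equal the elbow is
    undefined and the fixed value is returned with a warning.
    """
    certainties = post.certainty() if isinstance(post, PosteriorSequence) else np.asarray(post, float)
    certainties = np.ravel(certainties)
    if len(certainties) == 0:
        raise ValidationError("empty posterior sequence")
    if mode == "fixed":
        return DEFAULT_THRESHOLD
    if mode != "elbow":
        raise ValidationError(f"unknown threshold mode {mode!r}")
    xs = np.sort(certainties)
    if xs[0] == xs[-1]:
        warnings.warn(
            "all certainties equal; elbow undefined, falling back to "
            f"fixed threshold {DEFAULT_THRESHOLD}",
            stacklevel=2,
        )
        return DEFAULT_THRESHOLD
    # empirical CDF over unique values (one point per value, so vertical
    # risers of point masses cannot masquerade as the knee)
    x = np.unique(xs)
    yv = np.searchsorted(xs, x, side="right") / len(xs)
    # perpendicular distance of each CDF point from the end-to-end chord
    p0 = np.array([x[0], 0.0])
    p1 = np.array([x[-1], 1.0])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.stack([x - p0[0], yv - p0[1]], axis=1)
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return float(x[int(np.argmax(dist))])


def extract_ambiguous_intervals(
    post: PosteriorSequence, threshold: float = DEFAULT_THRESHOLD
) -> list[AmbiguousInterval]:
    """Maximal runs of epochs whose decoded-state probability is below θ."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must lie in (0, 1]")
    certainty = post.certainty()
    below = certainty < threshold
    intervals: list[AmbiguousInterval] = []
    t = 0
    T = len(below)
    while t < T:
        if below[t]:
            start = t
            while t < T and below[t]:
                t += 1
            residual = float(np.sum(1.0 - certainty[start:t]))
            intervals.append(
                AmbiguousInterval(start_epoch=start, end_epoch=t, residual_score=residual)
            )
        else:
            t += 1
    return intervals


def classify_ambiguous_intervals(
    intervals: list[AmbiguousInterval], post: PosteriorSequence
) -> list[AmbiguousInterval]:
    """Assign categories in place (and return the list).

    See the module docstring for the rule. The failed-transition target is
    the runner-up state by mean within-interval posterior, provided it
    strictly exceeds the remaining state's; otherwise the target is
    ``mixed`` (probability mass not concentrated in a single rival state).
    """
    T = post.n_epochs
    path = post.viterbi_path
    for iv in intervals:
        if iv.start_epoch < 0 or iv.end_epoch > T:
            raise ValidationError("interval out of range of the posterior sequence")
        if iv.start_epoch == 0 or iv.end_epoch == T:
            iv.category = BOUNDARY_UNCLASSIFIED
            continue
        s_pre = str(path[iv.start_epoch - 1])
        s_post = str(path[iv.end_epoch])
        inside = path[iv.start_epoch : iv.end_epoch]
        if s_pre != s_post or not np.all(inside == s_pre):
            iv.category = TRANSITION_ADJACENT
            iv.source_state = s_pre
            iv.target_state = s_post if s_pre != s_post else None
            continue
        iv.category = FAILED_TRANSITION
        iv.source_state = s_pre
        mean_post = post.probabilities[iv.start_epoch : iv.end_epoch].mean(axis=0)
        rivals = [k for k, s in enumerate(post.states) if s != s_pre]
        order = sorted(rivals, key=lambda k: -mean_post[k])
        if len(order) >= 2 and not mean_post[order[0]] > mean_post[order[1]]:
            iv.target_state = MIXED_TARGET
        else:
            iv.target_state = str(post.states[order[0]])
    return intervals


def transition_failure_stats(
    decoded,
    intervals: list[AmbiguousInterval],
    states: tuple[str, ...] = STATES,
    artefact_spans: list[tuple[int, int]] | None = None,
) -> TransitionStats:
    """Tally successful vs failed transitions and run the contingency tests.

    Successful transitions are decoded label changes (those inside supplied
    artefact spans are ignored). Failed transitions come from
    ``failed_transition`` intervals with a concrete target state. The
    chi-squared comparisons (2x2, no continuity correction) contrast
    failure rates out of NREM vs out of REM, REM->NREM vs REM->awake, and
    NREM->awake vs NREM->REM; a comparison with an empty margin is skipped
    with a notice.
    """
    decoded = as_label_array(decoded)
    idx = labels_to_indices(decoded, states)
    K = len(states)
    successful = np.zeros((K, K), dtype=np.int64)
    in_artefact = np.zeros(len(decoded), dtype=bool)
    for a, b in artefact_spans or []:
        in_artefact[a:b] = True
    for t in range(len(decoded) - 1):
        i, j = idx[t], idx[t + 1]
        if i < 0 or j < 0 or i == j or in_artefact[t] or in_artefact[t + 1]:
            continue
        successful[i, j] += 1

    failed = np.zeros((K, K), dtype=np.int64)
    for iv in intervals:
        if iv.category == FAILED_TRANSITION and iv.target_state in states:
            i = states.index(iv.source_state)
            j = states.index(iv.target_state)
            failed[i, j] += 1

    stats = TransitionStats(states=tuple(states), successful=successful, failed=failed)

    def out_of(state: str) -> tuple[int, int]:
        k = states.index(state)
        return int(failed[k].sum()), int(successful[k].sum())

    def pair_counts(src: str, dst: str) -> tuple[int, int]:
        i, j = states.index(src), states.index(dst)
        return int(failed[i, j]), int(successful[i, j])

    comparisons = [
        ("out_of_NREM_vs_out_of_REM", out_of("NREM"), out_of("REM")),
        ("REM_to_NREM_vs_REM_to_awake", pair_counts("REM", "NREM"), pair_counts("REM", "awake")),
        ("NREM_to_awake_vs_NREM_to_REM", pair_counts("NREM", "awake"), pair_counts("NREM", "REM")),
    ]
    for name, row1, row2 in comparisons:
        table = np.array([row1, row2], dtype=float)
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            stats.chi2_tests.append(
                {"comparison": name, "skipped": True, "reason": "zero margin in contingency table"}
            )
            continue
        chi2, p, _, _ = chi2_contingency(table, correction=False)
        stats.chi2_tests.append(
            {"comparison": name, "statistic": float(chi2), "p_value": float(p), "skipped": False}
        )
    return stats
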