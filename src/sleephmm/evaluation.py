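"""Performance metrics and evaluation harnesses.

Annotations are scored against a reference (typically a multi-rater
consensus) by accuracy, Cohen's kappa and support-weighted F1, computed over
epochs whose reference label is a definite vigilance state — epochs whose
reference is ambiguous or artefact are excluded, while a prediction of an
excluded class against a definite reference counts as an error. The module
also provides the hold-one-out harness (train on all recordings but one,
test on the held-out one) and the label-permutation robustness experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix, f1_score

from .annotation import permute_fraction
from .errors import AlignmentError, ValidationError
from .states import EXCLUDED_LABELS, STATES, as_label_array, labels_to_indices


@dataclass
class EvaluationReport:
    """Metrics comparing a predicted annotation with a reference."""

    labels: tuple[str, ...]
    confusion: np.ndarray  # [true x predicted]
    accuracy: float
    cohens_kappa: float
    weighted_f1: float
    occupancy_pred: dict[str, float]
    occupancy_truth: dict[str, float]
    transition_probability_ratio: np.ndarray  # predicted / reference, smoothed
    n_evaluated: int
    n_excluded: int

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "cohens_kappa": self.cohens_kappa,
            "weighted_f1": self.weighted_f1,
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
        }


def _smoothed_transition_probabilities(y: np.ndarray, states: tuple[str, ...]) -> np.ndarray:
    """Transition MLE with +1 additive smoothing (never zero)."""
    idx = labels_to_indices(y, states)
    K = len(states)
    counts = np.ones((K, K))
    valid = (idx[:-1] >= 0) & (idx[1:] >= 0)
    np.add.at(counts, (idx[:-1][valid], idx[1:][valid]), 1)
    return counts / counts.sum(axis=1, keepdims=True)


def score_annotation(
    pred,
    truth,
    exclude: frozenset[str] = EXCLUDED_LABELS,
    states: tuple[str, ...] = STATES,
) -> EvaluationReport:
    """Score a predicted dense annotation against a reference one."""
    pred = as_label_array(pred)
    truth = as_label_array(truth)
    if len(pred) != len(truth):
        raise AlignmentError(f"length mismatch: {len(pred)} predicted vs {len(truth)} reference")
    mask = ~np.isin(truth.astype(str), list(exclude))
    n_eval = int(mask.sum())
    if n_eval == 0:
        raise ValidationError("no evaluable epochs (all reference labels excluded)")

    p, t = pred[mask].astype(str), truth[mask].astype(str)
    label_set = list(states) + sorted((set(p) | set(t)) - set(states))
    conf = confusion_matrix(t, p, labels=label_set)
    accuracy = float(np.mean(p == t))
    kappa = float(cohen_kappa_score(t, p, labels=label_set)) if len(set(t) | set(p)) > 1 else 1.0
    f1 = float(f1_score(t, p, labels=label_set, average="weighted", zero_division=0))

    occ_pred = {s: float(np.mean(p == s)) for s in states}
    occ_truth = {s: float(np.mean(t == s)) for s in states}
    ratio = _smoothed_transition_probabilities(pred, states) / _smoothed_transition_probabilities(
        truth, states
    )
    return EvaluationReport(
        labels=tuple(label_set),
        confusion=conf,
        accuracy=accuracy,
        cohens_kappa=kappa,
        weighted_f1=f1,
        occupancy_pred=occ_pred,
        occupancy_truth=occ_truth,
        transition_probability_ratio=ratio,
        n_evaluated=n_eval,
        n_excluded=int(len(truth) - n_eval),
    )


def holdout_harness(
    datasets: Sequence[tuple[object, np.ndarray]],
    train_fn: Callable,
    predict_fn: Callable,
) -> list[EvaluationReport]:
    """Hold-one-out evaluation.

    For each dataset ``(inputs, labels)``, a model is trained with
    ``train_fn`` on all *other* datasets and evaluated on the held-out one
    via ``predict_fn(model, inputs) -> dense labels``.
    """
    if len(datasets) < 2:
        raise ValidationError("hold-one-out requires at least 2 datasets")
    reports = []
    for k in range(len(datasets)):
        train_sets = [d for i, d in enumerate(datasets) if i != k]
        model = train_fn(train_sets)
        pred = predict_fn(model, datasets[k][0])
        truth = as_label_array(datasets[k][1])
        pred = as_label_array(pred)
        if len(pred) != len(truth):  # prediction may cover a trimmed span
            n = min(len(pred), len(truth))
            pred, truth = pred[:n], truth[:n]
        reports.append(score_annotation(pred, truth))
    return reports


def mean_accuracy(reports: Sequence[EvaluationReport]) -> tuple[float, float]:
    """Mean ± sd of accuracy across hold-one-out folds."""
    acc = np.array([r.accuracy for r in reports])
    return float(acc.mean()), float(acc.std(ddof=1)) if len(acc) > 1 else 0.0


def robustness_curve(
    datasets: Sequence[tuple[object, np.ndarray]],
    fractions: Sequence[float],
    seed: int,
    train_fn: Callable,
    predict_fn: Callable,
) -> list[dict]:
    """Accuracy as a function of the fraction of permuted training labels.

    For each fraction, every training dataset's labels are independently
    shuffled with :func:`permute_fraction` before training; test labels are
    untouched. Returns one row per fraction with the mean realized
    mislabelled fraction and the hold-one-out mean accuracy.
    """
    if len(datasets) < 2:
        raise ValidationError("robustness experiment requires at least 2 datasets")
    rows = []
    root = np.random.default_rng(seed)
    for fraction in fractions:
        sub_seeds = root.integers(0, 2**31 - 1, size=len(datasets))
        permuted = []
        realized = []
        for (inputs, labels), s in zip(datasets, sub_seeds):
            y2, changed = permute_fraction(labels, fraction, seed=int(s))
            permuted.append((inputs, y2))
            realized.append(changed)
        # train on permuted labels, score against the clean labels
        reports = []
        for k in range(len(datasets)):
            train_sets = [d for i, d in enumerate(permuted) if i != k]
            model = train_fn(train_sets)
            pred = as_label_array(predict_fn(model, datasets[k][0]))
            truth = as_label_array(datasets[k][1])
            n = min(len(pred), len(truth))
            reports.append(score_annotation(pred[:n], truth[:n]))
        mean_acc, sd_acc = mean_accuracy(reports)
        rows.append(
            {
                "fraction": float(fraction),
                "mislabelled_fraction": float(np.mean(realized)),
                "mean_accuracy": mean_acc,
                "sd_accuracy": sd_acc,
            }
        )
    return rows
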