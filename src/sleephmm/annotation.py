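"""Hypnogram algebra: resolution changes, consensus votes, label shuffles.

Manual hypnograms are scored at 4-s resolution while automated annotation
runs at 1 s, so labels must move between epoch grids. Multiple raters are
combined by strict-majority vote (no majority -> ambiguous). The label
shuffle reproduces the perturbation used to probe robustness to training
errors: a random subset of epochs has its labels permuted among themselves,
which preserves the label multiset exactly — in a long sequence with state
occupancies p, shuffling a fraction f of epochs changes an expected
f·(1 − Σ pᵢ²) of all labels.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import AlignmentError, ValidationError
from .states import AMBIGUOUS, as_label_array


def resample_annotation(y, from_epoch_s: float, to_epoch_s: float) -> np.ndarray:
    """Re-grid dense labels between epoch resolutions.

    Upsampling (integral factor) replicates each label; downsampling
    (integral window) takes the within-window plurality, with tied windows
    labelled ``ambiguous``. The sequence length must tile the window.
    """
    if from_epoch_s <= 0 or to_epoch_s <= 0:
        raise ValidationError("epoch durations must be positive")
    y = as_label_array(y)
    if math.isclose(from_epoch_s, to_epoch_s):
        return y.copy()
    if from_epoch_s > to_epoch_s:
        factor = from_epoch_s / to_epoch_s
        if abs(factor - round(factor)) > 1e-9:
            raise ValidationError(f"upsampling factor {factor} is not integral")
        return np.repeat(y, int(round(factor)))
    window = to_epoch_s / from_epoch_s
    if abs(window - round(window)) > 1e-9:
        raise ValidationError(f"downsampling window {window} is not integral")
    window = int(round(window))
    if len(y) % window:
        raise ValidationError(
            f"sequence length {len(y)} does not tile the {window}-epoch window"
        )
    out = np.empty(len(y) // window, dtype=object)
    for i in range(len(out)):
        votes = y[i * window : (i + 1) * window]
        labels, counts = np.unique(votes.astype(str), return_counts=True)
        top = counts.max()
        winners = labels[counts == top]
        out[i] = str(winners[0]) if len(winners) == 1 else AMBIGUOUS
    return out


def consensus_annotation(annotations, min_raters: int = 3) -> np.ndarray:
    """Per-epoch strict-majority vote across raters.

    A label must be chosen by more than half of the raters; otherwise the
    epoch is ``ambiguous``. Invariant to rater order.
    """
    if len(annotations) < min_raters:
        raise ValidationError(
            f"need at least {min_raters} annotations, got {len(annotations)}"
        )
    arrs = [as_label_array(a) for a in annotations]
    n = len(arrs[0])
    for a in arrs[1:]:
        if len(a) != n:
            raise AlignmentError("annotations differ in length")
    stack = np.stack([a.astype(str) for a in arrs])  # [raters x epochs]
    n_raters = stack.shape[0]
    out = np.full(n, AMBIGUOUS, dtype=object)
    for i in range(n):
        labels, counts = np.unique(stack[:, i], return_counts=True)
        j = int(np.argmax(counts))
        if counts[j] * 2 > n_raters:
            out[i] = str(labels[j])
    return out


def permute_fraction(y, fraction: float, seed=None) -> tuple[np.ndarray, float]:
    """Shuffle the labels of a random subset of epochs among themselves.

    ``floor(fraction · n)`` epochs are chosen uniformly without replacement
    and their labels permuted (a shuffle, never a re-draw, so the label
    multiset is preserved exactly). Returns the perturbed labels and the
    realized fraction of epochs whose label changed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction {fraction} outside [0, 1]")
    y = as_label_array(y)
    if len(y) == 0:
        raise ValidationError("empty label sequence")
    rng = np.random.default_rng(seed)
    m = int(math.floor(fraction * len(y)))
    out = y.copy()
    if m >= 2:
        idx = rng.choice(len(y), size=m, replace=False)
        out[idx] = out[idx][rng.permutation(m)]
    changed = float(np.mean(out != y))
    return out, changed
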