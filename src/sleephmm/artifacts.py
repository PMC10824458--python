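"""Recording artefacts and review export.

Gross body movements drive the amplifier outside its dynamic range; such
clipped segments are detected as runs of samples at or beyond the configured
limits, padded on both sides (voltage deflections typically precede and
follow the clipped run itself), and merged. Ambiguous intervals are ranked
for human review by the sum of residual probabilities (one minus the
probability of the decoded state), largest first, so the most suspect
segments surface at the top of the exported CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .uncertainty import AmbiguousInterval

DEFAULT_PAD_S = 1.0


def detect_out_of_range(
    trace,
    fs: float,
    limits: tuple[float, float],
    pad_s: float = DEFAULT_PAD_S,
) -> list[tuple[float, float]]:
    """Find clipped segments: samples <= low or >= high, padded and merged.

    Returns half-open ``(start_s, end_s)`` intervals clipped to the
    recording span. Re-running detection on already-flagged output changes
    nothing (padding-merge idempotence), and total flagged duration is
    non-decreasing in ``pad_s``.
    """
    low, high = limits
    if low >= high:
        raise ValidationError("limits must satisfy low < high")
    if fs <= 0 or pad_s < 0:
        raise ValidationError("fs must be positive and pad_s non-negative")
    trace = np.asarray(trace, dtype=float).ravel()
    clipped = (trace <= low) | (trace >= high)
    if not clipped.any():
        return []
    duration = len(trace) / fs
    runs = []
    t = 0
    n = len(trace)
    while t < n:
        if clipped[t]:
            start = t
            while t < n and clipped[t]:
                t += 1
            runs.append((start, t))
        else:
            t += 1
    intervals = [
        (max(0.0, s / fs - pad_s), min(duration, e / fs + pad_s)) for s, e in runs
    ]
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def rank_intervals_for_review(
    intervals: list[AmbiguousInterval],
) -> list[AmbiguousInterval]:
    """Stable sort by descending residual score; ties by start time."""
    return sorted(intervals, key=lambda iv: (-iv.residual_score, iv.start_epoch))


def write_review_csv(intervals: list[AmbiguousInterval], path, epoch_s: float = 1.0) -> None:
    """Export ranked intervals for human review."""
    ranked = rank_intervals_for_review(intervals)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["start_s", "end_s", "residual_score", "category", "source_state", "target_state"]
        )
        for iv in ranked:
            writer.writerow(
                [
                    iv.start_epoch * epoch_s,
                    iv.end_epoch * epoch_s,
                    f"{iv.residual_score:.6g}",
                    iv.category or "",
                    iv.source_state or "",
                    iv.target_state or "",
                ]
            )
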