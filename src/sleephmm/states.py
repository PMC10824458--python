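"""Vigilance-state vocabulary and label helpers.

The classifier distinguishes three vigilance states — awake, NREM sleep and
REM sleep — plus two bookkeeping labels used by hypnograms: ``ambiguous``
(no clear state, e.g. a tied consensus vote) and ``artefact`` (signal
dominated by movement artefacts). The three-state tuple also fixes the
deterministic tie-break order used throughout (awake < NREM < REM).
"""

from __future__ import annotations

import numpy as np

#: Canonical vigilance states, in tie-break order.
STATES: tuple[str, ...] = ("awake", "NREM", "REM")

AMBIGUOUS = "ambiguous"
ARTEFACT = "artefact"

#: Full hypnogram label vocabulary.
VOCABULARY: tuple[str, ...] = STATES + (AMBIGUOUS, ARTEFACT)

#: Labels whose epochs are excluded from model fitting and scoring.
EXCLUDED_LABELS: frozenset[str] = frozenset({AMBIGUOUS, ARTEFACT})


def as_label_array(y) -> np.ndarray:
    """Coerce a label sequence to a 1-D numpy array of python strings."""
    arr = np.asarray(y, dtype=object).ravel()
    return arr


def labels_to_indices(y, states: tuple[str, ...] = STATES) -> np.ndarray:
    """Map labels to integer state indices; labels outside `states` map to -1."""
    lookup = {s: i for i, s in enumerate(states)}
    y = as_label_array(y)
    return np.array([lookup.get(lbl, -1) for lbl in y], dtype=np.int64)


def indices_to_labels(idx, states: tuple[str, ...] = STATES) -> np.ndarray:
    idx = np.asarray(idx, dtype=np.int64)
    return np.array([states[i] for i in idx], dtype=object)
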