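"""File formats: EDF recordings, hypnogram CSV, and model archives.

Recordings are multichannel electrophysiological traces (EEG/EMG/LFP) at a
common sampling rate, conventionally 256 Hz. Hypnograms are stored as CSV
interval lists ``onset_s,duration_s,label`` with half-open intervals
``[onset, onset + duration)`` in seconds. Trained models are stored as a
single JSON archive holding the projection weights, per-state Gaussian
parameters, transition matrix, initial distribution and the preprocessing
configuration, so a loaded model reproduces the saved model's predictions
bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    FormatError,
    SerializationError,
    ValidationError,
)
from .states import AMBIGUOUS, VOCABULARY, as_label_array

#: Edge region (s) in which missing samples are tolerated: recordings may
#: lack data while the animal is connected to / disconnected from the rig.
EDGE_MISSING_ALLOWANCE_S = 30.0

MODEL_FORMAT = "sleephmm-model"
MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Named signal traces sharing one sampling rate.

    Parameters
    ----------
    channels
        Mapping channel name -> 1-D float trace (amplifier units, µV by
        convention). All traces must have identical length.
    sampling_rate_hz
        Common sampling rate (> 0), default 256.
    missing_mask
        Optional per-sample boolean, True where the sample is missing.
        Missing samples may occur only within the first and/or last 30 s.
    """

    channels: dict[str, np.ndarray]
    sampling_rate_hz: float = 256.0
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if not self.channels:
            raise ValidationError("Recording requires at least one channel")
        self.channels = {k: np.asarray(v, dtype=float).ravel() for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError(f"channel traces differ in length: {sorted(lengths)}")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool).ravel()
            if len(self.missing_mask) != self.n_samples:
                raise ValidationError("missing_mask length does not match traces")
            edge = int(round(EDGE_MISSING_ALLOWANCE_S * self.sampling_rate_hz))
            interior = self.missing_mask[edge : max(edge, self.n_samples - edge)]
            if interior.any():
                raise ValidationError(
                    "missing samples are only permitted within the first/last "
                    f"{EDGE_MISSING_ALLOWANCE_S:g} s of a recording"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass
class StateAnnotation:
    """Hypnogram: sorted, non-overlapping labelled intervals.

    Intervals are ``(onset_s, duration_s, label)`` with labels drawn from the
    closed vocabulary (awake/NREM/REM/ambiguous/artefact) and half-open
    semantics ``[onset, onset + duration)``. ``epoch_s`` is a resolution hint
    (4 s for manual scoring, 1 s for automated).
    """

    intervals: list[tuple[float, float, str]]
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        canon = []
        for onset, duration, label in self.intervals:
            onset, duration = float(onset), float(duration)
            if onset < 0:
                raise ValidationError(f"interval onset {onset} < 0")
            if duration <= 0:
                raise ValidationError(f"interval duration {duration} <= 0")
            if label not in VOCABULARY:
                raise ValidationError(
                    f"unknown label {label!r}; valid labels: {', '.join(VOCABULARY)}"
                )
            canon.append((onset, duration, str(label)))
        canon.sort(key=lambda iv: iv[0])
        for (o1, d1, _), (o2, _, _) in zip(canon, canon[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValidationError(
                    f"overlapping intervals: [{o1}, {o1 + d1}) and onset {o2}"
                )
        self.intervals = canon

    @property
    def end_s(self) -> float:
        if not self.intervals:
            return 0.0
        onset, duration, _ = self.intervals[-1]
        return onset + duration

    def to_dense(self, epoch_s: float | None = None, n_epochs: int | None = None) -> np.ndarray:
        """Expand to one label per epoch over ``[0, end)``.

        Each epoch takes the label of the interval containing its midpoint;
        epochs covered by no interval become ``ambiguous``. With ``n_epochs``
        the expansion is truncated or right-padded (with ``ambiguous``) to
        that length.
        """
        if epoch_s is None:
            epoch_s = self.epoch_s
        if epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        if n_epochs is None:
            n_epochs = int(round(self.end_s / epoch_s))
        mids = (np.arange(n_epochs) + 0.5) * epoch_s
        labels = np.full(n_epochs, AMBIGUOUS, dtype=object)
        for onset, duration, label in self.intervals:
            sel = (mids >= onset) & (mids < onset + duration)
            labels[sel] = label
        return labels

    @classmethod
    def from_dense(
        cls, labels, epoch_s: float = 1.0, start_s: float = 0.0
    ) -> "StateAnnotation":
        """Compress dense epoch labels into merged run-length intervals."""
        labels = as_label_array(labels)
        intervals: list[tuple[float, float, str]] = []
        if len(labels):
            run_start = 0
            for i in range(1, len(labels) + 1):
                if i == len(labels) or labels[i] != labels[run_start]:
                    intervals.append(
                        (
                            start_s + run_start * epoch_s,
                            (i - run_start) * epoch_s,
                            str(labels[run_start]),
                        )
                    )
                    run_start = i
        return cls(intervals=intervals, epoch_s=epoch_s)


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------


def read_recording(
    path,
    channel_map: dict[str, str] | None = None,
    target_rate_hz: float = 256.0,
) -> Recording:
    """Read selected channels from an EDF file, resampled to a common rate.

    Parameters
    ----------
    path
        EDF file path.
    channel_map
        Mapping role -> channel name in the file (e.g. ``{"eeg_anterior":
        "EEG1"}``). ``None`` keeps every channel under its own name.
    target_rate_hz
        Output sampling rate; polyphase resampling is applied when the file's
        native rate differs.

    Returns
    -------
    Recording
        Traces in µV. Leading/trailing flat (constant) segments shorter than
        the 30-s edge allowance, present simultaneously on all channels, are
        flagged in ``missing_mask`` — EDF cannot represent missing samples,
        so disconnected-electrode periods appear as constant fill values.
    """
    import mne
    from scipy.signal import resample_poly

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if target_rate_hz <= 0:
        raise ValidationError("target_rate_hz must be positive")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted errors on malformed files
        raise FormatError(f"{path} is not a readable EDF file: {exc}") from exc

    available = list(raw.ch_names)
    if channel_map is None:
        channel_map = {name: name for name in available}
    for role, name in channel_map.items():
        if name not in available:
            raise ConfigurationError(
                f"channel {name!r} (role {role!r}) not in file; "
                f"available channels: {', '.join(available)}"
            )

    native_rate = float(raw.info["sfreq"])
    data = raw.get_data(picks=[channel_map[r] for r in channel_map]) * 1e6  # V -> µV

    if abs(native_rate - target_rate_hz) > 1e-9:
        ratio = Fraction(target_rate_hz / native_rate).limit_denominator(10000)
        data = resample_poly(data, ratio.numerator, ratio.denominator, axis=1)

    channels = {role: data[i] for i, role in enumerate(channel_map)}
    mask = _detect_edge_missing(np.vstack(list(channels.values())), target_rate_hz)
    return Recording(channels=channels, sampling_rate_hz=target_rate_hz, missing_mask=mask)


def _detect_edge_missing(data: np.ndarray, fs: float) -> np.ndarray | None:
    """Flag leading/trailing runs that are constant on every channel."""
    n = data.shape[1]
    edge = int(round(EDGE_MISSING_ALLOWANCE_S * fs))
    mask = np.zeros(n, dtype=bool)
    changed = np.abs(np.diff(data, axis=1)).max(axis=0) > 0  # (n-1,)
    # leading flat run: samples 0..k are missing if no channel changes before k
    lead = 0
    while lead < min(edge, n - 1) and not changed[lead]:
        lead += 1
    if lead >= int(fs):  # require at least 1 s of flatline to call it missing
        mask[: lead + 1] = True
    trail = 0
    while trail < min(edge, n - 1) and not changed[n - 2 - trail]:
        trail += 1
    if trail >= int(fs):
        mask[n - 1 - trail :] = True
    return mask if mask.any() else None


def write_recording(recording: Recording, path) -> None:
    """Write a :class:`Recording` as a minimal EDF file (µV, int16).

    One 1-s data record per second; each trace is scaled to the int16 digital
    range from its own physical min/max, so the round-trip error is bounded
    by the format quantization step. Missing samples are stored as zeros
    (EDF has no missing-value notion); the mask itself is not persisted.
    """
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    names = list(recording.channels)
    n_records = recording.n_samples // spr
    if n_records * spr != recording.n_samples:
        raise ValidationError("EDF writer requires a whole number of 1-s records")
    digmin, digmax = -32768, 32767

    scaled, phys = {}, {}
    for name in names:
        x = np.nan_to_num(recording.channels[name], nan=0.0)
        pmin, pmax = float(np.min(x)), float(np.max(x))
        if pmax == pmin:
            pmax = pmin + 1.0
        phys[name] = (pmin, pmax)
        d = (x - pmin) / (pmax - pmin) * (digmax - digmin) + digmin
        scaled[name] = np.round(d).astype("<i2")

    def pad(s, width):
        b = str(s).encode("ascii")[:width]
        return b + b" " * (width - len(b))

    n_sig = len(names)
    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2000 X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(256 + 256 * n_sig, 8),
            pad("", 44),
            pad(n_records, 8),
            pad("1", 8),
            pad(n_sig, 4),
        ]
    )
    header += b"".join(pad(n, 16) for n in names)
    header += b"".join(pad("", 80) for _ in names)
    header += b"".join(pad("uV", 8) for _ in names)
    header += b"".join(pad("%.8g" % phys[n][0], 8) for n in names)
    header += b"".join(pad("%.8g" % phys[n][1], 8) for n in names)
    header += b"".join(pad(digmin, 8) for _ in names)
    header += b"".join(pad(digmax, 8) for _ in names)
    header += b"".join(pad("", 80) for _ in names)
    header += b"".join(pad(spr, 8) for _ in names)
    header += b"".join(pad("", 32) for _ in names)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for name in names:
                fh.write(scaled[name][r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["onset_s", "duration_s", "label"]


def read_annotation(path) -> StateAnnotation:
    """Read a hypnogram CSV (``onset_s,duration_s,label``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; expected {_ANNOTATION_COLUMNS}")
    intervals = [
        (float(r.onset_s), float(r.duration_s), str(r.label)) for r in df.itertuples()
    ]
    return StateAnnotation(intervals=intervals)


def write_annotation(annotation: StateAnnotation, path) -> None:
    """Write a hypnogram CSV; ``write ∘ read`` is the identity."""
    df = pd.DataFrame(annotation.intervals, columns=_ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------


def save_model(model, path) -> None:
    """Serialize a fitted :class:`~sleephmm.pipeline.TrainedModel` to JSON."""
    payload = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "model": model.to_dict(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Load a model archive written by :func:`save_model`.

    Raises :class:`SerializationError` on truncated/corrupted content or a
    format-version mismatch; no partially constructed model is returned.
    """
    from .pipeline import TrainedModel

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SerializationError(f"{path}: not a valid model archive: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise SerializationError(f"{path}: not a {MODEL_FORMAT} archive")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise SerializationError(
            f"{path}: archive version {payload.get('format_version')} "
            f"!= supported version {MODEL_FORMAT_VERSION}"
        )
    try:
        return TrainedModel.from_dict(payload["model"])
    except (KeyError, TypeError, ValueError) as exc:
        raise SerializationError(f"{path}: corrupt model payload: {exc}") from exc
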