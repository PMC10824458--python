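"""Raw traces -> per-epoch normalized spectral features.

Each trace is cut into non-overlapping epochs (default 1 s) and converted to
a multitaper power spectrogram. Frequency bands dominated by non-vigilance
signals (locomotion drift below 0.5 Hz, mains interference at 45–55 Hz and
above 90 Hz) are discarded. Power values — approximately exponentially
distributed in EEG/EMG — are mapped through log(x + 1) toward normality and
standardized per frequency bin to z-scores, so every retained frequency
carries equal weight in the downstream discriminant analysis. The normalized
per-channel blocks are finally concatenated into one high-dimensional
feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ValidationError

#: Default exclusion bands (Hz); ``None`` upper bound means "to Nyquist".
DEFAULT_EXCLUDE_BANDS: tuple[tuple[float, float | None], ...] = (
    (0.0, 0.5),
    (45.0, 55.0),
    (90.0, None),
)

#: Effective multitaper parameters (1-s windows, no overlap, library
#: defaults otherwise); recorded in the model archive for reproducibility.
MULTITAPER_PARAMS = {
    "segment_s": 1.0,
    "overlap": 0.0,
    "half_bandwidth_product": 4.0,
    "n_tapers": 7,
    "adaptive": False,
}

_CHUNK_EPOCHS = 8192  # bound the working memory of the taper FFTs


@dataclass
class Spectrogram:
    """Per-epoch power spectrum of one channel.

    ``power`` is [frequency x epoch] and non-negative prior to
    normalization; ``excluded`` flags epochs overlapping missing samples.
    """

    frequencies_hz: np.ndarray
    epoch_times_s: np.ndarray
    power: np.ndarray
    channel: str = ""
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float).ravel()
        self.epoch_times_s = np.asarray(self.epoch_times_s, dtype=float).ravel()
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.frequencies_hz), len(self.epoch_times_s)):
            raise ValidationError(
                f"power shape {self.power.shape} does not match "
                f"{len(self.frequencies_hz)} frequencies x {len(self.epoch_times_s)} epochs"
            )
        if self.excluded is None:
            self.excluded = np.zeros(len(self.epoch_times_s), dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool).ravel()
            if len(self.excluded) != len(self.epoch_times_s):
                raise ValidationError("excluded mask length does not match epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_times_s)

    @property
    def epoch_s(self) -> float:
        if len(self.epoch_times_s) > 1:
            return float(self.epoch_times_s[1] - self.epoch_times_s[0])
        return 1.0


@dataclass
class FeatureMatrix:
    """[epoch x feature] matrix with names and an epoch exclusion mask."""

    values: np.ndarray
    feature_names: list[str]
    epoch_s: float = 1.0
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be 2-D [epoch x feature]")
        if self.values.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length does not match columns")
        if self.excluded is None:
            self.excluded = np.zeros(self.values.shape[0], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool).ravel()
            if len(self.excluded) != self.values.shape[0]:
                raise ValidationError("excluded mask length does not match epochs")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def compute_spectrogram(
    trace,
    fs: float,
    epoch_s: float = 1.0,
    channel: str = "",
    missing_mask=None,
) -> Spectrogram:
    """Multitaper power spectrogram over non-overlapping epochs.

    The frequency grid runs from 0 to fs/2 at 1/epoch_s spacing. Trailing
    samples that do not fill a whole epoch are dropped. Epochs overlapping
    missing samples (or non-finite values) are flagged as excluded.
    """
    from mne.time_frequency import psd_array_multitaper

    trace = np.asarray(trace, dtype=float).ravel()
    if fs <= 0 or epoch_s <= 0:
        raise ValidationError("fs and epoch_s must be positive")
    n_per = int(round(fs * epoch_s))
    n_epochs = len(trace) // n_per
    if n_epochs < 1:
        raise ValidationError(
            f"trace of {len(trace)} samples is shorter than one epoch ({n_per} samples)"
        )

    segments = trace[: n_epochs * n_per].reshape(n_epochs, n_per)
    excluded = ~np.isfinite(segments).all(axis=1)
    if missing_mask is not None:
        missing = np.asarray(missing_mask, dtype=bool).ravel()[: n_epochs * n_per]
        missing = np.pad(missing, (0, n_epochs * n_per - len(missing)))
        excluded |= missing.reshape(n_epochs, n_per).any(axis=1)
    segments = np.nan_to_num(segments, nan=0.0, posinf=0.0, neginf=0.0)

    psd_chunks = []
    freqs = None
    for start in range(0, n_epochs, _CHUNK_EPOCHS):
        psd, freqs = psd_array_multitaper(
            segments[start : start + _CHUNK_EPOCHS], fs, verbose="error"
        )
        psd_chunks.append(psd)
    power = np.vstack(psd_chunks).T  # [freq x epoch]

    return Spectrogram(
        frequencies_hz=freqs,
        epoch_times_s=np.arange(n_epochs) * epoch_s,
        power=power,
        channel=channel,
        excluded=excluded,
    )


def apply_frequency_mask(
    spec: Spectrogram,
    exclude: tuple[tuple[float, float | None], ...] = DEFAULT_EXCLUDE_BANDS,
) -> Spectrogram:
    """Drop frequency rows inside any excluded band (inclusive bounds).

    An upper bound of ``None`` extends the band to the Nyquist frequency.
    The epoch (column) count is unchanged; removing every row is an error.
    """
    nyquist = float(spec.frequencies_hz[-1])
    keep = np.ones(len(spec.frequencies_hz), dtype=bool)
    for low, high in exclude:
        if high is None:
            high = nyquist
        if low < 0 or high > nyquist + 1e-9:
            raise ValidationError(f"exclusion band ({low}, {high}) outside [0, {nyquist}]")
        keep &= ~((spec.frequencies_hz >= low) & (spec.frequencies_hz <= high))
    if not keep.any():
        raise ValidationError("frequency mask excludes the entire grid")
    return Spectrogram(
        frequencies_hz=spec.frequencies_hz[keep],
        epoch_times_s=spec.epoch_times_s,
        power=spec.power[keep],
        channel=spec.channel,
        excluded=spec.excluded.copy(),
    )


def log_z_normalize(spec: Spectrogram, exclude_epochs=None) -> FeatureMatrix:
    """log(x + 1) then per-frequency z-scoring -> FeatureMatrix.

    Standardization statistics are computed over non-excluded epochs only
    (per recording); zero-variance rows map to all-zeros. Output rows are
    epochs, columns are ``channel:frequency`` features.
    """
    if np.any(spec.power < 0):
        raise ValidationError("power values must be non-negative before normalization")
    if exclude_epochs is None:
        exclude_epochs = spec.excluded
    exclude_epochs = np.asarray(exclude_epochs, dtype=bool).ravel()
    if len(exclude_epochs) != spec.n_epochs:
        raise ValidationError("exclude_epochs length does not match epochs")
    if exclude_epochs.all():
        raise ValidationError("every epoch is excluded; cannot compute statistics")

    logged = np.log1p(spec.power)  # [freq x epoch]
    ref = logged[:, ~exclude_epochs]
    mean = ref.mean(axis=1, keepdims=True)
    sd = ref.std(axis=1, keepdims=True)
    z = np.zeros_like(logged)
    nonzero = sd[:, 0] > 0
    z[nonzero] = (logged[nonzero] - mean[nonzero]) / sd[nonzero]

    prefix = f"{spec.channel}:" if spec.channel else ""
    names = [f"{prefix}{f:g}Hz" for f in spec.frequencies_hz]
    epoch_s = (
        float(spec.epoch_times_s[1] - spec.epoch_times_s[0])
        if spec.n_epochs > 1
        else 1.0
    )
    return FeatureMatrix(
        values=z.T,
        feature_names=names,
        epoch_s=epoch_s,
        excluded=exclude_epochs.copy(),
    )


def assemble_features(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-channel normalized blocks along the feature axis.

    All blocks must share the epoch grid; the per-block exclusion masks are
    OR-combined so an epoch missing on any channel is excluded overall.
    """
    if not blocks:
        raise ValidationError("no feature blocks to assemble")
    n_epochs = blocks[0].n_epochs
    epoch_s = blocks[0].epoch_s
    for b in blocks[1:]:
        if b.n_epochs != n_epochs:
            raise AlignmentError(
                f"feature blocks disagree on epoch count: {n_epochs} vs {b.n_epochs}"
            )
        if abs(b.epoch_s - epoch_s) > 1e-9:
            raise AlignmentError("feature blocks disagree on epoch duration")
    values = np.hstack([b.values for b in blocks])
    names = [n for b in blocks for n in b.feature_names]
    excluded = np.zeros(n_epochs, dtype=bool)
    for b in blocks:
        excluded |= b.excluded
    return FeatureMatrix(values=values, feature_names=names, epoch_s=epoch_s, excluded=excluded)
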