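"""End-to-end orchestration: train a classifier, annotate recordings.

Training chains the stages: per-recording multitaper spectrograms with
frequency masks and log-z normalization, pooled LDA fit, then supervised
estimation of the Gaussian emissions and the pruned transition matrix
(annotations are brought to the working epoch resolution first).
Prediction preprocesses a recording with the stored configuration, projects
it, and returns the Viterbi annotation together with per-epoch posterior
probabilities, the ambiguous intervals ranked for review, and the fraction
of epochs below the certainty threshold. The only user-facing free
parameter is the epoch resolution; everything else carries recorded
defaults in the model archive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hmm as _hmm
from .artifacts import rank_intervals_for_review
from .errors import ConfigurationError, ValidationError
from .features import LDAProjection, fit_lda, project
from .io import EDGE_MISSING_ALLOWANCE_S, Recording, StateAnnotation
from .preprocess import (
    DEFAULT_EXCLUDE_BANDS,
    MULTITAPER_PARAMS,
    FeatureMatrix,
    apply_frequency_mask,
    assemble_features,
    compute_spectrogram,
    log_z_normalize,
)
from .states import AMBIGUOUS, EXCLUDED_LABELS, STATES, as_label_array
from .uncertainty import (
    DEFAULT_THRESHOLD,
    AmbiguousInterval,
    classify_ambiguous_intervals,
    extract_ambiguous_intervals,
)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Recorded preprocessing / decoding configuration."""

    epoch_s: float = 1.0
    channels: tuple[str, ...] = ("eeg_anterior", "eeg_posterior", "emg")
    exclude_bands: tuple[tuple[float, float | None], ...] = DEFAULT_EXCLUDE_BANDS
    states: tuple[str, ...] = STATES
    prune_per_s: float = _hmm.DEFAULT_PRUNE_PER_S
    certainty_threshold: float = DEFAULT_THRESHOLD
    threshold_mode: str = "fixed"
    multitaper: dict = field(default_factory=lambda: dict(MULTITAPER_PARAMS))

    def to_dict(self) -> dict:
        return {
            "epoch_s": self.epoch_s,
            "channels": list(self.channels),
            "exclude_bands": [list(b) for b in self.exclude_bands],
            "states": list(self.states),
            "prune_per_s": self.prune_per_s,
            "certainty_threshold": self.certainty_threshold,
            "threshold_mode": self.threshold_mode,
            "multitaper": dict(self.multitaper),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            epoch_s=float(d["epoch_s"]),
            channels=tuple(d["channels"]),
            exclude_bands=tuple(
                (float(lo), None if hi is None else float(hi)) for lo, hi in d["exclude_bands"]
            ),
            states=tuple(d["states"]),
            prune_per_s=float(d["prune_per_s"]),
            certainty_threshold=float(d["certainty_threshold"]),
            threshold_mode=str(d["threshold_mode"]),
            multitaper=dict(d["multitaper"]),
        )


@dataclass
class TrainedModel:
    """All fitted components plus provenance, mutually consistent."""

    config: PipelineConfig
    projection: LDAProjection
    emissions: _hmm.GaussianEmission
    transitions: _hmm.TransitionModel
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.emissions.states != self.transitions.states:
            raise ValidationError("emission and transition state sets differ")
        if self.emissions.ndim != self.projection.n_components:
            raise ValidationError("emission dimension does not match projection components")

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "config": self.config.to_dict(),
            "projection": self.projection.to_dict(),
            "emissions": self.emissions.to_dict(),
            "transitions": self.transitions.to_dict(),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            config=PipelineConfig.from_dict(d["config"]),
            projection=LDAProjection.from_dict(d["projection"]),
            emissions=_hmm.GaussianEmission.from_dict(d["emissions"]),
            transitions=_hmm.TransitionModel.from_dict(d["transitions"]),
            provenance=dict(d.get("provenance", {})),
        )


@dataclass
class PredictionResult:
    """Prediction output for one recording."""

    annotation: StateAnnotation
    posterior: _hmm.PosteriorSequence
    intervals: list[AmbiguousInterval]
    fraction_below_threshold: float
    start_epoch: int  # offset of the decoded span within the recording


def preprocess_recording(recording: Recording, config: PipelineConfig) -> FeatureMatrix:
    """Spectrogram -> mask -> log-z per channel, concatenated across channels."""
    blocks = []
    for ch in config.channels:
        if ch not in recording.channels:
            raise ConfigurationError(
                f"channel {ch!r} missing from recording; available: "
                f"{', '.join(recording.channel_names)}"
            )
        spec = compute_spectrogram(
            recording.channels[ch],
            fs=recording.sampling_rate_hz,
            epoch_s=config.epoch_s,
            channel=ch,
            missing_mask=recording.missing_mask,
        )
        spec = apply_frequency_mask(spec, config.exclude_bands)
        blocks.append(log_z_normalize(spec))
    return assemble_features(blocks)


def _dense_labels_for(
    annotation: StateAnnotation, config: PipelineConfig, n_epochs: int, duration_s: float
) -> np.ndarray:
    """Annotation -> dense labels on the working epoch grid, with coverage check."""
    uncovered = duration_s - annotation.end_s
    if uncovered > EDGE_MISSING_ALLOWANCE_S + 1e-6:
        raise ValidationError(
            f"annotation covers {annotation.end_s:g} s of a {duration_s:g} s recording; "
            f"shortfall exceeds the {EDGE_MISSING_ALLOWANCE_S:g} s edge allowance"
        )
    return annotation.to_dense(epoch_s=config.epoch_s, n_epochs=n_epochs)


def train_from_features(
    features: list[FeatureMatrix],
    labels: list[np.ndarray],
    config: PipelineConfig | None = None,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit LDA + HMM from preprocessed per-recording features and dense labels."""
    config = config or PipelineConfig()
    if len(features) != len(labels):
        raise ValidationError("features and labels lists differ in length")
    ys = [as_label_array(y) for y in labels]
    for X, y in zip(features, ys):
        if X.n_epochs != len(y):
            raise ValidationError("feature epochs and label count differ within a recording")

    pooled_X = np.vstack([X.values for X in features])
    pooled_y = np.concatenate(ys)
    pooled_ok = np.concatenate(
        [~X.excluded for X in features]
    ) & np.isin(pooled_y.astype(str), list(config.states))

    if not pooled_ok.any():
        raise ValidationError("no usable training epochs")
    projection = fit_lda(pooled_X[pooled_ok], pooled_y[pooled_ok])

    Z = pooled_X[pooled_ok] @ projection.weights
    emissions = _hmm.estimate_emissions(Z, pooled_y[pooled_ok], states=config.states)

    # transitions per recording (no counting across recording boundaries);
    # excluded epochs break the chain
    seqs = []
    for X, y in zip(features, ys):
        y_fit = y.copy()
        y_fit[X.excluded] = AMBIGUOUS
        seqs.append(y_fit)
    transitions = _hmm.estimate_transitions(
        seqs, epoch_s=config.epoch_s, prune_per_s=config.prune_per_s, states=config.states
    )
    return TrainedModel(
        config=config,
        projection=projection,
        emissions=emissions,
        transitions=transitions,
        provenance=provenance or {},
    )


def train(
    recordings: list[Recording],
    annotations: list[StateAnnotation],
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """Train from raw recordings and hypnograms. Deterministic given inputs."""
    config = config or PipelineConfig()
    if len(recordings) != len(annotations):
        raise ValidationError("recordings and annotations lists differ in length")
    if not recordings:
        raise ValidationError("no training recordings")
    features, labels = [], []
    for rec, ann in zip(recordings, annotations):
        X = preprocess_recording(rec, config)
        features.append(X)
        labels.append(_dense_labels_for(ann, config, X.n_epochs, rec.duration_s))
    provenance = {
        "n_training_recordings": len(recordings),
        "seed": seed,
        "version": __version__,
    }
    return train_from_features(features, labels, config, provenance)


def predict_from_features(model: TrainedModel, X: FeatureMatrix) -> PredictionResult:
    """Decode preprocessed features with a trained model."""
    Z = project(model.projection, X)
    ok = ~Z.excluded
    if not ok.any():
        raise ValidationError("no decodable epochs (all excluded)")
    start = int(np.argmax(ok))
    end = len(ok) - int(np.argmax(ok[::-1]))
    if not ok[start:end].all():
        raise ValidationError("excluded epochs must form edge regions only")

    span = FeatureMatrix(
        values=Z.values[start:end],
        feature_names=Z.feature_names,
        epoch_s=Z.epoch_s,
        excluded=np.zeros(end - start, dtype=bool),
    )
    posterior = _hmm.posterior_probabilities(model.transitions, model.emissions, span)
    threshold = model.config.certainty_threshold
    intervals = extract_ambiguous_intervals(posterior, threshold)
    classify_ambiguous_intervals(intervals, posterior)
    intervals = rank_intervals_for_review(intervals)
    fraction_below = float(np.mean(posterior.certainty() < threshold))
    annotation = StateAnnotation.from_dense(
        posterior.viterbi_path, epoch_s=model.config.epoch_s, start_s=start * model.config.epoch_s
    )
    return PredictionResult(
        annotation=annotation,
        posterior=posterior,
        intervals=intervals,
        fraction_below_threshold=fraction_below,
        start_epoch=start,
    )


def predict(model: TrainedModel, recording: Recording) -> PredictionResult:
    """Preprocess and decode a recording with a trained model."""
    X = preprocess_recording(recording, model.config)
    return predict_from_features(model, X)
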