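"""Targeted dimensionality reduction via linear discriminant analysis.

LDA projects the high-dimensional spectral features onto K−1 discriminant
components (two, for the three vigilance states) chosen to maximize
between-class relative to within-class scatter. In the whitened discriminant
space produced by the eigen solver, the LDA classification rule reduces to
nearest class mean plus a log-prior term; that rule doubles as the
context-free "LDA classifier" baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import ValidationError
from .preprocess import FeatureMatrix
from .states import STATES, as_label_array


@dataclass
class LDAProjection:
    """Fitted discriminant projection.

    ``weights`` is [input-features x components] (components = #classes − 1);
    ``class_means`` are the class centroids in component space, where the
    pooled within-class covariance is whitened to the identity.
    """

    weights: np.ndarray
    class_means: np.ndarray
    class_labels: tuple[str, ...]
    log_priors: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.class_means = np.asarray(self.class_means, dtype=float)
        self.log_priors = np.asarray(self.log_priors, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValidationError("projection weights must be finite")
        if self.weights.shape[1] != len(self.class_labels) - 1:
            raise ValidationError("components must equal number of classes - 1")

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def component_names(self) -> list[str]:
        return [f"LD{i + 1}" for i in range(self.n_components)]

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "class_means": self.class_means.tolist(),
            "class_labels": list(self.class_labels),
            "log_priors": self.log_priors.tolist(),
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAProjection":
        return cls(
            weights=np.array(d["weights"], dtype=float),
            class_means=np.array(d["class_means"], dtype=float),
            class_labels=tuple(d["class_labels"]),
            log_priors=np.array(d["log_priors"], dtype=float),
            feature_names=d.get("feature_names"),
        )


def _ordered_classes(y: np.ndarray) -> tuple[str, ...]:
    """Present classes in canonical state order, then any extras sorted."""
    present = set(y.tolist())
    ordered = [s for s in STATES if s in present]
    ordered += sorted(present - set(STATES))
    return tuple(ordered)


def fit_lda(X: FeatureMatrix | np.ndarray, y) -> LDAProjection:
    """Fit the discriminant projection on labelled epochs.

    Requires at least two distinct labels, each supported by at least two
    epochs. Deterministic given its input (eigen solver, no shrinkage).
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    names = X.feature_names if isinstance(X, FeatureMatrix) else None
    y = as_label_array(y)
    if len(y) != values.shape[0]:
        raise ValidationError("label count does not match epoch count")

    classes = _ordered_classes(y)
    if len(classes) < 2:
        raise ValidationError(f"LDA requires >= 2 classes, got {classes}")
    for c in classes:
        if int((y == c).sum()) < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 epochs")
    if values.shape[0] < len(classes):
        raise ValidationError("fewer epochs than classes")

    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=None)
    lda.fit(values, y.astype(str))

    # Re-order sklearn's (lexicographic) classes to the canonical state order.
    order = [list(lda.classes_).index(c) for c in classes]
    weights = lda.scalings_[:, : len(classes) - 1]
    class_means = (lda.means_ @ weights)[order]
    priors = lda.priors_[order]
    return LDAProjection(
        weights=weights,
        class_means=class_means,
        class_labels=classes,
        log_priors=np.log(priors),
        feature_names=names,
    )


def project(proj: LDAProjection, X: FeatureMatrix | np.ndarray) -> FeatureMatrix:
    """Project features into (LD1, LD2, ...) component space.

    The map is linear, so epoch count is preserved and affine combinations
    of inputs map to the same combinations of outputs.
    """
    if isinstance(X, FeatureMatrix):
        values, epoch_s, excluded = X.values, X.epoch_s, X.excluded.copy()
    else:
        values = np.asarray(X, dtype=float)
        epoch_s, excluded = 1.0, None
    if values.shape[1] != proj.weights.shape[0]:
        raise ValidationError(
            f"feature count {values.shape[1]} does not match projection input "
            f"dimension {proj.weights.shape[0]}"
        )
    return FeatureMatrix(
        values=values @ proj.weights,
        feature_names=proj.component_names,
        epoch_s=epoch_s,
        excluded=excluded,
    )


def lda_classify(proj: LDAProjection, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-epoch LDA classification (no temporal context).

    In whitened component space the discriminant score of class k is
    −||z − m_k||²/2 + log π_k; ties resolve to the first class in the fixed
    state order.
    """
    Z = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if Z.shape[1] == proj.weights.shape[0] and Z.shape[1] != proj.n_components:
        Z = Z @ proj.weights
    elif Z.shape[1] != proj.n_components:
        Z = project(proj, Z).values
    d2 = ((Z[:, None, :] - proj.class_means[None, :, :]) ** 2).sum(axis=2)
    scores = -0.5 * d2 + proj.log_priors[None, :]
    idx = np.argmax(scores, axis=1)  # first max wins -> state-order tie-break
    labels = np.array(proj.class_labels, dtype=object)
    return labels[idx]
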