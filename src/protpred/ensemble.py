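"""Training-accuracy-weighted ensemble of the four predictors.

Per (protein, fold), each method's weight is its training-set Pearson
correlation clipped at zero (an anti-predictive model must not flip signs),
normalized to sum to one over the methods that produced usable predictions.
If every clipped weight is zero the usable methods share equal weight.
Failed methods are excluded with renormalization rather than failing the
ensemble; the ensemble itself fails only when every component did.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ValidationError


class EnsembleFailure(RuntimeError):
    """All component methods failed for this (protein, fold)."""


@dataclass(frozen=True)
class EnsembleWeights:
    """Normalized per-method weights for one (protein, fold)."""

    weights: dict[str, float]
    train_correlations: dict[str, float]

    def __post_init__(self) -> None:
        usable = {m: w for m, w in self.weights.items() if w > 0}
        if usable and abs(sum(usable.values()) - 1.0) > 1e-9:
            raise ValidationError("positive weights must sum to 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be >= 0")


def ensemble_weights(
    train_correlations: dict[str, float],
    failed: set[str] | None = None,
) -> EnsembleWeights:
    """Weights from per-method training correlations.

    ``failed`` methods get weight 0 regardless of their correlation; an
    undefined (NaN) training correlation counts as 0 before clipping.
    """
    failed = failed or set()
    usable = [m for m in train_correlations if m not in failed]
    if not usable:
        raise EnsembleFailure("no method produced training predictions")
    clipped = {}
    for m in train_correlations:
        if m in failed:
            clipped[m] = 0.0
        else:
            r = train_correlations[m]
            clipped[m] = max(float(r), 0.0) if np.isfinite(r) else 0.0
    total = sum(clipped.values())
    if total > 0:
        weights = {m: w / total for m, w in clipped.items()}
    else:  # nothing positively predictive on train: spread equally
        weights = {m: (1.0 / len(usable) if m in usable else 0.0)
                   for m in train_correlations}
    return EnsembleWeights(weights=weights,
                           train_correlations=dict(train_correlations))


def ensemble_predict(
    predictions: dict[str, np.ndarray], weights: EnsembleWeights
) -> np.ndarray:
    """Elementwise convex combination over methods with positive weight."""
    active = {m: w for m, w in weights.weights.items() if w > 0}
    if not active:
        raise EnsembleFailure("no method carries positive weight")
    lengths = {len(np.asarray(predictions[m])) for m in active}
    if len(lengths) != 1:
        raise ValidationError("prediction vectors are not aligned")
    out = np.zeros(lengths.pop())
    for m, w in active.items():
        vec = np.asarray(predictions[m], dtype=float)
        if np.isnan(vec).any():
            raise ValidationError(f"method {m!r} has NaN predictions but weight > 0")
        out += w * vec
    return out
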