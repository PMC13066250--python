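"""Forward values of segmentation loss functions.

These are the training objectives whose pairing produces diverse model
variants for the ensemble: cross-entropy and its hard-pixel Top-K variant
(distribution-based), Dice and Generalized Dice (region-based), and their
hybrid sums.  Only forward evaluation is provided — enough to characterize
predictions; no gradients or training loops.

Notation: s_ic is the predicted probability of voxel i for class c, g_ic the
one-hot ground-truth indicator, N the voxel count, C the class count.

The Top-K loss averages the per-voxel cross-entropy over the top K% hardest
voxels (largest per-voxel CE), so K = 100% recovers plain cross-entropy
exactly.  Ties at the selection boundary include every tied voxel.

Both region losses carry a symmetric epsilon (1e-5) in numerator and
denominator so the empty-class case is defined; the epsilon placement is
identical in Dice and Generalized Dice, making them exactly equal under
uniform class weights.  Values are clipped below at 0, where the raw ratio
can undershoot by O(epsilon) on perfect predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import OneHotField, ProbabilityField, check_same_grid

__all__ = [
    "ClassWeights",
    "loss_ce",
    "loss_topk",
    "loss_dice",
    "loss_gdice",
    "loss_hybrid",
    "HYBRID_NAMES",
]

#: clamp on predicted probabilities inside logs
_LOG_CLAMP = 1e-12

#: smoothing epsilon of the region-based losses
REGION_EPS = 1e-5

HYBRID_NAMES = ("ce+dice", "topk+dice", "ce+gdice")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class weights w_c for the Generalized Dice loss.

    The default scheme is inverse squared class volume,
    w_c = 1 / (sum_i g_ic + eps)^2, which rebalances the loss toward rare
    classes; exponent 1 (plain inverse frequency) is available.
    """

    w: np.ndarray
    epsilon: float = REGION_EPS

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        if self.w.ndim != 1 or np.any(self.w < 0) or not np.any(self.w > 0):
            raise ValueError("class weights must be 1D, non-negative, not all zero")

    @classmethod
    def inverse_volume(cls, truth: OneHotField, exponent: int = 2) -> "ClassWeights":
        volumes = truth.values.reshape(-1, truth.n_classes).sum(axis=0).astype(float)
        return cls(w=1.0 / (volumes + REGION_EPS) ** exponent)


def _flat(prediction: ProbabilityField, truth: OneHotField) -> tuple[np.ndarray, np.ndarray]:
    check_same_grid([prediction, truth])
    if prediction.n_classes != truth.n_classes:
        raise ValueError(
            f"class count mismatch: prediction C={prediction.n_classes}, truth C={truth.n_classes}"
        )
    c = prediction.n_classes
    return prediction.values.reshape(-1, c), truth.values.reshape(-1, c).astype(float)


def _pixel_ce(prediction: ProbabilityField, truth: OneHotField) -> np.ndarray:
    s, g = _flat(prediction, truth)
    return -(g * np.log(np.clip(s, _LOG_CLAMP, 1.0))).sum(axis=1)


def loss_ce(prediction: ProbabilityField, truth: OneHotField) -> float:
    """Multi-class cross-entropy: -(1/N) sum_i sum_c g_ic log s_ic."""
    return float(_pixel_ce(prediction, truth).mean())


def loss_topk(prediction: ProbabilityField, truth: OneHotField, k_percent: float = 10.0) -> float:
    """Top-K cross-entropy: mean per-voxel CE over the K% hardest voxels."""
    if not (0 < k_percent <= 100):
        raise ValueError(f"k_percent must lie in (0, 100], got {k_percent}")
    ell = _pixel_ce(prediction, truth)
    n_keep = math.ceil(k_percent * ell.size / 100.0)
    cutoff = np.sort(ell)[::-1][n_keep - 1]
    return float(ell[ell >= cutoff].mean())


def loss_dice(prediction: ProbabilityField, truth: OneHotField) -> float:
    """Soft Dice loss: 1 - 2(sum g s + eps) / (sum g + sum s + eps)."""
    s, g = _flat(prediction, truth)
    intersection = float((g * s).sum())
    denom = float(g.sum() + s.sum())
    return max(0.0, 1.0 - (2.0 * intersection + 2.0 * REGION_EPS) / (denom + 2.0 * REGION_EPS))


def loss_gdice(
    prediction: ProbabilityField,
    truth: OneHotField,
    weights: ClassWeights | None = None,
    exponent: int = 2,
) -> float:
    """Generalized Dice loss with class weights w_c.

    Defaults to inverse squared class volume weights computed from the truth;
    uniform weights reduce it to :func:`loss_dice` exactly.
    """
    s, g = _flat(prediction, truth)
    if weights is None:
        weights = ClassWeights.inverse_volume(truth, exponent=exponent)
    w = weights.w
    if w.shape != (prediction.n_classes,):
        raise ValueError(f"need one weight per class, got {w.shape} for C={prediction.n_classes}")
    intersection = float((w * (g * s).sum(axis=0)).sum())
    denom = float((w * (g + s).sum(axis=0)).sum())
    return max(0.0, 1.0 - (2.0 * intersection + 2.0 * REGION_EPS) / (denom + 2.0 * REGION_EPS))


def loss_hybrid(
    prediction: ProbabilityField,
    truth: OneHotField,
    name: str,
    k_percent: float = 10.0,
    weights: ClassWeights | None = None,
) -> float:
    """Hybrid loss: plain sum of a distribution term and a region term.

    ``name`` is one of ``ce+dice``, ``topk+dice``, ``ce+gdice``.
    """
    key = name.lower().replace(" ", "")
    if key == "ce+dice":
        return loss_ce(prediction, truth) + loss_dice(prediction, truth)
    if key == "topk+dice":
        return loss_topk(prediction, truth, k_percent) + loss_dice(prediction, truth)
    if key == "ce+gdice":
        return loss_ce(prediction, truth) + loss_gdice(prediction, truth, weights)
    raise ValueError(f"unknown hybrid loss {name!r}; expected one of {HYBRID_NAMES}")
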