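"""Ensemble fusion of multi-rater binary segmentations.

Three strategies are implemented for combining candidate tumor masks from K
raters (here, independently trained model variants):

* **majority voting** — a voxel is foreground iff strictly more than half of
  the raters mark it (ties with even K go to background);
* **soft voting** — the unweighted arithmetic mean of per-class probability
  maps, hardened by per-voxel argmax;
* **STAPLE** — Simultaneous Truth and Performance Level Estimation, an EM
  algorithm that treats the true segmentation as a latent per-voxel variable
  and jointly estimates it together with each rater's sensitivity p_j and
  specificity q_j.

STAPLE model.  Let D_ij in {0,1} be rater j's decision at voxel i and gamma
the prior foreground probability.  The E-step computes the posterior
foreground weight

    W_i = a_i / (a_i + b_i),
    a_i = gamma       * prod_j p_j^D_ij (1-p_j)^(1-D_ij)
    b_i = (1 - gamma) * prod_j (1-q_j)^D_ij q_j^(1-D_ij)

(evaluated in the log domain), and the M-step re-estimates

    p_j = sum_i W_i D_ij / sum_i W_i
    q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i).

Iteration stops when the largest absolute change in any p_j or q_j drops
below the tolerance, or at the iteration cap.  The prior gamma is fixed at
the mean rater foreground fraction (not re-estimated), the classic choice
that avoids prior collapse on tiny foregrounds.  The algorithm is fully
deterministic.

The EM sums run either over the whole volume (default) or, optionally,
inside a region of interest built by dilating the union of rater masks — on
whole CT volumes the overwhelming background makes specificity nearly
uninformative, and the band restores its discriminative value.  The ROI mode
is explicit configuration, never applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .grids import (
    BinaryMask,
    DegenerateInputError,
    LabelVolume,
    ProbabilityField,
    check_same_grid,
)

__all__ = [
    "StapleParams",
    "StapleResult",
    "RaterSet",
    "majority_vote",
    "soft_vote",
    "argmax_labels",
    "staple_em",
    "threshold_weights",
    "grid_search_threshold",
    "fuse_multiclass",
    "DEFAULT_THRESHOLD_GRID",
]

#: clamp applied to p_j, q_j before the log-domain E-step (log(0) guard)
_PROB_CLAMP = 1e-6

#: default threshold grid for the validation-set search, step 0.05
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass(frozen=True)
class StapleParams:
    """Tunable parameters of the STAPLE EM run.

    Defaults follow common practice for model-ensemble fusion: near-perfect
    initial performance (0.9999 sensitivity/specificity for every rater),
    convergence tolerance 1e-4 on the parameter change, at most 100
    iterations.
    """

    init_sensitivity: float = 0.9999
    init_specificity: float = 0.9999
    tolerance: float = 1e-4
    max_iterations: int = 100
    #: None -> prior = mean rater foreground fraction; a float fixes gamma
    fixed_prior: float | None = None
    roi_mode: Literal["full_volume", "union_dilated"] = "full_volume"
    #: dilation margin (voxels) for the union ROI; only used in union_dilated mode
    roi_margin: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.init_sensitivity < 1 and 0 < self.init_specificity < 1):
            raise ValueError("initial sensitivity/specificity must lie in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.fixed_prior is not None and not (0 < self.fixed_prior < 1):
            raise ValueError("fixed prior must lie in (0, 1)")
        if self.roi_mode not in ("full_volume", "union_dilated"):
            raise ValueError(f"unknown roi_mode {self.roi_mode!r}")
        if self.roi_margin < 1:
            raise ValueError("roi_margin must be >= 1")


@dataclass
class StapleResult:
    """Output of one binary STAPLE run: the posterior weight field plus the
    per-rater performance estimates and a convergence record."""

    grid: object
    weights: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    iterations: int
    converged: bool
    prior: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.specificities = np.asarray(self.specificities, dtype=float)


@dataclass
class RaterSet:
    """Ordered binary masks from K raters on one grid."""

    masks: list[BinaryMask]
    rater_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.masks) < 1:
            raise ValueError("RaterSet needs at least one rater")
        check_same_grid(self.masks)
        if not self.rater_names:
            self.rater_names = [f"rater_{j + 1}" for j in range(len(self.masks))]
        if len(self.rater_names) != len(self.masks):
            raise ValueError("rater_names must match the number of masks")

    @property
    def k(self) -> int:
        return len(self.masks)

    @property
    def grid(self):
        return self.masks[0].grid

    def decision_stack(self) -> np.ndarray:
        """(K, *grid.shape) boolean array of rater decisions."""
        return np.stack([m.values for m in self.masks], axis=0)


def majority_vote(raters: RaterSet) -> BinaryMask:
    """Strict-majority fusion: foreground iff more than half the raters agree.

    With even K a tied voxel is background — the strict rule never invents
    foreground that lacks a true majority.
    """
    counts = raters.decision_stack().sum(axis=0)
    return BinaryMask(grid=raters.grid, values=counts > raters.k / 2)


def soft_vote(maps: Sequence[ProbabilityField]) -> ProbabilityField:
    """Unweighted arithmetic mean of per-class probability maps."""
    maps = list(maps)
    if not maps:
        raise ValueError("soft_vote needs at least one probability map")
    check_same_grid(maps)
    n_classes = {m.n_classes for m in maps}
    if len(n_classes) != 1:
        raise ValueError(f"probability maps disagree on class count: {sorted(n_classes)}")
    mean = np.mean([m.values for m in maps], axis=0)
    return ProbabilityField(grid=maps[0].grid, values=mean)


def argmax_labels(pmap: ProbabilityField) -> LabelVolume:
    """Per-voxel hard labels; ties break toward the lower class index
    (``np.argmax`` convention)."""
    return LabelVolume(
        grid=pmap.grid,
        labels=np.argmax(pmap.values, axis=-1).astype(np.int16),
        n_classes=pmap.n_classes,
    )


def _estep_weights(D: np.ndarray, p: np.ndarray, q: np.ndarray, gamma: float) -> np.ndarray:
    """Posterior foreground weights for decision matrix D (K, M), computed in
    the log domain.  Exposed for testing the monotone-agreement property."""
    p = np.clip(np.asarray(p, dtype=float), _PROB_CLAMP, 1 - _PROB_CLAMP)
    q = np.clip(np.asarray(q, dtype=float), _PROB_CLAMP, 1 - _PROB_CLAMP)
    Df = D.astype(float)
    log_a = np.log(gamma) + Df.T @ (np.log(p) - np.log1p(-p)) + np.log1p(-p).sum()
    log_b = np.log1p(-gamma) + Df.T @ (np.log1p(-q) - np.log(q)) + np.log(q).sum()
    return expit(log_a - log_b)


def staple_em(raters: RaterSet, params: StapleParams | None = None) -> StapleResult:
    """Run binary STAPLE EM on a rater set.

    Raises :class:`DegenerateInputError` when no rater marks any voxel
    foreground (the latent-truth model is vacuous there).
    """
    params = params or StapleParams()
    stack = raters.decision_stack()
    union = stack.any(axis=0)
    if not union.any():
        raise DegenerateInputError("STAPLE needs at least one foreground voxel in some rater")

    if params.roi_mode == "union_dilated":
        roi = ndimage.binary_dilation(union, iterations=params.roi_margin)
    else:
        roi = np.ones(raters.grid.shape, dtype=bool)

    D = stack[:, roi]  # (K, M) decisions inside the ROI
    m_voxels = D.shape[1]

    if params.fixed_prior is not None:
        gamma = params.fixed_prior
    else:
        gamma = float(D.mean())  # mean over raters of ROI foreground fraction
    gamma = float(np.clip(gamma, _PROB_CLAMP, 1 - _PROB_CLAMP))

    k = raters.k
    p = np.full(k, params.init_sensitivity, dtype=float)
    q = np.full(k, params.init_specificity, dtype=float)
    Df = D.astype(float)

    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        w = _estep_weights(D, p, q, gamma)
        sw = w.sum()
        sw_c = m_voxels - sw
        # M-step; a collapsed posterior keeps the previous estimate
        p_new = (Df @ w) / sw if sw > 0 else p
        q_new = ((1.0 - Df) @ (1.0 - w)) / sw_c if sw_c > 0 else q
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < params.tolerance:
            converged = True
            break

    weights = np.zeros(raters.grid.shape, dtype=float)
    weights[roi] = _estep_weights(D, p, q, gamma)
    return StapleResult(
        grid=raters.grid,
        weights=weights,
        sensitivities=p,
        specificities=q,
        iterations=iterations,
        converged=converged,
        prior=gamma,
    )


def threshold_weights(result: StapleResult, t: float) -> BinaryMask:
    """Harden a STAPLE weight field: foreground where ``W_i >= t``."""
    if not (0 < t < 1):
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    return BinaryMask(grid=result.grid, values=result.weights >= t)


def grid_search_threshold(
    results: Sequence[StapleResult],
    truths: Sequence[BinaryMask],
    grid: Sequence[float] | None = None,
) -> float:
    """Validation-set threshold search for STAPLE weight maps.

    Returns the grid value maximizing mean DSC over cases; ties (within
    1e-12) break first by minimal mean |precision - recall| (the balanced
    operating point), then by the smaller threshold.
    """
    from .metrics import confusion_counts, overlap_metrics

    results = list(results)
    truths = list(truths)
    if not results or len(results) != len(truths):
        raise ValueError("need equal-length, non-empty result and truth lists")
    grid = list(grid) if grid is not None else list(DEFAULT_THRESHOLD_GRID)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if any(not (0 < t < 1) for t in grid):
        raise ValueError("all grid thresholds must lie in (0, 1)")

    scored = []
    for t in grid:
        dscs, imbalances = [], []
        for res, truth in zip(results, truths):
            counts = confusion_counts(threshold_weights(res, t), truth)
            dsc, _, precision, recall = overlap_metrics(counts)
            dscs.append(dsc)
            imbalances.append(abs(precision - recall))
        scored.append((float(t), float(np.mean(dscs)), float(np.mean(imbalances))))

    best_dsc = max(s[1] for s in scored)
    tied = [s for s in scored if s[1] >= best_dsc - 1e-12]
    tied.sort(key=lambda s: (s[2], s[0]))
    return tied[0][0]


def fuse_multiclass(
    volumes: Sequence[LabelVolume],
    method: Literal["majority", "staple"] = "majority",
    staple_params: StapleParams | None = None,
    threshold: float = 0.5,
) -> LabelVolume:
    """Fuse multi-class label volumes by per-class binary fusion.

    Each foreground class is fused independently with the chosen method, then
    the binary results are composed back into labels with precedence to the
    higher class index on overlap (tumor overrides organ); voxels claimed by
    no class stay background.  Classes where STAPLE is degenerate (no rater
    foreground anywhere) fuse to empty.
    """
    from .grids import extract_class_mask

    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one label volume")
    check_same_grid(volumes)
    n_classes = {v.n_classes for v in volumes}
    if len(n_classes) != 1:
        raise ValueError(f"label volumes disagree on class count: {sorted(n_classes)}")
    c = n_classes.pop()
    if method not in ("majority", "staple"):
        raise ValueError(f"unknown fusion method {method!r}")

    grid = volumes[0].grid
    fused = np.zeros(grid.shape, dtype=np.int16)
    for class_id in range(1, c):  # ascending: higher class overwrites lower
        raters = RaterSet(masks=[extract_class_mask(v, class_id) for v in volumes])
        if method == "majority":
            mask = majority_vote(raters)
        else:
            try:
                mask = threshold_weights(staple_em(raters, staple_params), threshold)
            except DegenerateInputError:
                continue
        fused[mask.values] = class_id
    return LabelVolume(grid=grid, labels=fused, n_classes=c)
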