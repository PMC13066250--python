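"""In-memory data model for segmentations sharing a voxel grid.

All volumes live on a :class:`VoxelGrid` — a fixed 3D shape plus physical
voxel spacing in millimetres per axis.  Axis order is (x, y, z) with axis 2
taken as the axial (slice) direction throughout the package; 2D per-slice
operations always slice along axis 2.  Multi-channel fields (probabilities,
one-hot indicators) store the class channel last, shape ``grid.shape + (C,)``.

Grids are never resampled: objects on different grids are an error, caught by
:func:`check_same_grid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridMismatchError",
    "DegenerateInputError",
    "VoxelGrid",
    "LabelVolume",
    "BinaryMask",
    "ProbabilityField",
    "OneHotField",
    "check_same_grid",
    "onehot_encode",
    "extract_class_mask",
]

#: tolerance, in mm, for deciding two spacings describe the same grid
SPACING_ATOL_MM = 1e-4

#: tolerance for the per-voxel sum-to-one check on probability fields
PROB_SUM_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Raised when volumes expected to share a voxel grid do not."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no information
    for the requested operation (e.g. no foreground anywhere, all-zero paired
    differences)."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice: shape in voxels and spacing in mm per axis."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("VoxelGrid is strictly 3D: need 3 shape and 3 spacing entries")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing entries must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def compatible_with(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= SPACING_ATOL_MM for a, b in zip(self.spacing, other.spacing)
        )


def _check_field_shape(grid: VoxelGrid, arr: np.ndarray, name: str, extra_dims: int = 0) -> None:
    expect = grid.shape
    got = arr.shape[: arr.ndim - extra_dims] if extra_dims else arr.shape
    if arr.ndim != 3 + extra_dims or tuple(got) != expect:
        raise ValueError(f"{name} shape {arr.shape} does not match grid shape {expect}")


@dataclass
class LabelVolume:
    """Integer class labels on a grid; class 0 is background."""

    grid: VoxelGrid
    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.int16)
            else:
                raise ValueError(f"labels must be integer-valued, got dtype {self.labels.dtype}")
        _check_field_shape(self.grid, self.labels, "labels")
        self.n_classes = int(self.n_classes)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2 (background plus at least one class)")
        if self.labels.size:
            lo, hi = int(self.labels.min()), int(self.labels.max())
            if lo < 0 or hi >= self.n_classes:
                raise ValueError(
                    f"labels must lie in [0, {self.n_classes - 1}], found range [{lo}, {hi}]"
                )


@dataclass
class BinaryMask:
    """Boolean foreground mask for a single class on a grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != np.bool_:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be boolean or 0/1")
            self.values = self.values.astype(bool)
        _check_field_shape(self.grid, self.values, "mask values")

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


@dataclass
class ProbabilityField:
    """Per-class probabilities, channel-last, summing to one at every voxel."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_field_shape(self.grid, self.values, "probability values", extra_dims=1)
        if self.values.shape[-1] < 2:
            raise ValueError("probability field needs at least 2 classes")
        if self.values.min() < -PROB_SUM_ATOL or self.values.max() > 1 + PROB_SUM_ATOL:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.values.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=PROB_SUM_ATOL, rtol=0):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(f"per-voxel class probabilities must sum to 1 (worst deviation {worst:g})")

    @property
    def n_classes(self) -> int:
        return self.values.shape[-1]

    def class_probability(self, class_id: int) -> np.ndarray:
        return self.values[..., class_id]


@dataclass
class OneHotField:
    """Per-class boolean indicators with exactly one class set per voxel."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        _check_field_shape(self.grid, self.values, "one-hot values", extra_dims=1)
        if self.values.shape[-1] < 2:
            raise ValueError("one-hot field needs at least 2 classes")
        counts = self.values.sum(axis=-1)
        if not np.all(counts == 1):
            raise ValueError("exactly one class must be set at every voxel")

    @property
    def n_classes(self) -> int:
        return self.values.shape[-1]


def check_same_grid(items: Iterable) -> None:
    """Verify all grid-bearing objects share one grid (shape exactly, spacing
    within ``SPACING_ATOL_MM`` per axis); raise :class:`GridMismatchError`
    naming the first offending pair otherwise."""
    seq: Sequence = list(items)
    if not seq:
        raise ValueError("check_same_grid needs a non-empty collection")
    first = seq[0].grid if hasattr(seq[0], "grid") else seq[0]
    for idx, item in enumerate(seq[1:], start=1):
        grid = item.grid if hasattr(item, "grid") else item
        if not first.compatible_with(grid):
            raise GridMismatchError(
                f"grid mismatch between item 0 ({first.shape} @ {first.spacing} mm) "
                f"and item {idx} ({grid.shape} @ {grid.spacing} mm)"
            )


def onehot_encode(v: LabelVolume) -> OneHotField:
    """Expand integer labels into per-class boolean indicator channels."""
    eye = np.eye(v.n_classes, dtype=bool)
    return OneHotField(grid=v.grid, values=eye[v.labels])


def extract_class_mask(v: LabelVolume, class_id: int) -> BinaryMask:
    """Binary mask of one class: true exactly where ``labels == class_id``."""
    if not (0 <= class_id < v.n_classes):
        raise ValueError(f"class_id {class_id} out of range [0, {v.n_classes - 1}]")
    return BinaryMask(grid=v.grid, values=v.labels == class_id)
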