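"""Segmentation evaluation metrics and morphology descriptors.

Overlap metrics (DSC, Jaccard, precision, recall) come from the voxelwise
confusion matrix; the boundary metric is the 95th-percentile Hausdorff
distance (HD95) in millimetres.  Morphology descriptors — tumor volume,
tertile size stratification and solidity — support the stratified and
heterogeneity analyses.

Conventions pinned here (each is one of several in circulation, so it is
fixed once and documented):

* HD95 pools both directed nearest-surface distance sets (prediction->truth
  and truth->prediction) and takes a single 95th percentile with linear
  interpolation; a ``max_directed`` variant (max of the two directed 95th
  percentiles) is available.  HD95 is undefined (``None``) when either mask
  is empty.
* Surface voxels are foreground voxels with at least one face-adjacent
  background voxel; the volume border counts as background.
* Degenerate overlap: both masks empty -> all four overlap metrics are 1;
  exactly one empty -> any ratio with a zero denominator is 0.
* Solidity is computed in 2D on the axial slice (axis 2) of maximal
  foreground area — foreground pixel count over the pixel count of the
  rasterized convex hull of the foreground pixel centers; a 3D
  volume-over-hull-volume variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, check_same_grid

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "SizeStrata",
    "confusion_counts",
    "overlap_metrics",
    "hd95",
    "tumor_volume",
    "stratify_tertiles",
    "solidity",
    "evaluate_case",
    "reports_to_frame",
    "REPORT_COLUMNS",
]

#: fixed CSV column order for serialized reports
REPORT_COLUMNS = (
    "case_id",
    "class_id",
    "dsc",
    "ji",
    "hd95_mm",
    "precision",
    "recall",
    "volume_voxels",
    "volume_ml",
    "solidity",
)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise confusion-matrix counts; prediction positives not in the
    truth are FP (prediction-oriented)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Per-case, per-class evaluation row."""

    case_id: str
    class_id: int
    dsc: float
    ji: float
    hd95_mm: float | None
    precision: float
    recall: float
    volume_voxels: int
    volume_ml: float
    solidity: float | None


@dataclass
class SizeStrata:
    """Tertile assignment of cases by ground-truth tumor volume."""

    groups: dict[str, str]  # case_id -> "Small" | "Medium" | "Large"
    boundaries: tuple[int, int]  # max volume of Small, max volume of Medium


def confusion_counts(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Voxelwise TP/FP/FN/TN between a predicted and a reference mask."""
    check_same_grid([pred, truth])
    p, t = pred.values, truth.values
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(DSC, Jaccard, precision, recall) from confusion counts.

    DSC = 2TP / ((TP+FN) + (TP+FP)); JI = TP / (TP+FP+FN);
    precision = TP / (TP+FP); recall = TP / (TP+FN).
    """
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0, 1.0, 1.0  # both masks empty: perfect trivial agreement

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    dsc = ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)
    ji = ratio(c.tp, c.tp + c.fp + c.fn)
    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    return dsc, ji, precision, recall


def _surface(values: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 face-adjacent background voxel; the volume
    border counts as background (erosion border_value=0)."""
    eroded = ndimage.binary_erosion(values, structure=_FACE_STRUCT, border_value=0)
    return values & ~eroded


def hd95(
    pred: BinaryMask,
    truth: BinaryMask,
    mode: Literal["pooled", "max_directed"] = "pooled",
    percentile: float = 95.0,
) -> float | None:
    """95th-percentile Hausdorff distance between mask surfaces, in mm.

    Distances are Euclidean between voxel centers using the grid spacing.
    Returns ``None`` when either mask is empty (the metric is only defined
    when both masks contain the structure).
    """
    check_same_grid([pred, truth])
    if not pred.values.any() or not truth.values.any():
        return None
    spacing = pred.grid.spacing
    surf_p = _surface(pred.values)
    surf_t = _surface(truth.values)
    # distance from every voxel to the nearest surface voxel of the other mask
    dist_to_t = ndimage.distance_transform_edt(~surf_t, sampling=spacing)
    dist_to_p = ndimage.distance_transform_edt(~surf_p, sampling=spacing)
    d_pt = dist_to_t[surf_p]
    d_tp = dist_to_p[surf_t]
    if mode == "pooled":
        return float(np.percentile(np.concatenate([d_pt, d_tp]), percentile))
    if mode == "max_directed":
        return float(max(np.percentile(d_pt, percentile), np.percentile(d_tp, percentile)))
    raise ValueError(f"unknown hd95 mode {mode!r}")


def tumor_volume(mask: BinaryMask) -> tuple[int, float]:
    """(voxel count, volume in ml) using the grid's voxel volume in mm^3."""
    n = mask.foreground_count
    return n, n * mask.grid.voxel_volume_mm3 / 1000.0


def stratify_tertiles(volumes: Mapping[str, int]) -> SizeStrata:
    """Split cases into Small/Medium/Large tertiles by tumor volume.

    Cases are ranked ascending by volume (ties by case id) and cut into three
    contiguous groups as equal as possible, any remainder going to the lower
    (smaller-volume) groups; boundaries are the maximum volumes of the Small
    and Medium groups.
    """
    if len(volumes) < 3:
        raise ValueError("tertile stratification needs at least 3 cases")
    ranked = sorted(volumes.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(ranked)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    names = ("Small", "Medium", "Large")
    groups: dict[str, str] = {}
    idx = 0
    cut_volumes = []
    for name, size in zip(names, sizes):
        chunk = ranked[idx : idx + size]
        for case_id, _ in chunk:
            groups[case_id] = name
        cut_volumes.append(chunk[-1][1])
        idx += size
    return SizeStrata(groups=groups, boundaries=(cut_volumes[0], cut_volumes[1]))


def _collinear_hull_count(points: np.ndarray) -> int:
    """Lattice-point count of the segment spanned by collinear pixel centers."""
    span = points.max(axis=0) - points.min(axis=0)
    if np.all(span == 0):
        return 1
    return int(np.gcd.reduce(span.astype(int))) + 1


def _hull_pixel_count(plane: np.ndarray) -> int:
    """Pixel count of the rasterized convex hull of foreground pixel centers."""
    from skimage.morphology import convex_hull_image

    points = np.argwhere(plane)
    if len(points) <= 2 or np.linalg.matrix_rank(points - points[0]) < 2:
        return _collinear_hull_count(points)
    hull = convex_hull_image(plane, offset_coordinates=False)
    return int(hull.sum())


def solidity(mask: BinaryMask, mode: Literal["slice", "volume"] = "slice") -> float | None:
    """Foreground area over convex-hull area; ``None`` for an empty mask.

    In ``slice`` mode (default) the computation runs on the axial slice
    (axis 2) of maximal foreground area — a deterministic, representative 2D
    section; ``volume`` mode uses the full 3D voxel count over the 3D hull.
    """
    if not mask.values.any():
        return None
    if mode == "slice":
        areas = mask.values.sum(axis=(0, 1))
        k = int(np.argmax(areas))
        plane = mask.values[:, :, k]
        return float(plane.sum() / _hull_pixel_count(plane))
    if mode == "volume":
        from skimage.morphology import convex_hull_image

        points = np.argwhere(mask.values)
        if len(points) <= 3 or np.linalg.matrix_rank(points - points[0]) < 3:
            # degenerate (planar or lower) support: fall back to the planar rule
            return float(mask.values.sum() / _hull_pixel_count(mask.values.max(axis=2)))
        hull = convex_hull_image(mask.values, offset_coordinates=False)
        return float(mask.values.sum() / hull.sum())
    raise ValueError(f"unknown solidity mode {mode!r}")


def evaluate_case(
    pred: BinaryMask,
    truth: BinaryMask,
    case_id: str = "case",
    class_id: int = 1,
    with_solidity: bool = True,
) -> MetricReport:
    """Full per-case metric row for one class: overlap metrics, HD95, volume
    of the *truth* mask and its solidity."""
    counts = confusion_counts(pred, truth)
    dsc, ji, precision, recall = overlap_metrics(counts)
    vox, ml = tumor_volume(truth)
    return MetricReport(
        case_id=case_id,
        class_id=class_id,
        dsc=dsc,
        ji=ji,
        hd95_mm=hd95(pred, truth),
        precision=precision,
        recall=recall,
        volume_voxels=vox,
        volume_ml=ml,
        solidity=solidity(truth) if with_solidity else None,
    )


def reports_to_frame(reports: Sequence[MetricReport]):
    """Stack metric rows into a DataFrame with the fixed column order."""
    import pandas as pd

    rows = [
        {
            "case_id": r.case_id,
            "class_id": r.class_id,
            "dsc": r.dsc,
            "ji": r.ji,
            "hd95_mm": np.nan if r.hd95_mm is None else r.hd95_mm,
            "precision": r.precision,
            "recall": r.recall,
            "volume_voxels": r.volume_voxels,
            "volume_ml": r.volume_ml,
            "solidity": np.nan if r.solidity is None else r.solidity,
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
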