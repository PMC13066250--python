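"""NIfTI readers and writers for label volumes and probability maps.

Voxel spacing is taken from the NIfTI header zooms; orientation codes are
recorded and must agree across all volumes of a run — mismatched
orientations are an error, never silently reoriented, and grids are never
resampled.  Label volumes are stored with integer datatypes; probability
maps as 4D floating-point images (class channel last).  Per-class 3D
probability files are also read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .grids import LabelVolume, ProbabilityField, VoxelGrid, check_same_grid

__all__ = [
    "IOFormatError",
    "read_label_volume",
    "read_label_volumes",
    "write_label_volume",
    "read_probability_field",
    "write_probability_field",
    "orientation_codes",
]


class IOFormatError(ValueError):
    """Raised for unreadable or inconsistent volume files."""


def orientation_codes(path: str | Path) -> tuple[str, ...]:
    """Anatomical axis codes (e.g. ('R','A','S')) from a file's affine."""
    img = nib.load(str(path))
    return tuple(nib.aff2axcodes(img.affine))


def _load(path: str | Path):
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOFormatError(f"cannot read NIfTI file {path}: {exc}") from exc


def read_label_volume(path: str | Path, n_classes: int | None = None) -> LabelVolume:
    """Read an integer label volume; non-integer voxel data is rejected."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOFormatError(f"{path}: expected a 3D label volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise IOFormatError(
                f"{path}: label volume contains non-integer values; refusing to round"
            )
        data = rounded.astype(np.int32)
    grid = VoxelGrid(shape=data.shape, spacing=tuple(float(z) for z in img.header.get_zooms()[:3]))
    c = n_classes if n_classes is not None else max(2, int(data.max()) + 1)
    if int(data.max()) >= c:
        raise IOFormatError(f"{path}: label {int(data.max())} exceeds declared class count {c}")
    return LabelVolume(grid=grid, labels=data, n_classes=c)


def read_label_volumes(paths: Sequence[str | Path], n_classes: int | None = None) -> list[LabelVolume]:
    """Read several label volumes for one run, enforcing a common grid and a
    common orientation code (no silent reorientation)."""
    paths = list(paths)
    codes = [orientation_codes(p) for p in paths]
    if len(set(codes)) > 1:
        detail = ", ".join(f"{p}: {''.join(c)}" for p, c in zip(paths, codes))
        raise IOFormatError(f"inconsistent orientations within one run ({detail})")
    volumes = [read_label_volume(p, n_classes=n_classes) for p in paths]
    check_same_grid(volumes)
    return volumes


def write_label_volume(v: LabelVolume, path: str | Path) -> None:
    """Write an integer-datatype NIfTI with the grid spacing in the header."""
    affine = np.diag([*v.grid.spacing, 1.0])
    img = nib.Nifti1Image(v.labels.astype(np.int16), affine)
    img.header.set_zooms(v.grid.spacing)
    nib.save(img, str(path))


def read_probability_field(paths: str | Path | Sequence[str | Path]) -> ProbabilityField:
    """Read per-class probabilities: one 4D file, or one 3D file per class."""
    if isinstance(paths, (str, Path)):
        img = _load(paths)
        data = np.asanyarray(img.dataobj).astype(float)
        if data.ndim != 4:
            raise IOFormatError(f"{paths}: expected a 4D probability map, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        grid = VoxelGrid(shape=data.shape[:3], spacing=spacing)
        return ProbabilityField(grid=grid, values=data)
    imgs = [_load(p) for p in paths]
    datas = [np.asanyarray(i.dataobj).astype(float) for i in imgs]
    if any(d.ndim != 3 for d in datas):
        raise IOFormatError("per-class probability files must be 3D")
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    grid = VoxelGrid(shape=datas[0].shape, spacing=spacing)
    return ProbabilityField(grid=grid, values=np.stack(datas, axis=-1))


def write_probability_field(p: ProbabilityField, path: str | Path) -> None:
    """Write a probability field as one 4D floating-point NIfTI."""
    affine = np.diag([*p.grid.spacing, 1.0])
    img = nib.Nifti1Image(p.values.astype(np.float32), affine)
    img.header.set_zooms((*p.grid.spacing, 1.0))
    nib.save(img, str(path))
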