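import numpy as np
import pytest

from staplefuse.grids import BinaryMask, LabelVolume, ProbabilityField, VoxelGrid


@pytest.fixture
def unit_grid():
    return VoxelGrid((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid():
    return VoxelGrid((8, 8, 8), (0.5, 0.5, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_mask(grid: VoxelGrid, rng: np.random.Generator, p: float = 0.3) -> BinaryMask:
    return BinaryMask(grid=grid, values=rng.random(grid.shape) < p)


def random_labels(grid: VoxelGrid, rng: np.random.Generator, n_classes: int = 3) -> LabelVolume:
    return LabelVolume(
        grid=grid, labels=rng.integers(0, n_classes, size=grid.shape), n_classes=n_classes
    )


def random_probability_field(
    grid: VoxelGrid, rng: np.random.Generator, n_classes: int = 3
) -> ProbabilityField:
    raw = rng.random(grid.shape + (n_classes,)) + 1e-3
    return ProbabilityField(grid=grid, values=raw / raw.sum(axis=-1, keepdims=True))
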