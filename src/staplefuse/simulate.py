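"""Synthetic phantoms and rater-corruption models.

Real multi-rater fusion experiments need expert-annotated CT volumes; this
module replaces them with controlled synthetic analogues so that fusion,
metrics and statistics are testable end-to-end:

* **Phantoms** — 3D tumor-like blobs: convex ellipsoids, lobulated shapes
  (broad radial bumps) or spiky shapes (narrow protrusions), giving
  controllable solidity regimes from regular (solidity near 1) to highly
  irregular.  Optionally an enclosing smooth organ shell (label 1) around
  the tumor (label 2).
* **Raters** — corruptions of the true mask with *known* per-voxel
  sensitivity and specificity: inside the truth each voxel survives with
  probability = sensitivity; inside a surrounding band (truth dilated by a
  margin, minus truth) each voxel turns falsely positive with probability
  = 1 - specificity.  Specificity is defined on the band rather than the
  whole volume because whole-volume specificity is ~1 for any plausible
  rater and carries no information.  Optional morphological boundary jitter
  adds spatially correlated disagreement on top of the i.i.d. noise.
* **Probability maps** — logistic-of-signed-distance surrogates for softmax
  outputs, consistent with a rater's binary mask.

All randomness flows from explicit seeds; a master seed fans out to
per-case / per-rater child seeds by fixed arithmetic, so adding cases never
reshuffles existing ones.  :func:`run_ensemble_experiment` is the harness
that generates cases, applies every fusion method, scores them and runs the
paired comparison protocol.

The default rater panel (:func:`heterogeneous_rater_specs`) spans
sensitivities 0.95 down to 0.60 at band specificity 0.995 — a deliberately
heterogeneous reliability mix under which performance-weighted fusion can
outrank equal-weight averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .fusion import (
    RaterSet,
    StapleParams,
    StapleResult,
    argmax_labels,
    majority_vote,
    soft_vote,
    staple_em,
    threshold_weights,
)
from .grids import BinaryMask, LabelVolume, ProbabilityField, VoxelGrid
from .metrics import evaluate_case, reports_to_frame
from .stats import ComparisonTable, compare_methods

__all__ = [
    "PhantomSpec",
    "RaterSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "make_phantom",
    "corrupt_rater",
    "make_probability_map",
    "run_ensemble_experiment",
    "heterogeneous_rater_specs",
    "empirical_rater_performance",
    "PhantomExceedsGridError",
]

_SHAPE_KINDS = ("ellipsoid", "lobulated", "spiky")

#: angular sharpness of the lobulated radial bumps
_LOBE_POWER = 2.0


class PhantomExceedsGridError(ValueError):
    """Raised when a generated phantom touches the volume border."""


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic tumor phantom.

    ``irregularity`` scales the amplitude of radial perturbations (0 = exact
    ellipsoid); ``n_lobes`` sets how many random bump directions are drawn.
    The same spec and seed always produce the identical volume.
    """

    grid: VoxelGrid
    shape_kind: str = "ellipsoid"
    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] = (10.0, 10.0, 10.0)
    irregularity: float = 0.0
    n_lobes: int = 6
    seed: int = 0
    organ_scale: float | None = None  # e.g. 1.6 -> enclosing organ shell label

    def __post_init__(self) -> None:
        if self.shape_kind not in _SHAPE_KINDS:
            raise ValueError(f"shape_kind must be one of {_SHAPE_KINDS}")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if self.n_lobes < 0:
            raise ValueError("n_lobes must be >= 0")
        if self.organ_scale is not None and self.organ_scale <= 1:
            raise ValueError("organ_scale must exceed 1")


@dataclass(frozen=True)
class RaterSpec:
    """Generative corruption parameters for one simulated rater."""

    sensitivity: float = 0.9
    specificity: float = 0.99
    roi_margin: int = 3
    boundary_noise_radius: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity <= 1) or not (0 < self.specificity <= 1):
            raise ValueError("sensitivity and specificity must lie in (0, 1]")
        if self.roi_margin < 1:
            raise ValueError("roi_margin must be >= 1")
        if self.boundary_noise_radius < 0:
            raise ValueError("boundary_noise_radius must be >= 0")


def heterogeneous_rater_specs(
    sensitivities: Sequence[float] = (0.95, 0.90, 0.85, 0.70, 0.60),
    specificity: float = 0.995,
    roi_margin: int = 3,
    boundary_noise_radius: int = 0,
) -> list[RaterSpec]:
    """The default heterogeneous-reliability rater panel: sensitivities
    spanning 0.95 to 0.60 at band specificity 0.995."""
    return [
        RaterSpec(
            sensitivity=s,
            specificity=specificity,
            roi_margin=roi_margin,
            boundary_noise_radius=boundary_noise_radius,
            seed=j,
        )
        for j, s in enumerate(sensitivities)
    ]


def _unit_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Generate a deterministic tumor phantom from its spec.

    An ellipsoid is the set of voxels with normalized radius rho <= 1; the
    lobulated/spiky kinds inflate the surface along ``n_lobes`` seeded random
    directions, each bump a power of the cosine to the bump axis (broad for
    lobulated, narrow for spiky), scaled by ``irregularity``.  Raises
    :class:`PhantomExceedsGridError` if the shape touches the volume border.
    """
    grid = spec.grid
    rng = np.random.default_rng(np.random.SeedSequence((0x9A4F, spec.seed)))
    center = np.asarray(
        spec.center if spec.center is not None else [(s - 1) / 2.0 for s in grid.shape]
    )
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
    u = (coords - center) / np.asarray(spec.radii)
    rho = np.linalg.norm(u, axis=-1)

    threshold = np.ones(grid.shape)
    if spec.shape_kind == "lobulated" and spec.irregularity > 0 and spec.n_lobes > 0:
        # broad radial bumps along seeded random directions
        dirs = _unit_directions(rng, spec.n_lobes)
        amps = rng.uniform(0.5, 1.0, size=spec.n_lobes)
        with np.errstate(invalid="ignore"):
            uhat = u / np.where(rho[..., None] > 0, rho[..., None], 1.0)
        bump = np.zeros(grid.shape)
        for d, a in zip(dirs, amps):
            cosang = np.clip(uhat @ d, 0.0, 1.0)
            bump += a * cosang**_LOBE_POWER
        threshold = 1.0 + spec.irregularity * bump
    elif spec.shape_kind == "spiky" and spec.irregularity > 0 and spec.n_lobes > 0:
        # azimuthal star perturbation, strongest at the equator, so axial
        # slices are star-shaped with deep concavities
        safe_rho = np.where(rho > 0, rho, 1.0)
        theta = np.arctan2(u[..., 1], u[..., 0])
        sin2_polar = 1.0 - (u[..., 2] / safe_rho) ** 2
        freqs = rng.integers(5, 10, size=spec.n_lobes)
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_lobes)
        amps = rng.uniform(0.5, 1.0, size=spec.n_lobes)
        amps = amps / amps.sum()
        star = np.zeros(grid.shape)
        for m, phi, a in zip(freqs, phases, amps):
            star += a * np.cos(m * theta + phi)
        threshold = np.clip(1.0 + spec.irregularity * star * sin2_polar, 0.25, None)

    tumor = rho <= threshold
    border = np.zeros(grid.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    if (tumor & border).any():
        raise PhantomExceedsGridError("phantom touches the volume border; shrink radii or grid")

    if spec.organ_scale is None:
        return LabelVolume(grid=grid, labels=tumor.astype(np.int16), n_classes=2)

    organ = np.linalg.norm(u / spec.organ_scale, axis=-1) <= 1.0
    if (organ & border).any():
        raise PhantomExceedsGridError("organ shell touches the volume border")
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[organ] = 1
    labels[tumor] = 2
    return LabelVolume(grid=grid, labels=labels, n_classes=3)


def _boundary_jitter(values: np.ndarray, radius: int, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated boundary noise: dilate or erode random surface
    patches with structuring radius <= ``radius``."""
    out = values.copy()
    surface = out & ~ndimage.binary_erosion(out, border_value=0)
    centers = np.argwhere(surface)
    if len(centers) == 0:
        return out
    n_patches = max(1, len(centers) // 50)
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in out.shape], indexing="ij"), axis=-1)
    for _ in range(n_patches):
        c = centers[rng.integers(len(centers))]
        r = int(rng.integers(1, radius + 1))
        patch = np.linalg.norm(coords - c, axis=-1) <= r
        if rng.random() < 0.5:
            out |= ndimage.binary_dilation(out) & patch
        else:
            out &= ~(patch & ~ndimage.binary_erosion(out, border_value=0))
    return out


def corrupt_rater(truth: BinaryMask, spec: RaterSpec) -> BinaryMask:
    """Simulate one rater's mask from the truth with known error rates.

    Voxels inside the truth survive independently with probability equal to
    the sensitivity; voxels in the surrounding band (truth dilated by
    ``roi_margin`` minus truth) turn falsely positive with probability
    1 - specificity; everything further out stays background.  Optional
    seeded morphological jitter then perturbs the boundary.
    """
    if not truth.values.any():
        raise ValueError("corrupt_rater needs a non-empty truth mask")
    rng = np.random.default_rng(np.random.SeedSequence((0x7A7E, spec.seed)))
    t = truth.values
    band = ndimage.binary_dilation(t, iterations=spec.roi_margin) & ~t
    out = np.zeros_like(t)
    out[t] = rng.random(int(t.sum())) < spec.sensitivity
    out[band] = rng.random(int(band.sum())) < (1.0 - spec.specificity)
    if spec.boundary_noise_radius > 0:
        out = _boundary_jitter(out, spec.boundary_noise_radius, rng)
    return BinaryMask(grid=truth.grid, values=out)


def make_probability_map(
    truth: BinaryMask, sharpness: float = 1.0, noise_sd: float = 0.0, seed: int = 0
) -> ProbabilityField:
    """Two-class (background/tumor) probability surrogate for a mask.

    The tumor probability is a logistic of the signed Euclidean distance to
    the mask boundary (positive inside, in mm, steepness ``sharpness`` per
    mm), plus optional seeded Gaussian perturbation, clamped to (0, 1); the
    background class takes the complement so the field sums to one.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    v = truth.values
    spacing = truth.grid.spacing
    if v.any():
        inside = ndimage.distance_transform_edt(v, sampling=spacing)
        outside = ndimage.distance_transform_edt(~v, sampling=spacing)
        signed = inside - outside
    else:
        signed = np.full(truth.grid.shape, -np.inf)
    from scipy.special import expit

    p_tumor = expit(sharpness * signed)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((0x50F7, seed)))
        p_tumor = p_tumor + rng.normal(scale=noise_sd, size=p_tumor.shape)
    p_tumor = np.clip(p_tumor, 1e-6, 1 - 1e-6)
    values = np.stack([1.0 - p_tumor, p_tumor], axis=-1)
    return ProbabilityField(grid=truth.grid, values=values)


def empirical_rater_performance(
    rater: BinaryMask, truth: BinaryMask, roi: np.ndarray
) -> tuple[float, float]:
    """Observed sensitivity and band specificity of a rater mask against the
    generating truth, both evaluated inside ``roi``."""
    t = truth.values & roi
    bg = roi & ~truth.values
    sens = float((rater.values & t).sum() / t.sum()) if t.any() else float("nan")
    spec = float((~rater.values & bg).sum() / bg.sum()) if bg.any() else float("nan")
    return sens, spec


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully determines one synthetic ensemble experiment."""

    n_cases: int = 30
    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid((64, 64, 64), (1.0, 1.0, 1.0)))
    rater_specs: tuple[RaterSpec, ...] = field(
        default_factory=lambda: tuple(heterogeneous_rater_specs())
    )
    staple_params: StapleParams = field(
        default_factory=lambda: StapleParams(roi_mode="union_dilated", roi_margin=3)
    )
    threshold: float = 0.5
    shape_kinds: tuple[str, ...] = ("ellipsoid", "lobulated")
    radii_range: tuple[float, float] = (8.0, 13.0)
    irregularity_range: tuple[float, float] = (0.0, 0.5)
    prob_sharpness: float = 1.5
    prob_noise_sd: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class ExperimentResult:
    """Per-case scores, per-method summary, the paired comparison table and
    the STAPLE parameter-recovery record."""

    per_case: pd.DataFrame
    summary: pd.DataFrame
    comparisons: ComparisonTable
    recovery: pd.DataFrame
    config: ExperimentConfig


def _case_seed(master: int, case: int, stream: int) -> int:
    # fixed fan-out: stable per (case, stream), independent of n_cases
    return int(
        np.random.SeedSequence((master, case, stream)).generate_state(1)[0] & 0x7FFFFFFF
    )


def simulate_case(
    cfg: ExperimentConfig, case_idx: int
) -> tuple[BinaryMask, RaterSet, list[ProbabilityField]]:
    """Generate one case: truth mask, corrupted rater masks and per-rater
    probability maps, all deterministic from the master seed."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.master_seed, case_idx, 0)))
    kind = cfg.shape_kinds[int(rng.integers(len(cfg.shape_kinds)))]
    radii = tuple(rng.uniform(*cfg.radii_range, size=3))
    irregularity = float(rng.uniform(*cfg.irregularity_range)) if kind != "ellipsoid" else 0.0
    phantom = make_phantom(
        PhantomSpec(
            grid=cfg.grid,
            shape_kind=kind,
            radii=radii,
            irregularity=irregularity,
            seed=_case_seed(cfg.master_seed, case_idx, 1),
        )
    )
    truth = BinaryMask(grid=cfg.grid, values=phantom.labels == 1)

    masks, pmaps = [], []
    for j, rspec in enumerate(cfg.rater_specs):
        seeded = replace(rspec, seed=_case_seed(cfg.master_seed, case_idx, 10 + j))
        mask = corrupt_rater(truth, seeded)
        masks.append(mask)
        pmaps.append(
            make_probability_map(
                mask,
                sharpness=cfg.prob_sharpness,
                noise_sd=cfg.prob_noise_sd,
                seed=_case_seed(cfg.master_seed, case_idx, 100 + j),
            )
        )
    names = [f"rater_{j + 1}" for j in range(len(masks))]
    return truth, RaterSet(masks=masks, rater_names=names), pmaps


def run_ensemble_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the full in-silico ensemble study.

    For every case: generate truth and raters, fuse with STAPLE (thresholded
    weights), soft voting (argmax of averaged maps) and strict majority
    voting, score every method and every individual rater, then run the
    paired Wilcoxon + Benjamini–Hochberg comparison protocol.  STAPLE's
    estimated sensitivities/specificities are recorded next to each rater's
    empirical values for parameter-recovery analysis.
    """
    reports: dict[str, list] = {}
    recovery_rows = []
    for i in range(cfg.n_cases):
        case_id = f"case_{i:03d}"
        truth, raters, pmaps = simulate_case(cfg, i)

        staple_res = staple_em(raters, cfg.staple_params)
        fused = {
            "staple": threshold_weights(staple_res, cfg.threshold),
            "soft_voting": BinaryMask(
                grid=cfg.grid, values=argmax_labels(soft_vote(pmaps)).labels == 1
            ),
            "majority_voting": majority_vote(raters),
        }
        for name, mask in zip(raters.rater_names, raters.masks):
            fused[name] = mask

        for method, mask in fused.items():
            reports.setdefault(method, []).append(
                evaluate_case(mask, truth, case_id=case_id, with_solidity=(method == "staple"))
            )

        if cfg.staple_params.roi_mode == "union_dilated":
            roi = ndimage.binary_dilation(
                raters.decision_stack().any(axis=0), iterations=cfg.staple_params.roi_margin
            )
        else:
            roi = np.ones(cfg.grid.shape, dtype=bool)
        for j, (name, mask) in enumerate(zip(raters.rater_names, raters.masks)):
            emp_sens, emp_spec = empirical_rater_performance(mask, truth, roi)
            recovery_rows.append(
                dict(
                    case_id=case_id,
                    rater=name,
                    sensitivity_est=float(staple_res.sensitivities[j]),
                    specificity_est=float(staple_res.specificities[j]),
                    sensitivity_emp=emp_sens,
                    specificity_emp=emp_spec,
                    iterations=staple_res.iterations,
                    converged=staple_res.converged,
                )
            )

    frames = {m: reports_to_frame(r) for m, r in reports.items()}
    summary_rows = []
    for method, frame in frames.items():
        for metric in ("dsc", "ji", "hd95_mm", "precision", "recall"):
            vals = frame[metric].dropna()
            summary_rows.append(
                dict(
                    method=method,
                    metric=metric,
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    n=int(len(vals)),
                )
            )
    per_case = pd.concat(
        [f.assign(method=m) for m, f in frames.items()], ignore_index=True
    )
    comparisons = compare_methods(
        frames,
        staple="staple",
        soft="soft_voting",
        individuals=[n for n in frames if n.startswith("rater_")],
    )
    return ExperimentResult(
        per_case=per_case,
        summary=pd.DataFrame(summary_rows),
        comparisons=comparisons,
        recovery=pd.DataFrame(recovery_rows),
        config=cfg,
    )
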