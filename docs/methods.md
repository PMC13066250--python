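# Methods

## The fusion model

`staplefuse` treats a segmentation ensemble as a rater panel. Each rater j
contributes a binary decision D_ij at every voxel i of a shared grid; the
true segmentation T_i is latent. STAPLE models each rater by two numbers —
sensitivity p_j = P(D_ij = 1 | T_i = 1) and specificity
q_j = P(D_ij = 0 | T_i = 0) — assumed constant over voxels and independent
across raters given the truth. EM alternates a posterior weight field
W_i = P(T_i = 1 | D, p, q, γ) (E-step, evaluated in the log domain) with
closed-form re-estimates of p and q (M-step). Iteration stops when the
largest absolute change in any p_j or q_j drops below the tolerance
(default 1e-4), or at the iteration cap (default 100). The stopping
quantity is the parameter change: it is scale-free and the standard EM
choice when the monitored quantity is otherwise unspecified.

Choices worth knowing:

* **Prior γ.** Fixed at the mean rater foreground fraction inside the
  region of interest, not re-estimated each iteration. Re-estimating the
  prior on tiny foregrounds (tumors are well under 1% of a CT volume) can
  collapse the posterior toward background; the fixed prior is the classic
  safeguard.
* **Initialization.** p_j = q_j = 0.9999 for all raters — near-perfect
  initial trust, appropriate when the raters are trained models rather
  than noisy humans.
* **Clamping.** p and q are clamped to [1e-6, 1−1e-6] before the log-domain
  E-step; without this, perfect agreement drives parameters to exactly 1
  and the next E-step takes log(0).
* **Region of interest.** By default the EM sums run over the full volume.
  On whole-CT backgrounds, specificity is ≈1 for any rater and carries
  almost no information; `roi_mode="union_dilated"` restricts the sums to
  the union of rater masks dilated by a margin (default 3 voxels), which
  makes specificity informative and recoverable. This is explicit
  configuration — it is never applied silently.
* **Degenerate inputs.** A rater set with no foreground anywhere is
  rejected; a single rater is a valid (trivial) panel whose consensus is
  its own mask.

Majority voting uses the strict rule (foreground iff > K/2 raters agree;
even-K ties go to background). Soft voting is the unweighted arithmetic
mean of per-class probability maps; hard labels come from per-voxel argmax
with ties broken toward the lower class index. Multi-class volumes are
fused per foreground class as binary problems and composed with precedence
to the higher class index (tumor over organ) where two classes claim a
voxel.

The STAPLE hardening threshold can be chosen by validation-set grid search
(default grid 0.05 … 0.95 in steps of 0.05, so commonly reported operating
points are representable): the criterion is maximal mean DSC, with ties
broken by minimal mean |precision − recall| and then by the smaller
threshold.

## Loss functions

Forward values only; these characterize predictions and document the
objectives that produce model diversity. Per-voxel cross-entropy is clamped
at 1e-12 inside the log. The Top-K loss ranks per-voxel CE descending and
averages the top ⌈K%·N⌉ voxels, with boundary ties included, so K = 100%
recovers CE exactly. Dice and Generalized Dice share one symmetric
ε-smoothing (ε = 1e-5, identical placement in both), which makes
Generalized Dice with uniform weights equal Dice to machine precision and
defines the empty-class case; values are clipped below at zero, where the
raw ratio can undershoot by O(ε) on perfect predictions. Default
Generalized Dice weights are inverse squared class volume
(w_c = 1/(Σ_i g_ic + ε)²), the convention of the originating formulation;
exponent 1 is available. Hybrid losses are plain sums.

## Evaluation metrics

DSC, Jaccard, precision and recall come from the voxelwise confusion matrix
(prediction positives outside the truth are FP). Degenerate conventions:
both masks empty → all four metrics 1; exactly one empty → zero-denominator
ratios are 0. JI = DSC/(2−DSC) holds algebraically and is asserted in
tests.

HD95 uses surface voxels (foreground with ≥1 face-adjacent background
voxel; the volume border counts as background), Euclidean distances between
voxel centers in mm via the spacing-aware distance transform, both directed
nearest-surface distance sets pooled, and the 95th percentile with linear
interpolation. Pooled-vs-max-of-directed and the percentile rule are pinned
because several variants circulate; `mode="max_directed"` is available. The
metric is undefined when either mask is empty; such cases are dropped
pairwise from HD95 aggregation and paired tests.

Tumor volume is voxel count and millilitres (count × voxel volume / 1000).
Tertile stratification ranks cases ascending by volume (ties by case id)
and cuts three contiguous groups as equal as possible, remainder to the
smaller-volume groups. Solidity is computed on the axial slice of maximal
foreground area — foreground pixels over the rasterized convex hull of
foreground pixel centers — deterministic and representative when slices
are anisotropic; a 3D variant is available. Collinear or single-pixel
slices fall back to exact lattice-segment counting.

## Statistical protocol

Paired two-sided Wilcoxon signed-rank tests compare STAPLE vs soft voting,
STAPLE vs each individual rater, and soft voting vs each individual rater —
1 + K + K rows per metric family (11 with K = 5). Majority voting is
reported descriptively and never tested. Zero differences are discarded
(classic convention); tied absolute differences get mean ranks; the null is
exact by enumeration for n ≤ 25 without ties, otherwise a normal
approximation with tie and continuity corrections. Benjamini–Hochberg
adjustment runs within each metric family at α = 0.05. All-zero-difference
rows are flagged degenerate and reported non-significant rather than
failing the run. Note that BH step-up adjusted values are *not* fixed
points of re-adjustment; only monotonicity and domination of the raw p are
guaranteed. Sample skewness is the bias-corrected (adjusted Fisher–Pearson)
estimator.

## The synthetic generator

Phantoms are tumor-like blobs on a 64³ grid at 1 mm isotropic spacing by
default: ellipsoids (solidity ≈ 1), lobulated shapes (broad radial bumps
along random directions), and spiky shapes (an equator-weighted azimuthal
star perturbation whose axial slices have deep concavities, reaching
solidity < 0.7 at irregularity ≈ 1.2). A smooth enclosing organ shell is
optional. Phantoms touching the volume border are rejected.

Raters corrupt the truth with known error rates: inside the truth each
voxel survives with probability = sensitivity; inside the band (truth
dilated by a margin, default 3 voxels, minus truth) each voxel turns
falsely positive with probability = 1 − specificity; nothing appears
further out. Specificity is defined on the band, not the volume, because
whole-volume specificity is ≈ 1 regardless of rater quality and would be
unrecoverable. Optional morphological boundary jitter (seeded
dilation/erosion of random surface patches) adds spatially correlated
disagreement closer to real model behaviour than i.i.d. flips.

Probability-map surrogates for softmax outputs are a logistic of the signed
Euclidean distance to the mask boundary (default steepness 1.5 per mm,
Gaussian perturbation sd 0.05, clamped and renormalized) — these defaults
were chosen once as a realistic amount of softmax blur and are not tuned
per experiment.

The default rater panel has sensitivities (0.95, 0.90, 0.85, 0.70, 0.60) at
band specificity 0.995 — a deliberately heterogeneous reliability mix under
which reliability-weighted fusion can demonstrate its advantage. The
experiment harness runs STAPLE with the union-dilated ROI (so the
generating specificities are identifiable) and hardens at 0.5; real-data
workflows should pick the threshold by grid search on a validation set.

Seeding: a master seed fans out to per-case, per-rater child seeds through
fixed `SeedSequence` arithmetic, so results are bit-reproducible and adding
cases never reshuffles existing ones.

What the generator does *not* emulate: CT intensities and their artefacts,
anatomically realistic organs, spatially varying rater performance, and the
error correlations of models trained on shared data. Passing tests
demonstrate correctness of the algorithms under the stated observation
model, not performance on any clinical dataset; on real data the i.i.d.
rater-error assumption is optimistic for STAPLE.

## Problem sizes

The simulation experiments use 64³ grids with 20 cases (parameter recovery)
and 30 cases (fusion hierarchy); metric oracles use 1000 random 8³ mask
pairs and 100 random 10³ pairs for HD95; the null-calibration check uses
2000 Wilcoxon replicates of 30 pairs. These sizes give stable estimates at
desk scale — the full suite and the acceptance script each finish in about
a minute and a half on one CPU.

## Known limitations

* Binary STAPLE only; multi-label fusion is per-class composition, not a
  joint multi-category model. Spatially varying performance (Local MAP
  STAPLE) and rater-selection schemes (SIMPLE) are out of scope.
* Constant per-rater performance over the volume; violated near boundaries
  in practice.
* No resampling: volumes must share a grid, and mismatches are errors.
* Losses are forward-only — no gradients or training.
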