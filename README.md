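# staplefuse

Multi-rater fusion of tumor segmentations, with the evaluation and
statistics to decide whether fusion actually helped.

When several independently trained segmentation models (or human raters)
produce candidate tumor masks for the same CT volume, the masks disagree —
especially for small or irregular tumors. `staplefuse` implements three
ways of combining K binary masks into one consensus and a full pipeline for
comparing them:

* **Majority voting** — a voxel is tumor iff strictly more than K/2 raters
  say so.
* **Soft voting** — the unweighted mean of per-class softmax probability
  maps, hardened by per-voxel argmax.
* **STAPLE** (Simultaneous Truth and Performance Level Estimation) — an EM
  algorithm over the rater decision matrix D_ij that treats the true label
  T_i as latent. With prior γ = P(T_i = 1), rater sensitivities p_j and
  specificities q_j, the E-step computes the posterior weight

      W_i = γ ∏_j p_j^{D_ij}(1−p_j)^{1−D_ij} /
            [ γ ∏_j p_j^{D_ij}(1−p_j)^{1−D_ij} +
              (1−γ) ∏_j (1−q_j)^{D_ij} q_j^{1−D_ij} ]

  and the M-step re-estimates p_j = Σ_i W_i D_ij / Σ_i W_i and
  q_j = Σ_i (1−W_i)(1−D_ij) / Σ_i (1−W_i), until the largest parameter
  change falls below 1e-4 (at most 100 iterations; initialization 0.9999).
  The weight field is hardened at a threshold chosen by validation-set grid
  search maximizing mean DSC with balanced precision/recall.

Around the fusion core the package provides:

* **Metrics** — DSC, Jaccard, precision, recall from the voxel confusion
  matrix; 95th-percentile Hausdorff distance in mm; tumor volume, tertile
  size stratification, and solidity (area / convex-hull area) for
  morphology analysis.
* **Statistics** — paired two-sided Wilcoxon signed-rank tests (exact for
  n ≤ 25 without ties) between STAPLE, soft voting and each individual
  rater — 11 comparisons per metric with 5 raters — with
  Benjamini–Hochberg FDR control within each metric family.
* **Losses** — forward values of cross-entropy, Top-K, Dice, Generalized
  Dice and their hybrid sums, the objectives whose pairing produces diverse
  model variants.
* **Simulation** — synthetic tumor phantoms (ellipsoid / lobulated / spiky,
  i.e. controllable solidity) and rater corruptions with *known*
  sensitivity/specificity, so every claim above is testable end-to-end
  without any imaging dataset.

## Worked example

```python
from staplefuse import ExperimentConfig, run_ensemble_experiment

cfg = ExperimentConfig(n_cases=10, master_seed=0)   # 5 raters, 64³ phantoms
result = run_ensemble_experiment(cfg)
print(result.summary.query("metric == 'dsc'").set_index("method")[["mean", "sd"]].round(4))
```

```
                   mean      sd
method
staple           0.9982  0.0003
soft_voting      0.9780  0.0011
majority_voting  0.9776  0.0011
rater_1          0.9722  0.0009
rater_2          0.9450  0.0030
rater_3          0.9183  0.0035
rater_4          0.8233  0.0038
rater_5          0.7480  0.0045
```

The default panel simulates five raters with sensitivities 0.95 … 0.60 at
band specificity 0.995. STAPLE, by weighting raters by their estimated
reliability, beats equal-weight soft voting, which beats strict majority
voting; all three beat every individual rater. The recovery record shows
the EM estimates track the true per-rater error rates
(`(result.recovery.sensitivity_est - result.recovery.sensitivity_emp).abs().mean()`
→ 0.0007 here), and the comparison table carries the formal test, e.g.
STAPLE vs soft voting on DSC: adjusted p = 0.00195.

## Command line

```bash
staplefuse fuse --method staple --rater m1.nii.gz --rater m2.nii.gz ... --output fused.nii.gz
staplefuse evaluate --pred fused.nii.gz --truth gt.nii.gz --output report.csv
staplefuse compare --report staple=staple.csv --report soft_voting=soft.csv \
    --report m1=m1.csv --output comparisons.csv
staplefuse simulate --config experiment.yaml --outdir results/
```

Volumes are NIfTI with spacing taken from the header; mismatched grids or
orientations are an error, never silently fixed.

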