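import numpy as np
import pytest

from staplefuse.fusion import (
    DEFAULT_THRESHOLD_GRID,
    RaterSet,
    StapleParams,
    StapleResult,
    _estep_weights,
    argmax_labels,
    fuse_multiclass,
    grid_search_threshold,
    majority_vote,
    soft_vote,
    staple_em,
    threshold_weights,
)
from staplefuse.grids import (
    BinaryMask,
    DegenerateInputError,
    LabelVolume,
    ProbabilityField,
    VoxelGrid,
)
from staplefuse.simulate import (
    ExperimentConfig,
    empirical_rater_performance,
    simulate_case,
)

from conftest import random_mask, random_probability_field


def mask_from_flags(grid, flags):
    values = np.zeros(grid.shape, bool)
    values.flat[: len(flags)] = flags
    return BinaryMask(grid, values)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "k, positives, expected",
        [(5, 3, True), (5, 2, False), (4, 2, False), (1, 1, True)],
        ids=["3-of-5", "2-of-5", "even-tie", "single-rater"],
    )
    def test_strict_majority_rule(self, unit_grid, k, positives, expected):
        masks = [
            mask_from_flags(unit_grid, [j < positives]) for j in range(k)
        ]
        fused = majority_vote(RaterSet(masks=masks))
        assert bool(fused.values.flat[0]) is expected


class TestSoftVote:
    def test_identical_inputs_are_identity(self, unit_grid, rng):
        pmap = random_probability_field(unit_grid, rng)
        out = soft_vote([pmap, pmap, pmap])
        np.testing.assert_allclose(out.values, pmap.values)

    def test_mean_of_two_probabilities(self, unit_grid):
        def field(p):
            vals = np.zeros(unit_grid.shape + (2,))
            vals[..., 1] = p
            vals[..., 0] = 1 - p
            return ProbabilityField(unit_grid, vals)

        out = soft_vote([field(0.8), field(0.4)])
        assert out.values[0, 0, 0, 1] == pytest.approx(0.6)

    def test_average_then_argmax_differs_from_argmax_vote(self, unit_grid):
        # voxelwise 3-class toy: (0.6, 0.4, 0.0) and (0.0, 0.4, 0.6) -> each
        # map's argmax avoids class 1, but the averaged map selects class 1
        def field(trip):
            vals = np.zeros(unit_grid.shape + (3,))
            vals[...] = trip
            return ProbabilityField(unit_grid, vals)

        a, b = field((0.6, 0.4, 0.0)), field((0.0, 0.4, 0.6))
        fused_labels = argmax_labels(soft_vote([a, b]))
        assert np.all(fused_labels.labels == 1)
        assert np.all(argmax_labels(a).labels == 0)
        assert np.all(argmax_labels(b).labels == 2)


class TestArgmaxLabels:
    def test_one_hot_map_round_trips(self, unit_grid, rng):
        labels = rng.integers(0, 3, size=unit_grid.shape)
        vals = np.eye(3)[labels]
        out = argmax_labels(ProbabilityField(unit_grid, vals))
        assert np.array_equal(out.labels, labels)

    def test_exact_tie_goes_to_lower_class(self, unit_grid):
        vals = np.full(unit_grid.shape + (2,), 0.5)
        assert np.all(argmax_labels(ProbabilityField(unit_grid, vals)).labels == 0)

    def test_argmax_probability_dominates(self, unit_grid, rng):
        pmap = random_probability_field(unit_grid, rng)
        labels = argmax_labels(pmap).labels
        chosen = np.take_along_axis(pmap.values, labels[..., None], axis=-1)
        assert np.all(chosen >= pmap.values - 1e-15)


class TestStapleEM:
    def test_perfect_agreement_fixed_point(self, unit_grid, rng):
        mask = random_mask(unit_grid, rng, p=0.2)
        raters = RaterSet(masks=[mask] * 5)
        result = staple_em(raters)
        assert np.all(result.sensitivities >= 0.99)
        assert np.all(result.specificities >= 0.99)
        for t in (0.02, 0.5, 0.98):
            fused = threshold_weights(result, t)
            assert np.array_equal(fused.values, mask.values)

    def test_single_rater_reproduces_its_mask(self, unit_grid, rng):
        mask = random_mask(unit_grid, rng, p=0.3)
        result = staple_em(RaterSet(masks=[mask]))
        assert np.array_equal(threshold_weights(result, 0.5).values, mask.values)

    def test_all_empty_raters_rejected(self, unit_grid):
        empty = BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool))
        with pytest.raises(DegenerateInputError):
            staple_em(RaterSet(masks=[empty, empty]))

    def test_recovers_simulated_rater_performance(self):
        """EM sensitivity/specificity estimates track the empirical rates of
        simulated raters with heterogeneous reliability (within +/-0.03)."""
        from scipy import ndimage

        cfg = ExperimentConfig(n_cases=1, master_seed=41)
        truth, raters, _ = simulate_case(cfg, 0)
        result = staple_em(raters, cfg.staple_params)
        roi = ndimage.binary_dilation(
            raters.decision_stack().any(axis=0), iterations=cfg.staple_params.roi_margin
        )
        for j, mask in enumerate(raters.masks):
            emp_sens, emp_spec = empirical_rater_performance(mask, truth, roi)
            assert result.sensitivities[j] == pytest.approx(emp_sens, abs=0.03)
            assert result.specificities[j] == pytest.approx(emp_spec, abs=0.03)

    def test_rater_permutation_equivariance(self, unit_grid, rng):
        masks = [random_mask(unit_grid, rng, p=0.25) for _ in range(4)]
        res = staple_em(RaterSet(masks=masks))
        perm = [2, 0, 3, 1]
        res_p = staple_em(RaterSet(masks=[masks[j] for j in perm]))
        np.testing.assert_allclose(res_p.sensitivities, res.sensitivities[perm], atol=1e-10)
        np.testing.assert_allclose(res_p.specificities, res.specificities[perm], atol=1e-10)
        np.testing.assert_allclose(res_p.weights, res.weights, atol=1e-10)

    def test_estep_weight_monotone_in_rater_agreement(self, rng):
        # with better-than-chance raters, a voxel endorsed by a superset of
        # raters never gets a smaller posterior weight
        k = 5
        p = rng.uniform(0.6, 0.99, size=k)
        q = rng.uniform(0.6, 0.99, size=k)
        subsets = [(0b00000 | m) for m in range(32)]
        D = np.array([[(m >> j) & 1 for m in subsets] for j in range(k)], dtype=bool)
        w = _estep_weights(D, p, q, gamma=0.3)
        for a in range(32):
            for b in range(32):
                if a & b == a and a != b:  # a's raters are a subset of b's
                    assert w[a] <= w[b] + 1e-12

    def test_matches_simpleitk_reference(self):
        """Full-volume EM agrees with the independent ITK implementation on
        per-rater performance estimates and the hardened consensus."""
        sitk = pytest.importorskip("SimpleITK")
        cfg = ExperimentConfig(n_cases=1, master_seed=5, staple_params=StapleParams())
        _, raters, _ = simulate_case(cfg, 0)
        ours = staple_em(raters, StapleParams())
        filt = sitk.STAPLEImageFilter()
        filt.SetForegroundValue(1)
        filt.SetMaximumIterations(100)
        ref = filt.Execute([
            sitk.GetImageFromArray(m.values.astype(np.uint8)) for m in raters.masks
        ])
        np.testing.assert_allclose(ours.sensitivities, filt.GetSensitivity(), atol=0.01)
        np.testing.assert_allclose(ours.specificities, filt.GetSpecificity(), atol=0.01)
        w_ref = sitk.GetArrayFromImage(ref).transpose(2, 1, 0)
        agreement = np.mean((w_ref >= 0.5) == (ours.weights >= 0.5))
        assert agreement >= 0.98


class TestThresholdWeights:
    def test_threshold_is_inclusive(self, unit_grid):
        w = np.zeros(unit_grid.shape)
        w.flat[:3] = [0.1, 0.2, 0.9]
        res = StapleResult(unit_grid, w, [0.9], [0.9], 1, True, 0.1)
        out = threshold_weights(res, 0.2)
        assert list(out.values.flat[:3]) == [False, True, True]

    def test_near_one_keeps_only_certain_voxels(self, unit_grid):
        w = np.zeros(unit_grid.shape)
        w.flat[:2] = [1.0, 0.5]
        res = StapleResult(unit_grid, w, [0.9], [0.9], 1, True, 0.1)
        assert threshold_weights(res, 0.99).foreground_count == 1

    def test_out_of_range_threshold(self, unit_grid):
        res = StapleResult(unit_grid, np.zeros(unit_grid.shape), [0.9], [0.9], 1, True, 0.1)
        for t in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                threshold_weights(res, t)

    def test_masks_nested_as_threshold_grows(self, unit_grid, rng):
        res = StapleResult(
            unit_grid, rng.random(unit_grid.shape), [0.9], [0.9], 1, True, 0.1
        )
        prev = threshold_weights(res, 0.05).values
        for t in np.arange(0.15, 1.0, 0.1):
            cur = threshold_weights(res, float(t)).values
            assert np.all(cur <= prev)
            prev = cur


class TestGridSearchThreshold:
    def _result(self, grid, weights):
        w = np.zeros(grid.shape)
        w.flat[: len(weights)] = weights
        return StapleResult(grid, w, [0.9], [0.9], 1, True, 0.1)

    def test_single_element_grid(self, unit_grid, rng):
        res = self._result(unit_grid, rng.random(16))
        truth = random_mask(unit_grid, rng)
        assert grid_search_threshold([res], [truth], grid=[0.35]) == 0.35

    def test_exact_truth_threshold_recovered(self, unit_grid):
        # continuous weight spread: any lower threshold adds false positives,
        # any higher one loses true positives, so 0.30 is the unique optimum
        n = unit_grid.n_voxels
        w = np.linspace(0.01, 0.99, n)
        res = self._result(unit_grid, w)
        truth = BinaryMask(unit_grid, (res.weights >= 0.3))
        assert grid_search_threshold([res], [truth], grid=DEFAULT_THRESHOLD_GRID) == 0.30

    @pytest.mark.parametrize(
        "weights, truth_idx, expected",
        [
            # equal DSC at both thresholds; the balanced precision/recall wins
            ([0.2, 0.5, 0.5, 0.5, 0.5, 0.8], [0, 1, 5], 0.4),
            ([0.5, 0.5, 0.5, 0.5, 0.8, 0.8], [0, 4], 0.6),
        ],
        ids=["lower-threshold-balanced", "higher-threshold-balanced"],
    )
    def test_dsc_tie_broken_by_precision_recall_balance(
        self, unit_grid, weights, truth_idx, expected
    ):
        res = self._result(unit_grid, weights)
        tv = np.zeros(unit_grid.shape, bool)
        tv.flat[truth_idx] = True
        truth = BinaryMask(unit_grid, tv)
        assert grid_search_threshold([res], [truth], grid=[0.4, 0.6]) == expected


class TestFuseMulticlass:
    def test_unanimous_raters_identity(self, unit_grid, rng):
        labels = rng.integers(0, 3, size=unit_grid.shape)
        vols = [LabelVolume(unit_grid, labels, 3) for _ in range(5)]
        for method in ("majority", "staple"):
            fused = fuse_multiclass(vols, method=method)
            assert np.array_equal(fused.labels, labels)

    def test_majority_overlap_resolves_to_higher_class(self, unit_grid):
        # 3 of 5 raters say tumor (strict majority), 2 say organ -> tumor
        a = np.zeros(unit_grid.shape, int)
        a.flat[0] = 1
        b = np.zeros(unit_grid.shape, int)
        b.flat[0] = 2
        vols = [LabelVolume(unit_grid, a, 3)] * 2 + [LabelVolume(unit_grid, b, 3)] * 3
        fused = fuse_multiclass(vols, method="majority")
        assert fused.labels.flat[0] == 2

    def test_staple_double_claim_resolves_to_higher_class(self):
        # per-class STAPLE lets organ and tumor consensus both claim the
        # overlap of two blobs; composition must hand it to the tumor class
        grid = VoxelGrid((12, 12, 12))
        a = np.zeros(grid.shape, int)
        a[3:9, 3:9, 3:9] = 1
        b = np.zeros(grid.shape, int)
        b[5:11, 5:11, 5:11] = 2
        vols = [LabelVolume(grid, a, 3)] * 3 + [LabelVolume(grid, b, 3)] * 2
        fused = fuse_multiclass(vols, method="staple", threshold=0.5)
        overlap = (a == 1) & (b == 2)
        assert set(np.unique(fused.labels[overlap])) == {2}
        assert (fused.labels == 1).sum() > 0  # organ survives outside overlap

    def test_majority_method_equals_per_class_votes(self, unit_grid, rng):
        vols = [
            LabelVolume(unit_grid, rng.integers(0, 3, size=unit_grid.shape), 3)
            for _ in range(5)
        ]
        fused = fuse_multiclass(vols, method="majority")
        from staplefuse.grids import extract_class_mask

        expected = np.zeros(unit_grid.shape, int)
        for c in (1, 2):
            vote = majority_vote(RaterSet(masks=[extract_class_mask(v, c) for v in vols]))
            expected[vote.values] = c
        assert np.array_equal(fused.labels, expected)
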