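"""Consensus construction and accuracy metrics against ground truth."""

import numpy as np
import pytest

from plexuq import (
    BinaryMask,
    ImageGrid,
    ScalarVolume,
    binarize,
    dice,
    hausdorff,
    majority_vote,
    threshold_sweep,
    volume_correlation,
    volume_similarity,
)
from plexuq.grids import GridMismatchError
from plexuq.seg_metrics import evaluate_subject


def mask_from_coords(grid, coords):
    values = np.zeros(grid.shape, dtype=np.uint8)
    for c in coords:
        values[c] = 1
    return BinaryMask(grid, values)


@pytest.fixture
def grid4():
    return ImageGrid.from_spacing((4, 4, 4))


class TestBinarize:
    def test_tie_goes_to_foreground(self, grid16):
        vol = ScalarVolume(grid16, np.full(grid16.shape, 0.5), is_probability=True)
        assert binarize(vol, 0.5).n_foreground == grid16.n_voxels

    @pytest.mark.parametrize("p,expected", [(0.49, 0), (0.51, 1)])
    def test_strict_neighbourhood_of_threshold(self, grid16, p, expected):
        vol = ScalarVolume(grid16, np.full(grid16.shape, p), is_probability=True)
        assert int(binarize(vol, 0.5).values[0, 0, 0]) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_nesting_in_threshold(self, grid16, seed):
        rng = np.random.default_rng(seed)
        vol = ScalarVolume(grid16, rng.random(grid16.shape), is_probability=True)
        hi = binarize(vol, 0.6).astype_bool()
        lo = binarize(vol, 0.4).astype_bool()
        assert np.all(lo[hi])  # mask at 0.6 is a subset of mask at 0.4

    def test_invalid_threshold(self, grid16):
        vol = ScalarVolume(grid16, np.zeros(grid16.shape), is_probability=True)
        with pytest.raises(ValueError):
            binarize(vol, 1.5)


class TestMajorityVote:
    def test_three_of_five(self, grid4):
        fg = [mask_from_coords(grid4, [(0, 0, 0)])] * 3
        bg = [mask_from_coords(grid4, [])] * 2
        assert majority_vote(fg + bg).values[0, 0, 0] == 1

    def test_two_of_five(self, grid4):
        fg = [mask_from_coords(grid4, [(0, 0, 0)])] * 2
        bg = [mask_from_coords(grid4, [])] * 3
        assert majority_vote(fg + bg).values[0, 0, 0] == 0

    def test_even_split_tie_is_background(self, grid4):
        fg = [mask_from_coords(grid4, [(0, 0, 0)])] * 2
        bg = [mask_from_coords(grid4, [])] * 2
        assert majority_vote(fg + bg).values[0, 0, 0] == 0

    def test_single_mask_identity(self, grid4):
        m = mask_from_coords(grid4, [(1, 2, 3), (0, 0, 0)])
        assert np.array_equal(majority_vote([m]).values, m.values)

    @pytest.mark.parametrize("members", [1, 3, 5, 7])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_equivalence_with_mean_threshold_for_odd_m(self, grid16, members, seed):
        """For odd M binary stacks, majority vote == binarize(mean, 0.5)."""
        rng = np.random.default_rng(seed)
        masks = [
            BinaryMask(grid16, (rng.random(grid16.shape) > 0.5).astype(np.uint8))
            for _ in range(members)
        ]
        mean = ScalarVolume(
            grid16, np.mean([m.values for m in masks], axis=0), is_probability=True
        )
        assert np.array_equal(majority_vote(masks).values, binarize(mean, 0.5).values)

    def test_grid_mismatch(self, grid4):
        other = ImageGrid.from_spacing((4, 4, 4), (1, 1, 2))
        with pytest.raises(GridMismatchError):
            majority_vote([mask_from_coords(grid4, []), mask_from_coords(other, [])])


class TestDice:
    def test_identical_masks(self, grid4):
        m = mask_from_coords(grid4, [(0, 0, 0), (1, 1, 1)])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self, grid4):
        a = mask_from_coords(grid4, [(0, 0, 0)])
        b = mask_from_coords(grid4, [(3, 3, 3)])
        assert dice(a, b) == 0.0

    def test_hand_counted_overlap(self, grid4):
        """|a| = 3, |m| = 4, overlap 2 -> Dice = 4/7."""
        a = mask_from_coords(grid4, [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        m = mask_from_coords(grid4, [(1, 0, 0), (2, 0, 0), (3, 0, 0), (3, 3, 3)])
        assert dice(a, m) == pytest.approx(4 / 7)

    def test_symmetry(self, grid16):
        rng = np.random.default_rng(2)
        a = BinaryMask(grid16, (rng.random(grid16.shape) > 0.7).astype(np.uint8))
        b = BinaryMask(grid16, (rng.random(grid16.shape) > 0.7).astype(np.uint8))
        assert dice(a, b) == dice(b, a)

    def test_both_empty_warns_and_returns_one(self, grid4):
        empty = mask_from_coords(grid4, [])
        with pytest.warns(RuntimeWarning):
            assert dice(empty, empty) == 1.0

    def test_one_empty_is_zero(self, grid4):
        assert dice(mask_from_coords(grid4, []), mask_from_coords(grid4, [(0, 0, 0)])) == 0.0


class TestHausdorff:
    def test_identical_masks_zero(self, grid16):
        rng = np.random.default_rng(0)
        m = BinaryMask(grid16, (rng.random(grid16.shape) > 0.8).astype(np.uint8))
        assert hausdorff(m, m) == 0.0

    def test_single_voxels_axis_distance(self):
        grid = ImageGrid.from_spacing((8, 8, 8), (1, 1, 1))
        a = mask_from_coords(grid, [(2, 4, 4)])
        b = mask_from_coords(grid, [(5, 4, 4)])
        assert hausdorff(a, b) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        grid = ImageGrid.from_spacing((8, 8, 8), (0.5, 1, 1))
        a = mask_from_coords(grid, [(2, 4, 4)])
        b = mask_from_coords(grid, [(5, 4, 4)])
        assert hausdorff(a, b) == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetry_identity_and_hd95_bound(self, seed):
        grid = ImageGrid.from_spacing((10, 10, 10), (1.0, 1.2, 0.8))
        rng = np.random.default_rng(seed)
        a = BinaryMask(grid, (rng.random(grid.shape) > 0.85).astype(np.uint8))
        b = BinaryMask(grid, (rng.random(grid.shape) > 0.85).astype(np.uint8))
        if a.n_foreground == 0 or b.n_foreground == 0:
            pytest.skip("degenerate draw")
        hd_ab, hd_ba = hausdorff(a, b), hausdorff(b, a)
        assert hd_ab == pytest.approx(hd_ba)
        assert hausdorff(a, b, percentile=95) <= hd_ab + 1e-12
        assert hausdorff(a, a) == 0.0

    def test_empty_mask_rejected(self, grid4):
        with pytest.raises(ValueError):
            hausdorff(mask_from_coords(grid4, []), mask_from_coords(grid4, [(0, 0, 0)]))


class TestVolumeSimilarity:
    def test_equal_volumes(self, grid4):
        a = mask_from_coords(grid4, [(0, 0, 0), (1, 1, 1)])
        b = mask_from_coords(grid4, [(2, 2, 2), (3, 3, 3)])
        assert volume_similarity(a, b) == 1.0

    def test_unbalanced(self, grid4):
        """|a| = 2, |m| = 6 -> VS = 1 - 4/8 = 0.5."""
        a = mask_from_coords(grid4, [(0, 0, 0), (0, 0, 1)])
        m = mask_from_coords(grid4, [(i, 0, 0) for i in range(4)] + [(0, 1, 0), (0, 2, 0)])
        assert volume_similarity(a, m) == pytest.approx(0.5)

    def test_one_empty(self, grid4):
        assert volume_similarity(mask_from_coords(grid4, []), mask_from_coords(grid4, [(0, 0, 0)])) == 0.0

    def test_both_empty_error(self, grid4):
        with pytest.raises(ValueError):
            volume_similarity(mask_from_coords(grid4, []), mask_from_coords(grid4, []))


class TestVolumeCorrelation:
    def test_perfect_agreement(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert volume_correlation(v, v) == pytest.approx(1.0)

    def test_affine_invariance(self):
        truth = [1.0, 2.0, 3.0, 5.0]
        auto = [2 * t + 5 for t in truth]
        assert volume_correlation(auto, truth) == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x = rng.random(5)
        y = rng.random(5)
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert volume_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            volume_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestThresholdSweep:
    def test_half_column_matches_direct_dice(self, grid16):
        rng = np.random.default_rng(4)
        mean = ScalarVolume(grid16, rng.random(grid16.shape), is_probability=True)
        truth = BinaryMask(grid16, (rng.random(grid16.shape) > 0.5).astype(np.uint8))
        table = threshold_sweep([mean], [truth], [0.3, 0.5, 0.7], subject_ids=["s"])
        row = table[(table.subject_id == "s") & (table.threshold == 0.5)]
        assert row.dice.iloc[0] == pytest.approx(dice(binarize(mean, 0.5), truth))

    def test_degenerate_maps_constant_over_thresholds(self, grid16):
        values = np.zeros(grid16.shape)
        values[2:6, 2:6, 2:6] = 1.0
        mean = ScalarVolume(grid16, values, is_probability=True)
        truth = BinaryMask(grid16, values.astype(np.uint8))
        table = threshold_sweep([mean], [truth], np.linspace(0.1, 0.9, 9))
        subject_rows = table[table.subject_id != "__mean__"]
        assert subject_rows.dice.nunique() == 1
        assert subject_rows.dice.iloc[0] == 1.0


class TestEvaluateSubject:
    def test_full_report(self, grid16):
        values = np.zeros(grid16.shape, dtype=np.uint8)
        values[4:8, 4:8, 4:8] = 1
        truth = BinaryMask(grid16, values)
        res = evaluate_subject(truth, truth, subject_id="s0")
        assert res.dice == 1.0
        assert res.hausdorff_mm == 0.0
        assert res.hausdorff95_mm <= res.hausdorff_mm
        assert res.volume_similarity == 1.0
        assert res.auto_volume_mm3 == res.truth_volume_mm3 == 64.0
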