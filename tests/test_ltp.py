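import numpy as np
import pytest

import oracles
from cageclimb import FrameStack, RegionOfInterest
from cageclimb.ltp import (
    LTPParams,
    coded_margin,
    ltp_feature,
    ltp_feature_matrix,
    ltp_features_for_segment,
    trit_codes,
)


def _stack(rng, n=5, h=20, w=24):
    return FrameStack(rng.integers(0, 256, (n, h, w)).astype(np.uint8))


class TestTritCodes:
    def test_static_video_all_zero_codes(self):
        stack = FrameStack(np.full((5, 16, 16), 77, dtype=np.uint8))
        b_pos, b_neg = trit_codes(stack, RegionOfInterest(0, 0, 16, 16), 2)
        assert not b_pos.any() and not b_neg.any()

    def test_disjoint_set_bits(self, rng):
        stack = _stack(rng)
        b_pos, b_neg = trit_codes(stack, RegionOfInterest(0, 0, 24, 20), 2)
        assert not (b_pos & b_neg).any()

    def test_bit_assignment(self):
        """A +1 trit on offset 0 and a -1 on offset 7 give codes 1 and 128.

        Built by making the past patch at offset 0 differ strongly while
        the future matches, and vice versa for offset 7, everywhere else
        past == future so trits are 0.
        """
        params = LTPParams(patch_half=0, neighbor_radius=1, temporal_gap=1)
        h = w = 5
        center = 2  # the only coded pixel in a 5x5 ROI is not this one; margin=1 -> 3x3 coded
        past = np.full((h, w), 10, dtype=np.uint8)
        now = np.full((h, w), 10, dtype=np.uint8)
        future = np.full((h, w), 10, dtype=np.uint8)
        # offset 0 = (-1,-1): past patch differs -> d_minus > d_plus -> trit +1 (bit 0)
        past[1, 1] = 200
        # offset 7 = (0,-1): future patch differs -> trit -1 (bit 7)
        future[2, 1] = 200
        stack = FrameStack(np.stack([past, now, future]))
        b_pos, b_neg = trit_codes(stack, RegionOfInterest(0, 0, w, h), 1, params)
        assert b_pos[2, 2] == 1
        assert b_neg[2, 2] == 128
        # the perturbed pixels also affect their other neighbours, but
        # pixel (2,2) sees them only through offsets 0 and 7

    def test_time_reversal_swaps_codes(self, rng):
        """Reversing time exchanges past and future SSDs, hence B+ and B-."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            stack = _stack(r, n=5, h=14, w=15)
            roi = RegionOfInterest(0, 0, 15, 14)
            rev = FrameStack(stack.frames[::-1].copy())
            b_pos, b_neg = trit_codes(stack, roi, 2)
            r_pos, r_neg = trit_codes(rev, roi, 2)
            np.testing.assert_array_equal(b_pos, r_neg)
            np.testing.assert_array_equal(b_neg, r_pos)

    def test_temporal_range_enforced(self, rng):
        stack = _stack(rng)
        roi = RegionOfInterest(0, 0, 24, 20)
        with pytest.raises(IndexError):
            trit_codes(stack, roi, 1)
        with pytest.raises(IndexError):
            trit_codes(stack, roi, 3)

    def test_matches_per_pixel_oracle(self, rng):
        params = LTPParams(patch_half=1, neighbor_radius=1, temporal_gap=1)
        stack = _stack(rng, n=3, h=10, w=12)
        roi = RegionOfInterest(1, 1, 10, 8)
        b_pos, b_neg = trit_codes(stack, roi, 1, params)
        o_pos, o_neg = oracles.ltp_oracle_trits(stack.frames, roi, 1, params)
        np.testing.assert_array_equal(b_pos, o_pos)
        np.testing.assert_array_equal(b_neg, o_neg)


class TestFeature:
    def test_default_dimension_is_16384(self, rng):
        stack = FrameStack(rng.integers(0, 256, (5, 400, 700)).astype(np.uint8))
        fv = ltp_feature(stack, RegionOfInterest(0, 0, 690, 385), 2)
        assert fv.values.size == 16384
        assert LTPParams().dimension == 16384

    def test_static_video_indicator_of_bin_zero(self):
        stack = FrameStack(np.full((5, 40, 48), 100, dtype=np.uint8))
        fv = ltp_feature(stack, RegionOfInterest(0, 0, 48, 40), 2)
        hists = fv.values.reshape(-1, 256)
        np.testing.assert_allclose(hists[:, 0], 1.0)
        assert not hists[:, 1:].any()

    def test_uniform_intensity_shift_invariance(self, rng):
        stack = _stack(rng, h=16, w=18)
        roi = RegionOfInterest(0, 0, 18, 16)
        # halve intensities first so the +20 shift cannot clip at 255
        stack2 = FrameStack(stack.frames // 2)
        shifted2 = FrameStack(stack2.frames + 20)
        a = ltp_feature(stack2, roi, 2).values
        b = ltp_feature(shifted2, roi, 2).values
        np.testing.assert_array_equal(a, b)

    def test_l1_normalization_per_histogram(self, rng):
        stack = _stack(rng, h=20, w=24)
        fv = ltp_feature(stack, RegionOfInterest(0, 0, 24, 20), 2,
                         LTPParams(grid_cols=2, grid_rows=2))
        hists = fv.values.reshape(-1, 256)
        sums = hists.sum(axis=1)
        assert np.all((np.isclose(sums, 1.0)) | (sums == 0))

    @pytest.mark.parametrize(
        "params",
        [
            LTPParams(),
            LTPParams(patch_half=0, neighbor_radius=1, temporal_gap=1),
            LTPParams(patch_half=1, neighbor_radius=2, temporal_gap=2,
                      grid_cols=2, grid_rows=2),
            LTPParams(ssd_threshold=500.0),
            LTPParams(normalize="none"),
        ],
    )
    def test_matches_brute_force_oracle(self, params):
        rng = np.random.default_rng(7)
        stack = FrameStack(rng.integers(0, 256, (7, 20, 26)).astype(np.uint8))
        roi = RegionOfInterest(2, 1, 22, 18)
        t = params.temporal_gap
        got = ltp_feature(stack, roi, t, params).values
        expected = oracles.ltp_oracle_feature(stack.frames, roi, t, params)
        np.testing.assert_array_equal(got, expected)

    def test_roi_too_small_for_margin(self):
        stack = FrameStack(np.zeros((5, 10, 10), dtype=np.uint8))
        with pytest.raises(ValueError, match="margin"):
            ltp_feature(stack, RegionOfInterest(0, 0, 6, 6), 2)


class TestSegmentFeatures:
    def test_boundary_replication_minimal(self, rng):
        stack = _stack(rng, n=5)
        roi = RegionOfInterest(0, 0, 24, 20)
        vectors = ltp_features_for_segment(stack, roi)
        assert len(vectors) == 5
        interior = ltp_feature(stack, roi, 2).values
        for v in vectors:
            np.testing.assert_array_equal(v.values, interior)

    def test_counts_and_interior_range(self, rng):
        stack = _stack(rng, n=12)
        roi = RegionOfInterest(0, 0, 24, 20)
        mat = ltp_feature_matrix(stack, roi, sparse_output=False)
        assert mat.shape == (12, 16384)
        np.testing.assert_array_equal(mat[0], mat[2])
        np.testing.assert_array_equal(mat[1], mat[2])
        np.testing.assert_array_equal(mat[-1], mat[-3])
        assert not np.array_equal(mat[2], mat[3])

    def test_sparse_dense_agree(self, rng):
        stack = _stack(rng, n=6)
        roi = RegionOfInterest(0, 0, 24, 20)
        dense = ltp_feature_matrix(stack, roi, sparse_output=False)
        sp = ltp_feature_matrix(stack, roi, sparse_output=True)
        np.testing.assert_allclose(sp.toarray(), dense)

    def test_locality_of_frame_permutation(self, rng):
        """Swapping two interior frames only changes vectors within the gap."""
        stack = _stack(rng, n=14)
        roi = RegionOfInterest(0, 0, 24, 20)
        gap = 2
        a = ltp_feature_matrix(stack, roi, sparse_output=False)
        frames = stack.frames.copy()
        i, j = 6, 7
        frames[[i, j]] = frames[[j, i]]
        b = ltp_feature_matrix(FrameStack(frames), roi, sparse_output=False)
        affected = {t for t in range(14) if abs(t - i) <= gap or abs(t - j) <= gap}
        for t in range(2, 12):  # interior frames only; boundary replicas follow t=2/11
            if t not in affected:
                np.testing.assert_array_equal(a[t], b[t])
        assert any(not np.array_equal(a[t], b[t]) for t in affected)

    def test_too_short_stack(self, rng):
        stack = _stack(rng, n=4)
        with pytest.raises(ValueError, match="too short"):
            ltp_feature_matrix(stack, RegionOfInterest(0, 0, 24, 20))
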