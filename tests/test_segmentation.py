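"""Unit and property tests for the fundus preprocessing/segmentation chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from drscreen import (
    binarize,
    complement,
    equalize_histogram,
    local_average,
    overlay,
    remove_small_components,
    resize_image,
    ridler_calvard_threshold,
    segment_fundus,
    subtract_background,
    to_grayscale,
)

# ---------------------------------------------------------------------------
# resize
# ---------------------------------------------------------------------------


class TestResize:
    def test_forces_square_output(self):
        img = np.random.default_rng(0).random((70, 55, 3))
        out = resize_image(img, side=512)
        assert out.shape == (512, 512, 3)

    def test_same_size_is_pixel_identical(self):
        img = np.random.default_rng(1).random((512, 512))
        out = resize_image(img, side=512)
        np.testing.assert_array_equal(out, img)

    def test_bilinear_upscale_matches_hand_oracle(self):
        # 2x2 checkerboard -> 4x4: output coords map to input coords
        # (-0.25, 0.25, 0.75, 1.25); the half-sample symmetric boundary
        # mirrors -0.25 to 0.25, so the separable axis weights are
        # (0.75, 0.25), (0.75, 0.25), (0.25, 0.75), (0.25, 0.75).
        board = np.array([[1.0, 0.0], [0.0, 1.0]])
        w = [(0.75, 0.25), (0.75, 0.25), (0.25, 0.75), (0.25, 0.75)]
        expected = np.array(
            [[w[r][0] * w[c][0] + w[r][1] * w[c][1] for c in range(4)] for r in range(4)]
        )
        np.testing.assert_allclose(resize_image(board, side=4), expected, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resize_image(np.empty((0, 0)), side=512)


# ---------------------------------------------------------------------------
# grayscale
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rgb, expected",
    [
        ((100, 100, 100), 100 / 255),     # equal channels pass through
        ((0, 0, 0), 0.0),
        ((255, 0, 0), 0.299),             # red luma weight
        ((0, 255, 0), 0.587),
        ((0, 0, 255), 0.114),
    ],
)
def test_grayscale_bt601_weights(rgb, expected):
    img = np.full((2, 2, 3), rgb, dtype=np.uint8)
    out = to_grayscale(img)
    assert out.shape == (2, 2)
    np.testing.assert_allclose(out, expected, atol=1e-9)


def test_grayscale_rejects_non_rgb():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# histogram equalization
# ---------------------------------------------------------------------------


class TestEqualize:
    def test_uniform_histogram_maps_near_identity(self):
        img = (np.arange(256, dtype=np.uint8).reshape(16, 16))
        out = equalize_histogram(img)
        np.testing.assert_allclose(out, img / 255.0, atol=0.01)

    def test_constant_image_maps_to_one(self):
        out = equalize_histogram(np.full((8, 8), 0.4))
        np.testing.assert_array_equal(out, 1.0)

    def test_two_level_equal_counts(self):
        # equal mass at levels 10 and 200 -> CDF gives 0.5 and 1.0
        img = np.array([[10, 200]] * 4, dtype=np.uint8)
        out = equalize_histogram(img)
        np.testing.assert_allclose(out[:, 0], 0.5)
        np.testing.assert_allclose(out[:, 1], 1.0)

    @given(arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
    def test_monotone_and_mass_preserving(self, img):
        out = equalize_histogram(img)
        order = np.argsort(img.ravel(), kind="stable")
        mapped = out.ravel()[order]
        assert np.all(np.diff(mapped) >= -1e-12)
        # histogram mass is preserved at the 256-bin level granularity:
        # occupied levels map one-to-one onto output values
        levels = np.clip((img * 256).astype(np.int64), 0, 255)
        _, counts_in = np.unique(levels, return_counts=True)
        _, counts_out = np.unique(out, return_counts=True)
        assert sorted(counts_in.tolist()) == sorted(counts_out.tolist())


# ---------------------------------------------------------------------------
# mean filter and background subtraction
# ---------------------------------------------------------------------------


class TestLocalAverage:
    def test_constant_fixed_point(self):
        out = local_average(np.full((20, 20), 0.7), size=9)
        np.testing.assert_allclose(out, 0.7)

    def test_impulse_spreads_to_1_over_81(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = local_average(img, size=9)
        window = out[11:20, 11:20]
        np.testing.assert_allclose(window, 1 / 81, atol=1e-12)
        outside = out.copy()
        outside[11:20, 11:20] = 0
        np.testing.assert_allclose(outside, 0.0, atol=1e-12)

    def test_center_of_3x3_impulse(self):
        img = np.array([[0.0, 0, 0], [0, 9.0, 0], [0, 0, 0]])
        out = local_average(img, size=3)
        np.testing.assert_allclose(out[1, 1], 1.0, atol=1e-12)

    @pytest.mark.parametrize("size", [2, 4, 8])
    def test_even_size_rejected(self, size):
        with pytest.raises(ValueError):
            local_average(np.zeros((5, 5)), size=size)


class TestSubtract:
    def test_self_subtraction_is_zero(self):
        img = np.full((5, 5), 0.3)
        np.testing.assert_array_equal(subtract_background(img, img), 0.0)

    def test_negative_clipped_and_positive_kept(self):
        eq = np.array([[0.3, 0.9]])
        avg = np.array([[0.8, 0.4]])
        np.testing.assert_allclose(subtract_background(eq, avg), [[0.0, 0.5]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((3, 3)), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# Ridler-Calvard threshold
# ---------------------------------------------------------------------------


class TestRidlerCalvard:
    def test_balanced_binary_image(self):
        img = np.array([0.0] * 8 + [1.0] * 8).reshape(4, 4)
        assert ridler_calvard_threshold(img) == pytest.approx(0.5, abs=1e-4)

    def test_three_low_one_high(self):
        img = np.array([[0.2, 0.2], [0.2, 0.8]])
        assert ridler_calvard_threshold(img) == pytest.approx(0.5, abs=1e-4)

    def test_constant_image_degenerate(self):
        assert ridler_calvard_threshold(np.full((3, 3), 0.4)) == pytest.approx(0.4)

    def test_agrees_with_histogram_isodata(self):
        # independent oracle: skimage's histogram-based ISODATA threshold
        from skimage.filters import threshold_isodata

        rng = np.random.default_rng(0)
        img = np.concatenate(
            [rng.normal(0.3, 0.05, 3000), rng.normal(0.7, 0.05, 3000)]
        ).clip(0, 1).reshape(60, 100)
        mine = ridler_calvard_threshold(img)
        ref = threshold_isodata((img * 255).astype(np.uint8)) / 255.0
        assert mine == pytest.approx(ref, abs=0.01)

    @given(arrays(np.float64, (8, 8), elements=st.floats(0, 1, width=32)))
    def test_fixed_point_and_interior(self, img):
        t = ridler_calvard_threshold(img)
        lo, hi = img.min(), img.max()
        if hi - lo == 0:
            assert t == pytest.approx(lo)
            return
        assert lo < t <= hi
        fg, bg = img[img >= t], img[img < t]
        assert abs(t - (fg.mean() + bg.mean()) / 2) < 1e-3


# ---------------------------------------------------------------------------
# binarize / cleanup / complement / overlay
# ---------------------------------------------------------------------------


class TestBinaryOps:
    def test_binarize_inclusive_at_threshold(self):
        img = np.array([[0.49, 0.5, 0.51]])
        np.testing.assert_array_equal(binarize(img, 0.5), [[0, 1, 1]])

    def test_binarize_extremes(self):
        img = np.random.default_rng(2).random((6, 6))
        assert binarize(img, 0.0).all()
        assert not binarize(img, img.max() + 1e-9).any()

    def test_cluster_of_50_removed_51_kept(self):
        mask50 = np.zeros((20, 20), dtype=np.uint8)
        mask50[:5, :10] = 1                      # exactly 50 pixels
        assert remove_small_components(mask50, max_discard=50).sum() == 0
        mask51 = mask50.copy()
        mask51[5, 0] = 1                         # 51 pixels, 8-connected
        np.testing.assert_array_equal(remove_small_components(mask51, 50), mask51)

    def test_empty_mask_unchanged(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        np.testing.assert_array_equal(remove_small_components(mask), mask)

    def test_diagonal_touch_counts_as_connected(self):
        # two 26-pixel blobs joined only diagonally survive as one 52-px
        # component under 8-connectivity
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[0:2, 0:13] = 1
        mask[2:4, 13:26] = 1
        assert remove_small_components(mask, 50).sum() == 52

    @given(arrays(np.uint8, (7, 7), elements=st.integers(0, 1)))
    def test_complement_involution(self, mask):
        np.testing.assert_array_equal(complement(complement(mask)), mask)

    def test_complement_extremes(self):
        assert not complement(np.ones((3, 3), dtype=np.uint8)).any()
        assert complement(np.zeros((3, 3), dtype=np.uint8)).all()

    def test_overlay_support_equals_mask(self):
        rng = np.random.default_rng(3)
        gray = rng.random((16, 16)) + 0.01
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        out = overlay(mask, gray)
        np.testing.assert_array_equal(out != 0, mask.astype(bool))
        np.testing.assert_array_equal(out[mask == 1], gray[mask == 1])

    def test_overlay_identity_and_zero_masks(self):
        gray = np.random.default_rng(4).random((8, 8))
        np.testing.assert_array_equal(overlay(np.ones((8, 8), np.uint8), gray), gray)
        assert not overlay(np.zeros((8, 8), np.uint8), gray).any()


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


class TestSegmentFundus:
    def test_constant_image_gives_empty_mask(self):
        img = np.full((64, 64, 3), 0.5)
        res = segment_fundus(img, side=64)
        assert res.degenerate
        assert not res.mask.any()
        assert not res.segmented.any()

    def test_deterministic(self, phantom_pair):
        img = phantom_pair["dr"][0]
        a = segment_fundus(img)
        b = segment_fundus(img)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.segmented, b.segmented)
        assert a.threshold == b.threshold

    def test_result_invariants(self, segmented_pair):
        for res in segmented_pair.values():
            # segmented is zero off the mask
            assert not res.segmented[res.mask == 0].any()
            assert 0 <= res.threshold <= 1
            # every surviving 8-connected component exceeds 50 pixels
            labels, n = ndimage.label(res.mask, structure=np.ones((3, 3)))
            sizes = np.bincount(labels.ravel())[1:]
            assert n == 0 or sizes.min() > 50

    def test_vessel_skeleton_recall(self, phantom_pair, segmented_pair):
        # the mask (dilated 2 px) must cover >= 80% of the true centrelines
        for label in ("dr", "healthy"):
            truth = phantom_pair[label][1]
            mask = segmented_pair[label].mask.astype(bool)
            near = ndimage.binary_dilation(mask, iterations=2)
            skel = truth.vessel_skeleton
            recall = (near & skel).sum() / skel.sum()
            assert recall >= 0.8

    def test_invariants_on_random_phantoms(self):
        from drscreen import PhantomConfig, generate_fundus

        cfg = PhantomConfig(size=256)
        for seed in range(8):
            img, _ = generate_fundus(cfg, "dr" if seed % 2 else "healthy", seed=700 + seed)
            res = segment_fundus(img, side=256)
            assert not res.segmented[res.mask == 0].any()
            labels, n = ndimage.label(res.mask, structure=np.ones((3, 3)))
            sizes = np.bincount(labels.ravel())[1:]
            assert n == 0 or sizes.min() > 50
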