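import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from tonguecrack import (
    binarize_and_upsample,
    erode3x3,
    postprocess_pipeline,
    thin_to_skeleton,
)


def brute_force_erode(mask):
    """Definition-level oracle: output 1 iff the full 3x3 neighbourhood is
    1, out-of-image neighbours counting as 0."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        ok = False
            out[r, c] = 1 if ok else 0
    return out


def random_masks(n, shape=(16, 16), p=0.5, seed=0):
    rng = np.random.default_rng(seed)
    return [(rng.random(shape) < p).astype(np.uint8) for _ in range(n)]


class TestBinarizeUpsample:
    def test_all_negative_logits_give_empty_mask(self):
        out = binarize_and_upsample(np.full((4, 4), -50.0))
        assert out.shape == (32, 32) and out.sum() == 0

    def test_single_cell_becomes_8x8_block(self):
        logits = np.full((6, 6), -10.0)
        logits[2, 4] = 10.0
        out = binarize_and_upsample(logits)
        assert out.sum() == 64
        assert out[16:24, 32:40].all()

    def test_zero_logit_is_negative_at_half_threshold(self):
        out = binarize_and_upsample(np.zeros((2, 2)))
        assert out.sum() == 0  # sigmoid(0) = 0.5, strict >

    def test_bad_threshold_or_size_rejected(self):
        with pytest.raises(ValueError):
            binarize_and_upsample(np.zeros((2, 2)), threshold=0.0)
        with pytest.raises(ValueError, match="out_size"):
            binarize_and_upsample(np.zeros((2, 2)), out_size=(17, 16))


class TestErode:
    def test_isolated_pixel_vanishes(self):
        mask = np.zeros((9, 9), np.uint8)
        mask[4, 4] = 1
        assert erode3x3(mask).sum() == 0

    def test_solid_square_shrinks_by_one_ring(self):
        mask = np.zeros((9, 9), np.uint8)
        mask[2:7, 2:7] = 1  # 5x5
        out = erode3x3(mask)
        expected = np.zeros_like(mask)
        expected[3:6, 3:6] = 1  # 3x3
        assert np.array_equal(out, expected)

    def test_empty_stays_empty(self):
        assert erode3x3(np.zeros((5, 5), np.uint8)).sum() == 0

    def test_matches_brute_force_on_random_masks(self):
        for mask in random_masks(100, seed=7, p=0.7):
            assert np.array_equal(erode3x3(mask), brute_force_erode(mask))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_anti_extensive(self, seed):
        mask = random_masks(1, shape=(12, 12), p=0.6, seed=seed)[0]
        out = erode3x3(mask)
        assert not np.any(out & ~mask)


class TestThin:
    def test_wide_bar_becomes_single_pixel_line(self):
        mask = np.zeros((10, 26), np.uint8)
        mask[4:7, 3:23] = 1  # 3 pixels wide, 20 long
        skel = thin_to_skeleton(mask)
        assert not np.any(skel & ~mask)
        # one pixel per column over the bar's interior, one component
        cols = skel[:, 4:22].sum(axis=0)
        assert (cols <= 1).all() and cols.sum() >= 15
        assert ndimage.label(skel, structure=np.ones((3, 3)))[1] == 1

    def test_thin_diagonal_is_fixed_point(self):
        mask = np.eye(9, dtype=np.uint8)
        assert np.array_equal(thin_to_skeleton(mask), mask)

    def test_empty_stays_empty(self):
        assert thin_to_skeleton(np.zeros((6, 6), np.uint8)).sum() == 0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_and_subset(self, seed):
        mask = random_masks(1, shape=(16, 16), p=0.6, seed=seed)[0]
        skel = thin_to_skeleton(mask)
        assert not np.any(skel & ~mask)
        assert np.array_equal(thin_to_skeleton(skel), skel)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_no_2x2_block_on_crack_like_masks(self, seed):
        """Thinness holds on the mask family the pipeline produces
        (upsampled cell blocks and crack strips).  It is not universal:
        around holes and at rare branch junctions no connectivity-
        preserving thinning can delete every 2x2 block."""
        rng = np.random.default_rng(seed)
        logits = rng.normal(loc=-1.5, scale=2.0, size=(8, 8))
        _, skel = postprocess_pipeline(logits)
        assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()

    def test_preserves_component_count(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mask = ndimage.binary_dilation(rng.random((24, 24)) < 0.05).astype(np.uint8)
            skel = thin_to_skeleton(mask)
            s8 = np.ones((3, 3))
            assert ndimage.label(skel, s8)[1] == ndimage.label(mask, s8)[1]


class TestPipeline:
    def test_empty_logits_give_empty_outputs(self):
        mask, skel = postprocess_pipeline(np.full((5, 5), -30.0))
        assert mask.sum() == 0 and skel.sum() == 0

    def test_skeleton_subset_of_mask_on_random_logits(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            logits = rng.normal(scale=3.0, size=(8, 8))
            mask, skel = postprocess_pipeline(logits)
            assert not np.any(skel & ~mask)

    def test_50x50_logits_give_400x400_outputs(self):
        mask, skel = postprocess_pipeline(np.zeros((50, 50)), out_size=(400, 400))
        assert mask.shape == (400, 400) and skel.shape == (400, 400)
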