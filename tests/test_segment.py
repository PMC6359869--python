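"""Blur, bandpass, Otsu and skeletonization contracts."""

import numpy as np
import pytest
from scipy.ndimage import label

from microvasq import (
    CalibratedImage,
    SegmentationError,
    fft_bandpass,
    gaussian_blur,
    otsu_threshold,
    segment_image,
    skeletonize,
)
from microvasq.segment import _bandpass_raw, _bandpass_transfer

from conftest import bruteforce_otsu, random_blob_mask


def _img(px, fov=(1.0, 1.0)):
    return CalibratedImage(np.asarray(px, dtype=np.float64), fov_mm=fov)


def _u8(px, fov=(1.0, 1.0)):
    return CalibratedImage(np.asarray(px, dtype=np.uint8), fov_mm=fov)


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        out = gaussian_blur(_img(np.full((32, 32), 7.0)), 4.0)
        assert np.allclose(out.pixels, 7.0, atol=1e-10)

    def test_impulse_center_matches_kernel_formula(self):
        px = np.zeros((65, 65))
        px[32, 32] = 1.0
        out = gaussian_blur(_img(px), 4.0)
        assert out.pixels[32, 32] == pytest.approx(1.0 / (2 * np.pi * 16), abs=1e-4)

    def test_total_intensity_conserved_for_interior_content(self, rng):
        px = np.zeros((128, 128))
        px[40:90, 40:90] = rng.random((50, 50))
        out = gaussian_blur(_img(px), 4.0)
        assert out.pixels.sum() == pytest.approx(px.sum(), rel=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(SegmentationError):
            gaussian_blur(_img(np.zeros((8, 8))), 0.0)


class TestFftBandpass:
    def test_constant_image_maps_to_flat_mid_level(self):
        out = fft_bandpass(_img(np.full((64, 64), 90.0)), 40, 3)
        assert np.allclose(out.pixels, 128.0)

    @pytest.mark.parametrize(
        "period, lo, hi",
        [(12, 0.7, 1.0), (200, 0.0, 0.2)],
        ids=["in_band_retained", "out_of_band_suppressed"],
    )
    def test_sinusoid_gain(self, period, lo, hi):
        """In-band waves pass (>0.7); structures larger than the band are
        suppressed (<0.2).  Gain measured by projection onto the input."""
        h, w = 120, 600
        sig = np.sin(2 * np.pi * np.arange(w) / period)
        img = np.tile(128 + 100 * sig, (h, 1))
        out = _bandpass_raw(img, 40, 3)
        gain = (out * np.tile(sig, (h, 1))).sum() / (100 * (sig**2).sum() * h)
        assert lo < gain < hi

    def test_padding_is_transparent_mirror(self, rng):
        """Filtering a mirror-pretiled input gives the same interior result
        as letting the filter pad internally."""
        px = rng.random((96, 96)) * 255
        internal = _bandpass_raw(px, 40, 3)
        pretiled = np.pad(px, ((0, 128 - 96), (0, 128 - 96)), mode="reflect")
        manual = np.fft.ifft2(
            np.fft.fft2(pretiled) * _bandpass_transfer((128, 128), 40, 3)
        ).real[:96, :96]
        assert np.allclose(internal, manual, atol=1e-3)

    def test_invalid_band_rejected(self):
        with pytest.raises(SegmentationError):
            fft_bandpass(_img(np.zeros((16, 16))), 3, 40)


class TestOtsu:
    def test_two_level_image(self):
        px = np.full((16, 16), 240, np.uint8)
        px[:8] = 10
        level, mask = otsu_threshold(_u8(px))
        assert level == bruteforce_otsu(px) == 10
        assert mask.sum() == 128 and (mask[8:]).all()

    def test_bimodal_mixture_separates_classes(self, rng):
        vals = np.concatenate(
            [rng.normal(60, 10, 5000), rng.normal(190, 10, 5000)]
        )
        px = np.clip(vals, 0, 255).astype(np.uint8).reshape(100, 100)
        level, mask = otsu_threshold(_u8(px))
        assert level == bruteforce_otsu(px)
        # the threshold cleanly separates the two components
        assert 60 < level < 190
        assert mask.mean() == pytest.approx(0.5, abs=0.02)

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError, match="degenerate histogram"):
            otsu_threshold(_u8(np.full((8, 8), 3)))

    def test_agrees_with_bruteforce_on_random_histograms(self, rng):
        for _ in range(50):
            n_levels = int(rng.integers(2, 30))
            levels = rng.choice(256, size=n_levels, replace=False)
            weights = rng.integers(1, 50, size=n_levels)
            px = np.repeat(levels, weights).astype(np.uint8)
            px = np.resize(px, 1024).reshape(32, 32)
            level, _ = otsu_threshold(_u8(px))
            assert level == bruteforce_otsu(px)

    def test_agrees_with_skimage_up_to_convention(self, rng):
        """Independent library cross-check: thresholds within one bin."""
        from skimage.filters import threshold_otsu

        px = (rng.beta(2, 3, (64, 64)) * 255).astype(np.uint8)
        level, _ = otsu_threshold(_u8(px))
        assert abs(level - threshold_otsu(px)) <= 1


class TestSkeletonize:
    def test_empty_mask_empty_skeleton(self):
        assert not skeletonize(np.zeros((16, 16), bool)).any()

    def test_solid_bar_thins_to_middle_row_centerline(self):
        m = np.zeros((9, 104), bool)
        m[2:7, 2:102] = True  # 5 x 100 bar
        s = skeletonize(m)
        rows = np.unique(np.where(s)[0])
        assert list(rows) == [4]  # the bar's middle row
        assert abs(int(s.sum()) - 98) <= 2

    def test_single_pixel_preserved(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert skeletonize(m)[2, 2]

    def test_thinness_and_component_count_on_random_blobs(self, rng):
        eight = np.ones((3, 3))
        for _ in range(20):
            m = random_blob_mask(rng)
            s = skeletonize(m)
            assert (s <= m).all()
            no22 = ~(s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()
            assert no22
            _, n_in = label(m, structure=eight)
            _, n_out = label(s, structure=eight)
            assert n_in == n_out


class TestChainDeterminism:
    def test_identical_input_identical_skeleton(self, rng):
        px = (rng.random((128, 128)) * 255).astype(np.uint8)
        px[40:60, :] = 250  # guarantee segmentable structure
        a = segment_image(_u8(px))
        b = segment_image(_u8(px))
        assert np.array_equal(a.skeleton, b.skeleton)
        assert a.threshold_level == b.threshold_level

    def test_skeleton_subset_of_binary(self, rng):
        px = (rng.random((128, 128)) * 255).astype(np.uint8)
        px[40:60, :] = 250
        res = segment_image(_u8(px))
        assert (res.skeleton <= res.binary).all()
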