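"""Calibrated-image I/O, FOV bookkeeping, registration and overlays."""

import numpy as np
import pytest

from microvasq import (
    CalibratedImage,
    CalibrationError,
    GeometryError,
    center_crop,
    overlay_skeletons,
    read_image,
    register_translation,
    resize,
    resize_to_width,
    write_image,
)
from microvasq.geometry import _shift_mask


class TestReadWrite:
    def test_uint8_roundtrip_is_lossless(self, tmp_path, rng):
        px = rng.integers(0, 256, size=(40, 50), dtype=np.uint8)
        img = CalibratedImage(px, fov_mm=(2.0, 1.6), modality="octa_like")
        path = str(tmp_path / "img.png")
        write_image(img, path)
        back = read_image(path)
        assert np.array_equal(back.pixels, px)
        assert back.fov_mm == (2.0, 1.6)
        assert back.modality == "octa_like"

    def test_rgb_roundtrip_keeps_channels_and_tag(self, tmp_path, rng):
        px = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        img = CalibratedImage(px, fov_mm=(1.0, 1.0), modality="fslb_like")
        path = str(tmp_path / "img.bmp")
        write_image(img, path)
        back = read_image(path)
        assert back.pixels.shape == (16, 16, 3)
        assert back.modality == "fslb_like"

    def test_missing_fov_is_an_error(self, tmp_path):
        import imageio.v3 as iio

        path = str(tmp_path / "nofov.png")
        iio.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(CalibrationError, match="FOV required"):
            read_image(path)

    def test_missing_file_and_bad_format_have_distinct_messages(self, tmp_path):
        with pytest.raises(CalibrationError, match="no such image"):
            read_image(str(tmp_path / "absent.png"))
        bad = tmp_path / "x.jpg"
        bad.write_bytes(b"")
        with pytest.raises(CalibrationError, match="unsupported image format"):
            read_image(str(bad), fov_mm=(1, 1))


class TestResizeCrop:
    def test_upsample_keeps_fov(self):
        img = CalibratedImage(np.zeros((304, 304), np.uint8), fov_mm=(8.775, 8.775))
        out = resize(img, 1024, 1024)
        assert (out.width_px, out.height_px) == (1024, 1024)
        assert out.fov_mm == (8.775, 8.775)

    def test_aspect_preserving_resize_gives_expected_height(self):
        img = CalibratedImage(np.zeros((3456, 5184), np.uint8), fov_mm=(15.74, 10.50))
        out = resize_to_width(img, 1024)
        assert (out.width_px, out.height_px) == (1024, 683)

    def test_resize_to_same_dims_is_identity(self, gradient_image):
        out = resize(gradient_image, 96, 96)
        assert np.array_equal(out.pixels, gradient_image.pixels)

    def test_resize_rejects_nonpositive_dims(self, gradient_image):
        with pytest.raises(GeometryError):
            resize(gradient_image, 0, 10)

    def test_crop_shrinks_fov_proportionally(self):
        img = CalibratedImage(np.zeros((1024, 1024), np.uint8), fov_mm=(8.775, 8.775))
        out = center_crop(img, 768, 768)
        assert out.fov_mm_rounded == (6.581, 6.581)
        assert out.fov_mm[0] == pytest.approx(8.775 * 768 / 1024, abs=1e-12)

    def test_crop_full_size_is_identity(self, gradient_image):
        out = center_crop(gradient_image, 96, 96)
        assert np.array_equal(out.pixels, gradient_image.pixels)
        assert out.fov_mm == gradient_image.fov_mm

    def test_crop_larger_than_image_is_an_error(self, gradient_image):
        with pytest.raises(GeometryError):
            center_crop(gradient_image, 768, 768)

    def test_crop_offset_selects_window(self, gradient_image):
        out = center_crop(gradient_image, 10, 10, offset=(0, 0))
        assert np.array_equal(out.pixels, gradient_image.pixels[:10, :10])

    def test_mm_per_px_consistent_after_resize_and_crop(self):
        img = CalibratedImage(np.zeros((304, 304), np.uint8), fov_mm=(8.775, 8.775))
        out = center_crop(resize(img, 1024, 1024), 768, 768)
        assert out.mm_per_px[0] == pytest.approx(8.775 / 1024, rel=1e-12)

    def test_crop_and_resize_commute_on_fov(self):
        img = CalibratedImage(np.zeros((100, 100), np.uint8), fov_mm=(10.0, 10.0))
        a = center_crop(resize(img, 200, 200), 100, 100)
        b = resize(center_crop(img, 50, 50), 100, 100)
        assert a.fov_mm[0] == pytest.approx(b.fov_mm[0], abs=1e-9)
        assert a.fov_mm[1] == pytest.approx(b.fov_mm[1], abs=1e-9)


class TestRegistration:
    def _mask(self, rng, shape=(64, 64)):
        m = np.zeros(shape, bool)
        m[rng.integers(5, shape[0] - 5, 40), rng.integers(5, shape[1] - 5, 40)] = True
        return m

    def test_identity_registration(self, rng):
        m = self._mask(rng)
        t = register_translation(m, m, 5)
        assert (t.dx_px, t.dy_px) == (0, 0)

    def test_known_shift_recovered(self, rng):
        m = self._mask(rng)
        moving = _shift_mask(m, -3, 5)  # shifted by (dx,dy) = (+5,-3)
        t = register_translation(m, moving, 10)
        assert (t.dx_px, t.dy_px) == (-5, 3)

    def test_empty_mask_rejected(self, rng):
        m = self._mask(rng)
        with pytest.raises(GeometryError, match="empty mask"):
            register_translation(m, np.zeros_like(m), 5)

    def test_agrees_with_bruteforce_oracle(self, rng):
        """Exhaustive double-loop NCC oracle on small random masks."""
        for _ in range(5):
            ref = self._mask(rng)
            moving = _shift_mask(ref, int(rng.integers(-4, 5)), int(rng.integers(-4, 5)))
            if not moving.any():
                continue
            t = register_translation(ref, moving, 6)
            best_score, best = -1.0, None
            ref_f = ref.astype(float)
            for dy in range(-6, 7):
                for dx in range(-6, 7):
                    s = _shift_mask(moving, dy, dx).astype(float)
                    denom = np.sqrt((ref_f**2).sum() * (s**2).sum())
                    score = (ref_f * s).sum() / denom if denom > 0 else 0.0
                    key = (abs(dx) + abs(dy), dy, dx)
                    if score > best_score + 1e-12 or (
                        abs(score - best_score) <= 1e-12 and best is not None and key < best
                    ):
                        best_score, best = score, key
            assert (t.dx_px, t.dy_px) == (best[2], best[1])


class TestOverlay:
    def test_identical_masks_all_yellow(self, rng):
        m = np.zeros((32, 32), bool)
        m[5:20, 7] = True
        rgb = overlay_skeletons(m, m, tolerance_px=0)
        assert np.array_equal(rgb[m], np.tile([255, 255, 0], (m.sum(), 1)))
        assert (rgb[~m] == 0).all()

    def test_disjoint_masks_pure_red_green(self):
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[5, 5:10] = True
        b[20, 5:10] = True
        rgb = overlay_skeletons(a, b, tolerance_px=0)
        assert np.array_equal(rgb[a], np.tile([255, 0, 0], (5, 1)))
        assert np.array_equal(rgb[b], np.tile([0, 255, 0], (5, 1)))

    def test_one_pixel_shift_mostly_yellow_at_tolerance_one(self, rng):
        a = np.zeros((64, 64), bool)
        a[10:50, 10:50:4] = True
        b = _shift_mask(a, 0, 1)
        rgb = overlay_skeletons(a, b, tolerance_px=1)
        yellow_a = (rgb[a] == [255, 255, 0]).all(axis=1).mean()
        assert yellow_a >= 0.9

    def test_dim_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            overlay_skeletons(np.zeros((4, 4), bool), np.zeros((5, 5), bool), 0)
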