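"""Calibrated raster images and the geometry bookkeeping between modalities.

Every image in the pipeline carries its physical field of view (FOV) in mm.
The unit cost of each geometric operation is therefore explicit: resizing
changes sampling but not physical extent; cropping shrinks the FOV in
proportion to the retained pixels.  Conventions: 0-based (row, col) pixel
indices, origin at the top-left, x rightward, y downward; pixel centers sit
at (i + 0.5, j + 0.5) * (mm/px); crop windows are half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import imageio.v3 as iio
import yaml
from skimage.morphology import dilation, disk
from skimage.transform import resize as _sk_resize

from .errors import CalibrationError, GeometryError

_SUPPORTED_EXT = {".png", ".bmp", ".tif", ".tiff"}


@dataclass
class CalibratedImage:
    """A 2-D intensity grid plus its physical field of view.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB.  Either 8-bit integers
        in 0..255 or floats in [0, 1].
    fov_mm : (float, float)
        Physical extent as ``(width_mm, height_mm)``.
    modality : str
        Free-form tag, e.g. ``"octa_like"`` or ``"fslb_like"``.
    """

    pixels: np.ndarray
    fov_mm: Tuple[float, float]
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise CalibrationError("pixels must be 2-D grayscale or 3-D RGB")
        w, h = float(self.fov_mm[0]), float(self.fov_mm[1])
        if not (np.isfinite(w) and np.isfinite(h) and w > 0 and h > 0):
            raise CalibrationError(f"fov_mm must be positive and finite, got {self.fov_mm}")
        self.fov_mm = (w, h)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def mm_per_px(self) -> Tuple[float, float]:
        """(x, y) sampling pitch in mm/pixel."""
        return (self.fov_mm[0] / self.width_px, self.fov_mm[1] / self.height_px)

    @property
    def fov_mm_rounded(self) -> Tuple[float, float]:
        """FOV rounded to 3 decimals, the reporting convention for tables."""
        return (round(self.fov_mm[0], 3), round(self.fov_mm[1], 3))

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


def _sidecar_path(path: str) -> str:
    return str(path) + ".yaml"


def read_image(
    path: str,
    fov_mm: Optional[Tuple[float, float]] = None,
    modality: Optional[str] = None,
) -> CalibratedImage:
    """Read a PNG/BMP/TIFF raster and attach its FOV.

    The FOV comes either from the ``fov_mm`` argument or from a YAML
    sidecar ``<path>.yaml`` written by :func:`write_image`; an image
    without any physical calibration is rejected.
    """
    path = str(path)
    if not os.path.exists(path):
        raise CalibrationError(f"no such image file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise CalibrationError(f"unsupported image format '{ext}' (use PNG, BMP or TIFF)")
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    meta = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    if fov_mm is None:
        if "fov_mm" not in meta:
            raise CalibrationError("FOV required: pass fov_mm or provide a sidecar with fov_mm")
        fov_mm = tuple(float(v) for v in meta["fov_mm"])
    if modality is None:
        modality = meta.get("modality", "unknown")
    return CalibratedImage(pixels=pixels, fov_mm=fov_mm, modality=modality)


def write_image(img: CalibratedImage, path: str) -> None:
    """Write 8-bit PNG/BMP/TIFF plus a YAML sidecar with FOV and modality.

    Float images in [0, 1] are quantized to 8 bits; integer images are
    written losslessly, so write-then-read round-trips 8-bit data exactly.
    """
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise CalibrationError(f"unsupported image format '{ext}' (use PNG, BMP or TIFF)")
    px = img.pixels
    if np.issubdtype(px.dtype, np.floating):
        px = np.clip(np.rint(px * 255.0), 0, 255).astype(np.uint8)
    else:
        px = px.astype(np.uint8)
    iio.imwrite(path, px)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {"fov_mm": [float(img.fov_mm[0]), float(img.fov_mm[1])], "modality": img.modality},
            fh,
        )


def resize(img: CalibratedImage, new_w_px: int, new_h_px: int) -> CalibratedImage:
    """Bilinear resample to ``new_w_px`` x ``new_h_px``; the FOV is unchanged.

    Down-sampling applies the standard Gaussian anti-alias prefilter.
    Resizing changes the sampling grid, not the physical extent.
    """
    if new_w_px <= 0 or new_h_px <= 0:
        raise GeometryError(f"resize target must be positive, got {new_w_px}x{new_h_px}")
    if (new_w_px, new_h_px) == (img.width_px, img.height_px):
        return replace(img, pixels=img.pixels.copy())
    shape = (new_h_px, new_w_px) + img.pixels.shape[2:]
    downscale = new_w_px < img.width_px or new_h_px < img.height_px
    out = _sk_resize(
        img.pixels.astype(np.float64),
        shape,
        order=1,
        mode="reflect",
        anti_aliasing=downscale,
        preserve_range=True,
    )
    if np.issubdtype(img.pixels.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(img.pixels.dtype)
    else:
        out = out.astype(img.pixels.dtype)
    return replace(img, pixels=out)


def resize_to_width(img: CalibratedImage, new_w_px: int) -> CalibratedImage:
    """Resize to a target width, preserving aspect ratio (height rounded)."""
    new_h = int(round(img.height_px * new_w_px / img.width_px))
    return resize(img, new_w_px, new_h)


def center_crop(
    img: CalibratedImage,
    crop_w_px: int,
    crop_h_px: int,
    offset: Optional[Tuple[int, int]] = None,
) -> CalibratedImage:
    """Crop a window; the FOV shrinks by the retained pixel fraction.

    ``offset`` is the (row, col) of the window's top-left corner; by
    default the window is centered.  New FOV per axis is
    ``old_fov * crop_px / old_px`` (exact; round with
    :attr:`CalibratedImage.fov_mm_rounded` for reporting).
    """
    if crop_w_px <= 0 or crop_h_px <= 0:
        raise GeometryError("crop dims must be positive")
    if crop_w_px > img.width_px or crop_h_px > img.height_px:
        raise GeometryError(
            f"crop {crop_w_px}x{crop_h_px} exceeds image {img.width_px}x{img.height_px}"
        )
    if offset is None:
        r0 = (img.height_px - crop_h_px) // 2
        c0 = (img.width_px - crop_w_px) // 2
    else:
        r0, c0 = int(offset[0]), int(offset[1])
    if r0 < 0 or c0 < 0 or r0 + crop_h_px > img.height_px or c0 + crop_w_px > img.width_px:
        raise GeometryError("crop window falls outside the image")
    new_fov = (
        img.fov_mm[0] * crop_w_px / img.width_px,
        img.fov_mm[1] * crop_h_px / img.height_px,
    )
    out = img.pixels[r0 : r0 + crop_h_px, c0 : c0 + crop_w_px].copy()
    return CalibratedImage(pixels=out, fov_mm=new_fov, modality=img.modality)


@dataclass
class RegistrationTransform:
    """Integer translation aligning a moving mask into a reference frame.

    Applying ``(dx_px, dy_px)`` to the moving mask (x rightward, y
    downward) maximizes normalized cross-correlation with the reference.
    """

    dx_px: int
    dy_px: int
    score: float


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate with zero fill (no wrap-around)."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def register_translation(
    reference: np.ndarray, moving: np.ndarray, search_px: int
) -> RegistrationTransform:
    """Exhaustive integer-translation registration of two binary masks.

    Scans all shifts within ``±search_px`` and returns the one maximizing
    normalized cross-correlation, breaking ties by smallest |dx|+|dy|,
    then smallest dy, then smallest dx.
    """
    reference = np.asarray(reference, dtype=bool)
    moving = np.asarray(moving, dtype=bool)
    if reference.shape != moving.shape:
        raise GeometryError("masks must share dims for registration")
    if search_px < 0:
        raise GeometryError("search_px must be >= 0")
    if not reference.any() or not moving.any():
        raise GeometryError("cannot register empty mask")
    ref = reference.astype(np.float64)
    ref_norm = float(np.sqrt((ref**2).sum()))
    offsets = [
        (dx, dy)
        for dy in range(-search_px, search_px + 1)
        for dx in range(-search_px, search_px + 1)
    ]
    offsets.sort(key=lambda o: (abs(o[0]) + abs(o[1]), o[1], o[0]))
    best: Optional[RegistrationTransform] = None
    for dx, dy in offsets:
        shifted = _shift_mask(moving, dy, dx).astype(np.float64)
        denom = ref_norm * np.sqrt((shifted**2).sum())
        score = float((ref * shifted).sum() / denom) if denom > 0 else 0.0
        if best is None or score > best.score + 1e-12:
            best = RegistrationTransform(dx_px=dx, dy_px=dy, score=score)
    assert best is not None
    return best


def apply_translation(mask: np.ndarray, transform: RegistrationTransform) -> np.ndarray:
    """Shift a mask by a registration result (zero fill at borders)."""
    return _shift_mask(np.asarray(mask, dtype=bool), transform.dy_px, transform.dx_px)


def overlay_skeletons(
    a: np.ndarray, b: np.ndarray, tolerance_px: int = 0
) -> np.ndarray:
    """Tri-color agreement overlay of two skeletons.

    Yellow marks vessels found by both (each mask's pixels within
    ``tolerance_px`` of the other), red vessels only in ``a``, green only
    in ``b``; background stays black.  Returns ``(H, W, 3)`` uint8.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("masks must share dims for overlay")
    if tolerance_px > 0:
        se = disk(int(tolerance_px))
        a_zone = dilation(a, se)
        b_zone = dilation(b, se)
    else:
        a_zone, b_zone = a, b
    yellow = (a & b_zone) | (b & a_zone)
    red = a & ~yellow
    green = b & ~yellow
    rgb = np.zeros(a.shape + (3,), dtype=np.uint8)
    rgb[yellow] = (255, 255, 0)
    rgb[red] = (255, 0, 0)
    rgb[green] = (0, 255, 0)
    return rgb


def resize_mask(mask: np.ndarray, new_w_px: int, new_h_px: int) -> np.ndarray:
    """Nearest-neighbor mask resize, preserving binarity."""
    if new_w_px <= 0 or new_h_px <= 0:
        raise GeometryError("resize target must be positive")
    out = _sk_resize(
        np.asarray(mask, dtype=bool).astype(np.float64),
        (new_h_px, new_w_px),
        order=0,
        mode="constant",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out > 0.5
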