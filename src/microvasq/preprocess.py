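"""Photograph-side cleanup preceding the shared segmentation chain.

Slit-lamp photographs show dark vessels on a bright, vignetted
conjunctiva; angiograms show bright vessels on a dark background.  The
steps here — grayscale conversion, histogram equalization (global or
contrast-limited adaptive), and black-top-hat background removal —
normalize the photograph to the "vessels bright on flat background"
polarity the downstream Otsu stage expects.

All operations preserve image dimensions and the physical FOV.
Intensities are handled on the 8-bit 0..255 scale internally; float
inputs in [0, 1] are quantized on entry and returned as uint8.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.morphology import disk, white_tophat

from .errors import PreprocessError
from .geometry import CalibratedImage

logger = logging.getLogger(__name__)

#: Rec.601 luma weights for the "luminance" grayscale method.
_REC601 = np.array([0.299, 0.587, 0.114])


def as_uint8(pixels: np.ndarray) -> np.ndarray:
    """Quantize float data to 0..255; pass integer data through.

    Floats with max <= 1 are treated as normalized [0, 1]; larger floats
    are assumed to already be on the 0..255 scale and are only rounded
    and clipped.
    """
    if np.issubdtype(pixels.dtype, np.floating):
        arr = pixels
        if arr.size and float(np.nanmax(arr)) <= 1.0:
            arr = arr * 255.0
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return pixels.astype(np.uint8)


def to_grayscale(img: CalibratedImage, method: str = "green") -> CalibratedImage:
    """Collapse RGB to one channel.

    ``method="green"`` extracts the green channel (matching a slit lamp's
    built-in green filter, which maximizes hemoglobin contrast);
    ``method="luminance"`` applies Rec.601 weights.  Grayscale input is
    returned unchanged with a logged note.
    """
    if not img.is_rgb:
        logger.info("to_grayscale: input already grayscale; returned unchanged")
        return replace(img, pixels=img.pixels.copy())
    px = as_uint8(img.pixels)
    if method == "green":
        gray = px[:, :, 1]
    elif method == "luminance":
        gray = np.clip(np.rint(px.astype(np.float64) @ _REC601), 0, 255).astype(np.uint8)
    else:
        raise PreprocessError(f"unknown grayscale method {method!r}")
    return replace(img, pixels=gray)


def _require_gray(img: CalibratedImage, op: str) -> np.ndarray:
    if img.is_rgb:
        raise PreprocessError(f"{op} requires a grayscale image")
    return as_uint8(img.pixels)


def equalize_global(img: CalibratedImage) -> CalibratedImage:
    """Classic 256-bin histogram equalization.

    Maps level v to ``round(255 * (cdf(v) - cdf(0)) / (1 - cdf(0)))``,
    anchoring gray level 0 at 0 so an image whose histogram is already
    uniform over 0..255 is an exact fixed point.  A constant image is
    returned unchanged (its histogram carries no contrast to spread).
    """
    px = _require_gray(img, "equalize_global")
    hist = np.bincount(px.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) <= 1:
        return replace(img, pixels=px.copy())
    cdf = np.cumsum(hist) / hist.sum()
    cdf0 = hist[0] / hist.sum()
    lut = np.clip(np.rint(255.0 * (cdf - cdf0) / (1.0 - cdf0)), 0, 255).astype(np.uint8)
    return replace(img, pixels=lut[px])


def equalize_adaptive(
    img: CalibratedImage, tiles: int = 8, clip_limit: float = 0.01
) -> CalibratedImage:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    The image is equalized over a ``tiles x tiles`` grid of contextual
    regions with bilinear blending; ``clip_limit`` is the fraction of a
    tile's mass any histogram bin may hold.  ``tiles=1`` with no clip
    (``clip_limit`` None or inf) degenerates to :func:`equalize_global`.
    """
    px = _require_gray(img, "equalize_adaptive")
    if tiles < 1:
        raise PreprocessError("tiles must be >= 1")
    h, w = px.shape
    if min(h, w) // tiles < 2:
        raise PreprocessError(f"tile smaller than 2 px for {tiles} tiles on {w}x{h}")
    no_clip = clip_limit is None or clip_limit == np.inf
    if tiles == 1 and no_clip:
        return equalize_global(img)
    if np.count_nonzero(np.bincount(px.ravel(), minlength=256)) <= 1:
        return replace(img, pixels=px.copy())
    out = equalize_adapthist(
        px,
        kernel_size=(max(h // tiles, 2), max(w // tiles, 2)),
        clip_limit=1.0 if no_clip else float(clip_limit),
        nbins=256,
    )
    return replace(img, pixels=np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8))


def remove_background(
    img: CalibratedImage, opening_radius_px: int = 15, vessels_dark: bool = True
) -> CalibratedImage:
    """Top-hat background removal; output is always vessels-bright.

    With ``vessels_dark`` (photographs) the image is inverted first, then
    the morphological opening (disk structuring element) is subtracted,
    so dark tubular structures narrower than ``2 * opening_radius_px``
    become bright foreground on a flat (zero) background.  With
    ``vessels_dark=False`` the plain white top-hat is applied — which
    makes the operation idempotent on its own (bright-vessel) output.
    The radius must exceed the widest vessel's displayed half-width and
    stay below half the image size.
    """
    px = _require_gray(img, "remove_background")
    if opening_radius_px < 1:
        raise PreprocessError("opening radius must be >= 1 px")
    if opening_radius_px > min(px.shape) / 2:
        raise PreprocessError(
            f"opening radius {opening_radius_px} exceeds half the image size"
        )
    work = (255 - px).astype(np.uint8) if vessels_dark else px
    tophat = white_tophat(work, footprint=disk(int(opening_radius_px)))
    return replace(img, pixels=np.clip(tophat, 0, 255).astype(np.uint8))
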