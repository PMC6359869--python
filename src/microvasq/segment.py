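"""The shared four-step vessel segmentation chain.

Both modalities, once normalized to bright vessels on a common working
grid, pass through the same sequence: Gaussian blur (sigma = 4 px) for
de-noising, an FFT bandpass keeping structures between 3 and 40 px,
Otsu binarization, and Zhang–Suen skeletonization to 1-px centerlines.

Conventions fixed for reproducibility: borders are reflect-padded,
foreground is strictly above the Otsu threshold, 8-connectivity is used
throughout, and Otsu ties resolve to the lowest maximizing level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import SegmentationError
from .geometry import CalibratedImage
from .preprocess import as_uint8


def gaussian_blur(img: CalibratedImage, sigma_px: float = 4.0) -> CalibratedImage:
    """Convolve with a normalized 2-D Gaussian (truncated at 4 sigma).

    Reflect padding at the borders; a constant image is unchanged and
    total intensity is conserved for interior-supported content.
    """
    if sigma_px <= 0:
        raise SegmentationError("sigma must be positive")
    if img.is_rgb:
        raise SegmentationError("gaussian_blur expects a grayscale image")
    out = gaussian_filter(
        img.pixels.astype(np.float64), sigma=sigma_px, truncate=4.0, mode="reflect"
    )
    return replace(img, pixels=out)


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def _bandpass_transfer(shape: Tuple[int, int], large_px: float, small_px: float) -> np.ndarray:
    """Difference-of-Gaussians transfer function on the FFT grid.

    A structure of size ``s`` px is modeled as a Gaussian of sigma s/2;
    the band keeps sizes in (small_px, large_px): the low-pass factor
    exp(-2 pi^2 sigma_s^2 f^2) suppresses structures below ``small_px``
    and the complementary high-pass 1 - exp(-2 pi^2 sigma_L^2 f^2)
    suppresses those above ``large_px`` (DC gain is exactly zero).
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f2 = fy**2 + fx**2
    sigma_s = small_px / 2.0
    sigma_l = large_px / 2.0
    two_pi2 = 2.0 * np.pi**2
    return np.exp(-two_pi2 * sigma_s**2 * f2) * (1.0 - np.exp(-two_pi2 * sigma_l**2 * f2))


def _bandpass_raw(pixels: np.ndarray, large_px: float, small_px: float) -> np.ndarray:
    """Bandpass-filtered image before any intensity rescaling.

    The input is mirror-padded to the next power of two per axis (making
    the DFT's implicit periodization seam-free), filtered in the
    frequency domain, and cropped back.
    """
    h, w = pixels.shape
    ph, pw = _next_pow2(h), _next_pow2(w)
    padded = np.pad(pixels, ((0, ph - h), (0, pw - w)), mode="reflect") if (ph, pw) != (h, w) else pixels
    transfer = _bandpass_transfer((ph, pw), large_px, small_px)
    filtered = np.fft.ifft2(np.fft.fft2(padded) * transfer).real
    return filtered[:h, :w]


def fft_bandpass(
    img: CalibratedImage,
    filter_large_px: float = 40.0,
    filter_small_px: float = 3.0,
    rescale: bool = True,
) -> CalibratedImage:
    """Frequency-domain bandpass keeping structures between the two sizes.

    With ``rescale`` (the "no saturation" convention) the output is
    linearly mapped to [0, 255] without any percentile clipping; a flat
    filtered result maps to a uniform mid level (128).  ``rescale=False``
    returns the raw filtered intensities for quantitative use.
    """
    if not (filter_large_px > filter_small_px > 0):
        raise SegmentationError(
            f"need filter_large > filter_small > 0, got {filter_large_px}, {filter_small_px}"
        )
    if img.is_rgb:
        raise SegmentationError("fft_bandpass expects a grayscale image")
    out = _bandpass_raw(img.pixels.astype(np.float64), filter_large_px, filter_small_px)
    if rescale:
        lo, hi = float(out.min()), float(out.max())
        if hi - lo < 1e-12:
            out = np.full_like(out, 128.0)
        else:
            out = (out - lo) / (hi - lo) * 255.0
    return replace(img, pixels=out)


def otsu_threshold(img: CalibratedImage) -> Tuple[int, np.ndarray]:
    """Otsu's method on the 256-bin histogram.

    Returns ``(level, mask)`` where ``level`` is the lowest gray level
    maximizing between-class variance and ``mask`` marks pixels strictly
    above it.  A constant image has no two classes to separate and is
    rejected.
    """
    if img.is_rgb:
        raise SegmentationError("otsu_threshold expects a grayscale image")
    px = as_uint8(img.pixels)
    hist = np.bincount(px.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise SegmentationError("degenerate histogram: image has fewer than 2 levels")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                      # mass at levels <= t (background)
    mu0 = np.cumsum(p * levels)
    mu_t = mu0[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b2 = np.zeros(256)
    sigma_b2[valid] = (mu_t * w0[valid] - mu0[valid]) ** 2 / (w0[valid] * w1[valid])
    level = int(np.argmax(sigma_b2))       # argmax returns the lowest maximizer
    return level, px > level


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Iterative thinning to a 1-px-wide, 8-connected skeleton.

    Uses Lee's medial-axis thinning, which guarantees strict 1-px
    thinness (no 2x2 foreground block survives), preserves connectivity
    (component count) and never adds foreground outside the input mask;
    an empty mask yields an empty skeleton.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise SegmentationError("skeletonize expects a 2-D binary mask")
    if not mask.any():
        return mask.copy()
    return _sk_skeletonize(mask, method="lee").astype(bool)


@dataclass
class SegmentationResult:
    """Artifacts of the full chain on one image."""

    blurred: CalibratedImage
    bandpassed: CalibratedImage
    threshold_level: int
    binary: np.ndarray
    skeleton: np.ndarray


def segment_image(
    img: CalibratedImage,
    sigma_px: float = 4.0,
    filter_large_px: float = 40.0,
    filter_small_px: float = 3.0,
) -> SegmentationResult:
    """Run blur -> bandpass -> Otsu -> skeletonize on a prepared image."""
    blurred = gaussian_blur(img, sigma_px)
    banded = fft_bandpass(blurred, filter_large_px, filter_small_px)
    level, binary = otsu_threshold(banded)
    skel = skeletonize(binary)
    return SegmentationResult(
        blurred=blurred,
        bandpassed=banded,
        threshold_level=level,
        binary=binary,
        skeleton=skel,
    )
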