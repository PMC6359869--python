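"""Shared fixtures: small synthetic inputs generated at test time."""

import numpy as np
import pytest

from microvasq import (
    CalibratedImage,
    ModalityParams,
    SyntheticConfig,
    generate_network,
)


@pytest.fixture(scope="session")
def dense_network():
    """Default-condition network (dense plexus over the photo FOV)."""
    return generate_network(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def sparse_wide_network():
    """Sparse network of wide vessels (>=3 px on the coarse native grid);
    the recovery-test condition where vessel merging is negligible."""
    cfg = SyntheticConfig(
        seed=5, n_roots=10, branch_probability=0.03, width_range_mm=(0.09, 0.12)
    )
    return generate_network(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gradient_image():
    """Smooth grayscale image with a full intensity range."""
    y, x = np.mgrid[0:96, 0:96]
    px = ((x + y) / (2 * 95) * 255).astype(np.uint8)
    return CalibratedImage(px, fov_mm=(4.0, 4.0), modality="test")


def random_blob_mask(rng, shape=(96, 96), threshold_pct=70, sigma=4):
    """Random smooth blobs, the standard mask fixture for thinning tests."""
    from skimage.filters import gaussian

    img = gaussian(rng.random(shape), sigma)
    return img > np.percentile(img, threshold_pct)


def bruteforce_otsu(u8):
    """Independent oracle: scan all 256 thresholds, maximize between-class
    variance; exact plateau ties resolve to the lowest level."""
    hist = np.bincount(u8.ravel(), minlength=256) / u8.size
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v * (1 + 1e-9) + 1e-15:
            best_v, best_t = v, t
    return best_t
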