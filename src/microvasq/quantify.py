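"""Vessel-density readouts from a skeletonized mask.

Two complementary density indices are computed from the same skeleton:

* **density %** — foreground pixels as a percentage of all pixels, the
  pixel-counting convention that weights every vessel equally once the
  mask is thinned to centerlines;
* **Dbox** — the box-counting fractal dimension, the slope of
  log N(s) versus log(1/s) where N(s) is the number of s x s grid boxes
  containing at least one skeleton pixel.  The default schedule uses 15
  box sizes in geometric progression from a 104-px largest box down to
  2 px, fitted by ordinary least squares with the r^2 reported so poor
  fits are visible.

Boxes tile from the top-left origin and partial boxes at the edges
count.  Optionally the count at each size can be minimized over several
regularly spaced grid origins; the default is a single origin for
determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import QuantifyError


@dataclass
class BoxCountConfig:
    """Box-counting schedule: largest box side, number of sizes, spacing."""

    largest_box_px: int = 104
    n_sizes: int = 15
    schedule: str = "geometric"  # "geometric" | "linear"
    grid_offsets: int = 1
    smallest_box_px: int = 2

    def validate(self) -> None:
        if self.n_sizes < 3:
            raise QuantifyError("n_sizes must be >= 3 (the log-log fit needs 3 points)")
        if self.largest_box_px < self.smallest_box_px or self.smallest_box_px < 1:
            raise QuantifyError(
                f"need largest_box >= smallest_box >= 1, got "
                f"{self.largest_box_px}, {self.smallest_box_px}"
            )
        if self.schedule not in ("geometric", "linear"):
            raise QuantifyError(f"unknown schedule {self.schedule!r}")
        if self.grid_offsets < 1:
            raise QuantifyError("grid_offsets must be >= 1")


@dataclass
class BoxCountResult:
    """Per-size occupied-box counts and the fitted log-log slope."""

    sizes_px: List[int]
    counts: List[int]
    dbox: float
    r_squared: float


@dataclass
class DensityRecord:
    """One image's pair of density readouts with provenance."""

    subject: str = ""
    eye: str = ""
    modality: str = ""
    density_percent: float = 0.0
    dbox: float = 0.0
    r_squared: float = 0.0


def density_percent(skel: np.ndarray) -> float:
    """Percentage of skeleton (foreground) pixels over the whole image."""
    skel = np.asarray(skel, dtype=bool)
    if skel.size == 0:
        raise QuantifyError("empty image has no density")
    return 100.0 * float(skel.sum()) / float(skel.size)


def box_size_schedule(cfg: BoxCountConfig) -> List[int]:
    """Integer box sizes, strictly decreasing from the largest box.

    Geometric (default) or linear spacing between ``largest_box_px`` and
    ``smallest_box_px``; after rounding, duplicates are collapsed and the
    list is backfilled with unused integer sizes (nearest the ideal
    real-valued targets) to keep ``n_sizes`` distinct sizes when the
    integer range allows.
    """
    cfg.validate()
    lo, hi, n = cfg.smallest_box_px, cfg.largest_box_px, cfg.n_sizes
    if cfg.schedule == "geometric":
        targets = hi * (lo / hi) ** (np.arange(n) / (n - 1))
    else:
        targets = np.linspace(hi, lo, n)
    sizes: List[int] = []
    used = set()
    for t in targets:
        s = int(round(t))
        if s not in used and lo <= s <= hi:
            sizes.append(s)
            used.add(s)
    # Backfill collapsed duplicates with the free integers closest to the
    # ideal schedule, as long as the integer range can host them.
    free = [s for s in range(hi, lo - 1, -1) if s not in used]
    while len(sizes) < n and free:
        best = min(
            free,
            key=lambda s: min(abs(s - t) for t in targets),
        )
        sizes.append(best)
        used.add(best)
        free.remove(best)
    return sorted(sizes, reverse=True)


def _count_occupied(skel: np.ndarray, size: int, origin: Tuple[int, int] = (0, 0)) -> int:
    """Occupied s x s boxes tiling from ``origin``; partial edge boxes count."""
    r0, c0 = origin
    h, w = skel.shape
    # Shift the grid by padding in front; pad behind to a multiple of size.
    padded = np.pad(skel, ((r0, (-(h + r0)) % size), (c0, (-(w + c0)) % size)))
    ph, pw = padded.shape
    blocks = padded.reshape(ph // size, size, pw // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count(skel: np.ndarray, cfg: BoxCountConfig | None = None) -> BoxCountResult:
    """Box-counting dimension of a skeleton mask.

    For each size in the schedule, tiles the image from the top-left
    origin with s x s boxes and counts those containing foreground; with
    ``cfg.grid_offsets > 1`` the minimum count over that many regularly
    spaced origins is taken.  Dbox is the OLS slope of log N(s) on
    log(1/s).
    """
    if cfg is None:
        cfg = BoxCountConfig()
    cfg.validate()
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        raise QuantifyError("Dbox undefined for empty mask")
    if cfg.largest_box_px > min(skel.shape):
        raise QuantifyError(
            f"grid {skel.shape[1]}x{skel.shape[0]} too small to host the "
            f"largest box ({cfg.largest_box_px} px)"
        )
    sizes = box_size_schedule(cfg)
    counts: List[int] = []
    for s in sizes:
        if cfg.grid_offsets == 1 or s == 1:
            counts.append(_count_occupied(skel, s))
        else:
            offs = np.unique(np.linspace(0, s - 1, cfg.grid_offsets).astype(int))
            counts.append(min(_count_occupied(skel, s, (o, o)) for o in offs))
    x = np.log(1.0 / np.asarray(sizes, dtype=np.float64))
    y = np.log(np.asarray(counts, dtype=np.float64))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return BoxCountResult(sizes_px=sizes, counts=counts, dbox=float(slope), r_squared=r2)


def quantify_skeleton(
    skel: np.ndarray,
    cfg: BoxCountConfig | None = None,
    subject: str = "",
    eye: str = "",
    modality: str = "",
) -> DensityRecord:
    """Bundle the two density readouts for one skeleton."""
    result = box_count(skel, cfg)
    return DensityRecord(
        subject=subject,
        eye=eye,
        modality=modality,
        density_percent=density_percent(skel),
        dbox=result.dbox,
        r_squared=result.r_squared,
    )
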