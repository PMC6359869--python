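"""Synthetic paired-modality vascular phantoms.

The conjunctival plexus is emulated by a seeded branching random walk:
``n_roots`` seed points each grow a polyline whose heading receives
wrapped-normal jitter per step; at each step a tip may spawn a daughter
branch (probability ``branch_probability``) whose caliber tapers by a
fixed factor per generation.  The same ground-truth network is then
rendered twice:

* ``octa_like`` — a coarse scanning grid (304 x 304 over 8.775 x 8.775
  mm^2, i.e. ~29 um pixels, wider than most vessel calibers) with
  multiplicative exponential speckle and bright vessels;
* ``fslb_like`` — a fine photographic grid (5184 x 3456 over 15.74 x
  10.50 mm^2, ~3 um pixels) with additive Gaussian noise, radial
  vignetting, and dark vessels on a bright background.

Vessels are drawn as tubes with a Gaussian cross-section.  Two
grid-derived factors attenuate vessels narrower than the sampling
pitch: the lateral point spread dilutes the peak by
sigma_vessel / sigma_eff (sigma_eff^2 = sigma_vessel^2 + sigma_psf^2,
half-pixel PSF) and the resolution-cell fill fraction
min(width / pitch, 1) bounds the signal a cell can carry — together the
mechanism by which a coarse scanning raster under-reports capillaries
while a fine photographic grid renders them at full contrast.

All coordinates are physical mm with origin at the field's top-left,
x rightward, y downward.  Every operation is a pure function of its
inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage.draw import line as _bresenham_line

from .errors import MicrovasqError
from .geometry import CalibratedImage

# Native acquisition geometries of the two emulated instruments.
OCTA_GRID = (304, 304)            # (width, height) px
OCTA_FOV_MM = (8.775, 8.775)
FSLB_GRID = (5184, 3456)
FSLB_FOV_MM = (15.74, 10.50)


@dataclass
class SyntheticConfig:
    """Parameters of the branching-walk network generator.

    Calibers are bounded at 0.2 mm: conjunctival capillaries, arterioles
    and venules measure tens of micrometres.
    """

    seed: int = 0
    n_roots: int = 35
    branch_probability: float = 0.04
    mean_segment_len_mm: float = 0.15
    width_range_mm: Tuple[float, float] = (0.015, 0.08)
    fov_mm: Tuple[float, float] = FSLB_FOV_MM
    n_steps: int = 45
    taper: float = 0.9
    angle_jitter_sd: float = 0.35
    max_segments: int = 50_000

    def validate(self) -> None:
        lo, hi = self.width_range_mm
        if not (0 < lo <= hi <= 0.2):
            raise MicrovasqError(
                f"width_range_mm must satisfy 0 < min <= max <= 0.2, got {self.width_range_mm}"
            )
        if self.n_roots < 0:
            raise MicrovasqError("n_roots must be >= 0")
        if not (0.0 <= self.branch_probability <= 1.0):
            raise MicrovasqError("branch_probability must be in [0, 1]")
        if self.mean_segment_len_mm <= 0:
            raise MicrovasqError("mean_segment_len_mm must be positive")
        if self.fov_mm[0] <= 0 or self.fov_mm[1] <= 0:
            raise MicrovasqError("fov_mm must be positive")


@dataclass
class ModalityParams:
    """Rendering geometry and noise model of one imaging modality."""

    native_grid: Tuple[int, int]       # (width, height) px
    fov_mm: Tuple[float, float]
    noise_model: str = "gaussian"      # "speckle" | "gaussian"
    noise_level: float = 0.0
    vignetting_strength: float = 0.0
    background_level: float = 0.0
    vessels_dark: bool = False
    modality: str = "unknown"

    def validate(self) -> None:
        if self.native_grid[0] <= 0 or self.native_grid[1] <= 0:
            raise MicrovasqError("native_grid must be positive")
        if self.noise_model not in ("speckle", "gaussian"):
            raise MicrovasqError(f"unknown noise model {self.noise_model!r}")
        if self.noise_level < 0:
            raise MicrovasqError("noise_level must be >= 0")
        if not (0.0 <= self.vignetting_strength <= 1.0):
            raise MicrovasqError("vignetting_strength must be in [0, 1]")
        if not (0.0 <= self.background_level <= 1.0):
            raise MicrovasqError("background_level must be in [0, 1]")

    @classmethod
    def octa_like(cls, **overrides) -> "ModalityParams":
        """Coarse angiography-like raster: speckle, bright vessels."""
        kw = dict(
            native_grid=OCTA_GRID,
            fov_mm=OCTA_FOV_MM,
            noise_model="speckle",
            noise_level=0.3,
            vignetting_strength=0.0,
            background_level=0.05,
            vessels_dark=False,
            modality="octa_like",
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def fslb_like(cls, **overrides) -> "ModalityParams":
        """Fine photography-like raster: Gaussian noise, vignetting, dark vessels."""
        kw = dict(
            native_grid=FSLB_GRID,
            fov_mm=FSLB_FOV_MM,
            noise_model="gaussian",
            noise_level=0.02,
            vignetting_strength=0.3,
            background_level=0.85,
            vessels_dark=True,
            modality="fslb_like",
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GroundTruthNetwork:
    """Shared vascular truth both modality renderers consume.

    ``segments`` are polylines in mm; ``widths_mm`` gives one caliber per
    segment.  All vertices lie inside ``fov_mm``.
    """

    segments: List[np.ndarray] = field(default_factory=list)
    widths_mm: List[float] = field(default_factory=list)
    fov_mm: Tuple[float, float] = FSLB_FOV_MM

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_length_mm(self) -> float:
        total = 0.0
        for poly in self.segments:
            total += float(np.sqrt(np.diff(poly, axis=0) ** 2 @ [1.0, 1.0]).sum())
        return total


def _clip_to_fov(p: np.ndarray, q: np.ndarray, fov: Tuple[float, float]) -> np.ndarray:
    """Clip segment p->q at the FOV border; q is assumed outside."""
    d = q - p
    t = 1.0
    for axis, bound in ((0, fov[0]), (1, fov[1])):
        if d[axis] > 0:
            t = min(t, (bound - p[axis]) / d[axis])
        elif d[axis] < 0:
            t = min(t, (0.0 - p[axis]) / d[axis])
    return p + max(t, 0.0) * d


def generate_network(config: SyntheticConfig) -> GroundTruthNetwork:
    """Grow a seeded branching-walk network clipped to the FOV.

    Identical ``(config, seed)`` yields bitwise-identical networks;
    ``n_roots = 0`` yields an empty network.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fw, fh = config.fov_mm
    lo_w, hi_w = config.width_range_mm

    # Roots are stratified over a jittered grid so the plexus is dense
    # everywhere, as the conjunctival network is; a purely uniform draw
    # leaves unrealistic empty patches in the analyzed window.
    roots: List[np.ndarray] = []
    if config.n_roots > 0:
        ncols = max(int(round(math.sqrt(config.n_roots * fw / fh))), 1)
        nrows = max(int(math.ceil(config.n_roots / ncols)), 1)
        cells = [(r, c) for r in range(nrows) for c in range(ncols)]
        for r, c in cells[: config.n_roots]:
            roots.append(
                np.array(
                    [
                        (c + rng.uniform(0.1, 0.9)) * fw / ncols,
                        (r + rng.uniform(0.1, 0.9)) * fh / nrows,
                    ]
                )
            )

    # Active tips: (current point, heading, width, vertex list)
    tips: List[dict] = []
    for p in roots:
        tips.append(
            {
                "pos": p,
                "heading": rng.uniform(0, 2 * math.pi),
                "width": rng.uniform(lo_w, hi_w),
                "verts": [p.copy()],
            }
        )

    done_segments: List[np.ndarray] = []
    done_widths: List[float] = []

    def _emit(tip: dict) -> None:
        if len(tip["verts"]) >= 2:
            done_segments.append(np.asarray(tip["verts"], dtype=np.float64))
            done_widths.append(float(tip["width"]))

    for _ in range(config.n_steps):
        if not tips:
            break
        next_tips: List[dict] = []
        for tip in tips:
            tip["heading"] += rng.normal(0.0, config.angle_jitter_sd)
            step = config.mean_segment_len_mm * rng.uniform(0.7, 1.3)
            q = tip["pos"] + step * np.array(
                [math.cos(tip["heading"]), math.sin(tip["heading"])]
            )
            if not (0.0 <= q[0] <= fw and 0.0 <= q[1] <= fh):
                q = _clip_to_fov(tip["pos"], q, config.fov_mm)
                if np.linalg.norm(q - tip["pos"]) > 1e-9:
                    tip["verts"].append(q)
                _emit(tip)
                continue  # tip dies at the border
            tip["verts"].append(q)
            tip["pos"] = q
            next_tips.append(tip)
            n_alive = (
                len(next_tips) + len(done_segments)
            )
            if (
                rng.uniform() < config.branch_probability
                and n_alive < config.max_segments
            ):
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                child_width = max(tip["width"] * config.taper, lo_w)
                next_tips.append(
                    {
                        "pos": q.copy(),
                        "heading": tip["heading"] + sign * rng.uniform(0.3, 0.9),
                        "width": child_width,
                        "verts": [q.copy()],
                    }
                )
        tips = next_tips

    for tip in tips:
        _emit(tip)
    return GroundTruthNetwork(
        segments=done_segments, widths_mm=done_widths, fov_mm=config.fov_mm
    )


def _mm_to_px(
    net_fov: Tuple[float, float],
    render_fov: Tuple[float, float],
    grid: Tuple[int, int],
) -> Tuple[float, float, float, float]:
    """Affine mm->px mapping for the centered render window.

    Returns (x0_mm, y0_mm, sx, sy): px = (mm - origin) * scale - 0.5,
    so pixel centers sit at (i + 0.5) * (mm/px).
    """
    w_px, h_px = grid
    x0 = (net_fov[0] - render_fov[0]) / 2.0
    y0 = (net_fov[1] - render_fov[1]) / 2.0
    sx = w_px / render_fov[0]
    sy = h_px / render_fov[1]
    return x0, y0, sx, sy


def _render_tubes(
    net: GroundTruthNetwork,
    grid: Tuple[int, int],
    fov_mm: Tuple[float, float],
    sigma_psf_px: float = 0.5,
) -> np.ndarray:
    """Rasterize the network as Gaussian-profile tubes, peak-combined.

    Vessels narrower than the sampling pitch are doubly attenuated: the
    lateral point spread dilutes the peak by sigma_vessel / sigma_eff
    (cross-sectional flux conservation), and the resolution-cell fill
    fraction min(width / pitch, 1) scales the signal a cell can carry.
    On a coarse scanning grid (pitch wider than capillary calibers) thin
    vessels therefore fade toward the noise floor, while a fine
    photographic grid renders them at full contrast.
    """
    w_px, h_px = grid
    canvas = np.zeros((h_px, w_px), dtype=np.float32)
    if not net.segments:
        return canvas
    x0, y0, sx, sy = _mm_to_px(net.fov_mm, fov_mm, grid)
    s_iso = 0.5 * (sx + sy)  # tube cross-sections use the mean scale
    pitch_mm = 1.0 / s_iso
    for poly, width in zip(net.segments, net.widths_mm):
        sigma_w = max(width / 2.0 * s_iso, 1e-6)
        sigma_eff = math.hypot(sigma_w, sigma_psf_px)
        amp = (sigma_w / sigma_eff) * min(width / pitch_mm, 1.0)
        pad = int(math.ceil(3.0 * sigma_eff)) + 1
        px = (poly[:, 0] - x0) * sx - 0.5
        py = (poly[:, 1] - y0) * sy - 0.5
        for k in range(len(poly) - 1):
            ax, ay, bx, by = px[k], py[k], px[k + 1], py[k + 1]
            c0 = max(int(math.floor(min(ax, bx))) - pad, 0)
            c1 = min(int(math.ceil(max(ax, bx))) + pad + 1, w_px)
            r0 = max(int(math.floor(min(ay, by))) - pad, 0)
            r1 = min(int(math.ceil(max(ay, by))) + pad + 1, h_px)
            if c0 >= c1 or r0 >= r1:
                continue
            yy, xx = np.mgrid[r0:r1, c0:c1]
            dx, dy = bx - ax, by - ay
            denom = dx * dx + dy * dy
            if denom < 1e-12:
                d2 = (xx - ax) ** 2 + (yy - ay) ** 2
            else:
                t = ((xx - ax) * dx + (yy - ay) * dy) / denom
                t = np.clip(t, 0.0, 1.0)
                d2 = (xx - (ax + t * dx)) ** 2 + (yy - (ay + t * dy)) ** 2
            patch = (amp * np.exp(-d2 / (2.0 * sigma_eff**2))).astype(np.float32)
            np.maximum(canvas[r0:r1, c0:c1], patch, out=canvas[r0:r1, c0:c1])
    return canvas


def render_modality(
    net: GroundTruthNetwork, params: ModalityParams, seed: int = 0
) -> CalibratedImage:
    """Render the network through one modality's geometry and noise model.

    The render window is the centered ``params.fov_mm`` region of the
    network's FOV.  Output pixels are float32 in [0, 1] with the FOV and
    modality tag attached.
    """
    params.validate()
    if params.fov_mm[0] > net.fov_mm[0] + 1e-9 or params.fov_mm[1] > net.fov_mm[1] + 1e-9:
        raise MicrovasqError(
            "network FOV must cover the modality FOV "
            f"({net.fov_mm} vs {params.fov_mm})"
        )
    rng = np.random.default_rng(seed)
    clean = _render_tubes(net, params.native_grid, params.fov_mm)  # float32, in-place below
    w_px, h_px = params.native_grid

    bg = np.float32(params.background_level)
    if params.vessels_dark:
        clean *= np.float32(-0.85)
        clean += np.float32(1.0)
        clean *= bg  # bg * (1 - 0.85 * vessels)
    else:
        clean *= np.float32(1.0) - bg
        clean += bg  # bg + (1 - bg) * vessels

    if params.vignetting_strength > 0:
        cx, cy = (w_px - 1) / 2.0, (h_px - 1) / 2.0
        rx2 = (((np.arange(w_px, dtype=np.float32) - cx) / max(cx, 1.0)) ** 2)[None, :]
        ry2 = (((np.arange(h_px, dtype=np.float32) - cy) / max(cy, 1.0)) ** 2)[:, None]
        vign = ry2 + rx2
        vign *= np.float32(-params.vignetting_strength / 2.0)
        vign += np.float32(1.0)
        clean *= vign

    if params.noise_level > 0:
        if params.noise_model == "speckle":
            # multiplicative exponential speckle, mean-preserving
            mult = rng.standard_exponential(size=clean.shape, dtype=np.float32)
            mult -= np.float32(1.0)
            mult *= np.float32(params.noise_level)
            mult += np.float32(1.0)
            clean *= mult
        else:
            noise = rng.standard_normal(size=clean.shape, dtype=np.float32)
            noise *= np.float32(params.noise_level)
            clean += noise
    np.clip(clean, 0.0, 1.0, out=clean)
    return CalibratedImage(pixels=clean, fov_mm=params.fov_mm, modality=params.modality)


def ground_truth_skeleton(
    net: GroundTruthNetwork,
    grid: Tuple[int, int],
    fov_mm: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Rasterize 1-px centerlines of the network on the requested grid.

    Serves as the oracle mask for recovery tests.  ``fov_mm`` defaults to
    the network's own FOV; otherwise the centered window is used, as in
    :func:`render_modality`.
    """
    w_px, h_px = grid
    if w_px <= 0 or h_px <= 0:
        raise MicrovasqError("grid must be positive")
    if fov_mm is None:
        fov_mm = net.fov_mm
    if fov_mm[0] <= 0 or fov_mm[1] <= 0:
        raise MicrovasqError("fov_mm must be positive")
    mask = np.zeros((h_px, w_px), dtype=bool)
    if not net.segments:
        return mask
    x0, y0, sx, sy = _mm_to_px(net.fov_mm, fov_mm, grid)
    for poly in net.segments:
        cols = np.clip(np.rint((poly[:, 0] - x0) * sx - 0.5).astype(int), 0, w_px - 1)
        rows = np.clip(np.rint((poly[:, 1] - y0) * sy - 0.5).astype(int), 0, h_px - 1)
        inside = (
            (poly[:, 0] >= x0)
            & (poly[:, 0] <= x0 + fov_mm[0])
            & (poly[:, 1] >= y0)
            & (poly[:, 1] <= y0 + fov_mm[1])
        )
        for k in range(len(poly) - 1):
            if not (inside[k] or inside[k + 1]):
                continue
            rr, cc = _bresenham_line(rows[k], cols[k], rows[k + 1], cols[k + 1])
            mask[rr, cc] = True
    return mask
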