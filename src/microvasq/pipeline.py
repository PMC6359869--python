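"""End-to-end orchestration: raw modality image -> density record.

The processing chain mirrors the acquisition-to-analysis route used for
paired conjunctival imaging studies:

* angiogram-like inputs (bright vessels, 304 px native grid, 8.775 mm
  FOV) are up-sampled to a 1024-px intermediate grid and center-cropped
  to the 768-px working window (6.581 mm reported FOV);
* photograph-like inputs (dark vessels, 5184 x 3456 native grid,
  15.74 x 10.50 mm FOV) are converted to grayscale, resized to width
  1024, enhanced with adaptive equalization and black-top-hat background
  removal (which also flips them to bright-vessel polarity), then
  cropped to the same physical window and resampled to 768 px.

Both then share global equalization and the common segmentation chain
(Gaussian blur sigma 4, bandpass 40/3 px, Otsu, skeletonization) and the
same density quantification.  ``run_paired_study`` is the synthetic
analog of a 2-eyes-per-subject paired design.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import preprocess, quantify, segment, stats, synthetic
from .errors import MicrovasqError, PipelineError
from .geometry import CalibratedImage, center_crop, resize, resize_to_width, write_image
from .quantify import BoxCountConfig, DensityRecord
from .synthetic import ModalityParams, SyntheticConfig


@dataclass
class ModalityProfile:
    """Per-modality preprocessing toggles ahead of the shared chain."""

    vessels_dark: bool = False
    adaptive_equalize: bool = False
    open_radius_px: Optional[int] = None
    gray_method: str = "green"
    adaptive_tiles: int = 8
    adaptive_clip: float = 0.01


def default_profiles() -> Dict[str, ModalityProfile]:
    return {
        "octa_like": ModalityProfile(vessels_dark=False),
        "fslb_like": ModalityProfile(
            vessels_dark=True, adaptive_equalize=True, open_radius_px=15
        ),
    }


@dataclass
class PipelineConfig:
    """Everything a deterministic end-to-end run needs."""

    working_px: int = 768
    intermediate_px: int = 1024
    target_fov_mm: float = 8.775 * 768 / 1024  # 6.58125, reported as 6.581
    sigma_px: float = 4.0
    bp_large_px: float = 40.0
    bp_small_px: float = 3.0
    boxcount: BoxCountConfig = field(default_factory=BoxCountConfig)
    seed: int = 0
    profiles: Dict[str, ModalityProfile] = field(default_factory=default_profiles)
    synthetic_cfg: SyntheticConfig = field(default_factory=SyntheticConfig)
    octa_params: ModalityParams = field(default_factory=ModalityParams.octa_like)
    fslb_params: ModalityParams = field(default_factory=ModalityParams.fslb_like)

    def to_yaml(self) -> str:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return yaml.safe_dump(listify(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        kw = dict(raw)
        if "boxcount" in kw:
            kw["boxcount"] = BoxCountConfig(**kw["boxcount"])
        if "profiles" in kw:
            kw["profiles"] = {
                k: ModalityProfile(**v) for k, v in kw["profiles"].items()
            }
        if "synthetic_cfg" in kw:
            sc = dict(kw["synthetic_cfg"])
            for key in ("width_range_mm", "fov_mm"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            kw["synthetic_cfg"] = SyntheticConfig(**sc)
        for name in ("octa_params", "fslb_params"):
            if name in kw:
                mp = dict(kw[name])
                for key in ("native_grid", "fov_mm"):
                    if key in mp:
                        mp[key] = tuple(mp[key])
                kw[name] = ModalityParams(**mp)
        return cls(**kw)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MicrovasqError as err:
        raise PipelineError(f"{name}: {err}") from err


def _dump(img_or_mask, outdir: Optional[str], name: str, fov_mm: Tuple[float, float]) -> None:
    if outdir is None:
        return
    px = img_or_mask
    if isinstance(px, CalibratedImage):
        image = px
    else:
        image = CalibratedImage(
            pixels=np.asarray(px, dtype=bool).astype(np.uint8) * 255,
            fov_mm=fov_mm,
            modality="mask",
        )
    if np.issubdtype(image.pixels.dtype, np.floating):
        lo, hi = float(image.pixels.min()), float(image.pixels.max())
        scale = (image.pixels - lo) / (hi - lo) if hi > lo else image.pixels * 0.0
        image = replace(image, pixels=scale)
    write_image(image, os.path.join(outdir, name))


@dataclass
class PipelineResult:
    """Artifacts of a full single-image run."""

    working: CalibratedImage
    threshold_level: int
    binary: np.ndarray
    skeleton: np.ndarray
    record: DensityRecord


def process_image(
    img: CalibratedImage,
    cfg: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
    subject: str = "",
    eye: str = "",
) -> PipelineResult:
    """Process one calibrated image through the full chain.

    Executes the modality-appropriate preparation, geometry
    normalization to the working grid, the shared segmentation chain and
    the density quantification.  When ``outdir`` is given every
    intermediate is written as a PNG in stage order.  Any stage failure
    aborts with the stage name in the message.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
    profile = cfg.profiles.get(img.modality, ModalityProfile())

    _dump(img, outdir, "00_input.png", img.fov_mm)
    if img.is_rgb:
        img = _stage("to_grayscale", preprocess.to_grayscale, img, profile.gray_method)
        _dump(img, outdir, "01_grayscale.png", img.fov_mm)

    # Resample to the shared intermediate sampling pitch (width 1024).
    img = _stage("resize_intermediate", resize_to_width, img, cfg.intermediate_px)
    _dump(img, outdir, "02_resized.png", img.fov_mm)

    if profile.adaptive_equalize:
        img = _stage(
            "equalize_adaptive",
            preprocess.equalize_adaptive,
            img,
            profile.adaptive_tiles,
            profile.adaptive_clip,
        )
        _dump(img, outdir, "03_equalized_adaptive.png", img.fov_mm)
    if profile.open_radius_px is not None:
        img = _stage(
            "remove_background", preprocess.remove_background, img, profile.open_radius_px
        )
        _dump(img, outdir, "04_background_removed.png", img.fov_mm)
    elif profile.vessels_dark:
        img = _stage(
            "invert",
            lambda im: replace(im, pixels=255 - preprocess.as_uint8(im.pixels)),
            img,
        )

    # Crop the common physical window and resample to the working grid.
    mmx, mmy = img.mm_per_px
    crop_w = int(round(cfg.target_fov_mm / mmx))
    crop_h = int(round(cfg.target_fov_mm / mmy))
    img = _stage("crop_working_fov", center_crop, img, crop_w, crop_h)
    img = _stage("resize_working", resize, img, cfg.working_px, cfg.working_px)
    _dump(img, outdir, "05_working.png", img.fov_mm)

    img = _stage("equalize_global", preprocess.equalize_global, img)
    _dump(img, outdir, "06_equalized.png", img.fov_mm)

    blurred = _stage("gaussian_blur", segment.gaussian_blur, img, cfg.sigma_px)
    _dump(blurred, outdir, "07_blurred.png", img.fov_mm)
    banded = _stage(
        "fft_bandpass", segment.fft_bandpass, blurred, cfg.bp_large_px, cfg.bp_small_px
    )
    _dump(banded, outdir, "08_bandpassed.png", img.fov_mm)
    level, binary = _stage("otsu_threshold", segment.otsu_threshold, banded)
    _dump(binary, outdir, "09_binary.png", img.fov_mm)
    skel = _stage("skeletonize", segment.skeletonize, binary)
    _dump(skel, outdir, "10_skeleton.png", img.fov_mm)

    record = _stage(
        "quantify",
        quantify.quantify_skeleton,
        skel,
        cfg.boxcount,
        subject,
        eye,
        img.modality,
    )
    if outdir is not None:
        with open(os.path.join(outdir, "record.json"), "w") as fh:
            json.dump(dataclasses.asdict(record), fh, indent=2, sort_keys=True)
    return PipelineResult(
        working=img,
        threshold_level=level,
        binary=binary,
        skeleton=skel,
        record=record,
    )


def run_single(
    img: CalibratedImage,
    cfg: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
    subject: str = "",
    eye: str = "",
) -> DensityRecord:
    """Full chain on one image; returns just the density record."""
    return process_image(img, cfg, outdir=outdir, subject=subject, eye=eye).record


def process_pair(
    net: synthetic.GroundTruthNetwork,
    cfg: PipelineConfig,
    render_seeds: Tuple[int, int],
    subject: str = "",
    eye: str = "",
    outdir: Optional[str] = None,
) -> Tuple[DensityRecord, DensityRecord]:
    """Render one network through both modalities and quantify each."""
    img_o = synthetic.render_modality(net, cfg.octa_params, seed=render_seeds[0])
    img_f = synthetic.render_modality(net, cfg.fslb_params, seed=render_seeds[1])
    sub_o = os.path.join(outdir, f"{subject}_{eye}_octa") if outdir else None
    sub_f = os.path.join(outdir, f"{subject}_{eye}_fslb") if outdir else None
    rec_o = run_single(img_o, cfg, outdir=sub_o, subject=subject, eye=eye)
    rec_f = run_single(img_f, cfg, outdir=sub_f, subject=subject, eye=eye)
    return rec_o, rec_f


def _study_stats(df: pd.DataFrame, a_mod: str, b_mod: str) -> Dict:
    """All between-modality statistics for a records table."""
    da = df[df.modality == a_mod].sort_values(["subject", "eye"])
    db = df[df.modality == b_mod].sort_values(["subject", "eye"])
    out: Dict = {"orientation": f"{a_mod} - {b_mod}", "n_pairs": int(len(da))}
    for metric in ("density_percent", "dbox"):
        a = da[metric].to_numpy()
        b = db[metric].to_numpy()
        pc = stats.paired_compare(a, b)
        ba = stats.bland_altman(a, b)
        out[metric] = {
            "paired": dataclasses.asdict(pc),
            "bland_altman": dataclasses.asdict(ba),
            "summary": {
                a_mod: dict(zip(("mean", "sd"), stats.summarize(a))),
                b_mod: dict(zip(("mean", "sd"), stats.summarize(b))),
            },
        }
        try:
            r, p = stats.pearson(a, b)
            out[metric]["cross_modality_pearson"] = {"r": r, "p": p}
        except MicrovasqError:
            out[metric]["cross_modality_pearson"] = None
    for mod, sub in (("a", da), ("b", db)):
        r, p = stats.pearson(sub["density_percent"].to_numpy(), sub["dbox"].to_numpy())
        out[f"percent_vs_dbox_pearson_{mod}"] = {
            "modality": a_mod if mod == "a" else b_mod,
            "r": r,
            "p": p,
        }
    return out


def run_paired_study(
    n_subjects: int,
    cfg: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
    subject_level: bool = False,
    save_intermediates: bool = False,
) -> Dict:
    """Simulate a paired two-eyes-per-subject study and compare modalities.

    For every eye a fresh ground-truth network is grown, rendered through
    both modality models, pushed through the full pipeline and
    quantified.  Returns a report with the records and all comparison
    statistics; when ``outdir`` is given, writes ``records.csv``,
    ``report.json`` and the Bland–Altman / scatter plots.

    ``subject_level=True`` averages the two eyes per subject before the
    paired statistics (units are then subjects, not eyes).
    """
    if n_subjects < 2:
        raise PipelineError("run_paired_study: need n_subjects >= 2")
    if cfg is None:
        cfg = PipelineConfig()
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    eye_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects * 2, 3))
    records: List[DensityRecord] = []
    idx = 0
    for s in range(n_subjects):
        for eye in ("OD", "OS"):
            net_seed, so, sf = (int(v) for v in eye_seeds[idx])
            idx += 1
            net = synthetic.generate_network(replace(cfg.synthetic_cfg, seed=net_seed))
            rec_o, rec_f = process_pair(
                net,
                cfg,
                (so, sf),
                subject=f"S{s:02d}",
                eye=eye,
                outdir=outdir if save_intermediates else None,
            )
            records.extend([rec_o, rec_f])

    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    stats_df = df
    if subject_level:
        stats_df = (
            df.groupby(["subject", "modality"], as_index=False)
            .agg({"density_percent": "mean", "dbox": "mean", "r_squared": "mean"})
            .assign(eye="both")
        )
    report = {
        "n_subjects": n_subjects,
        "n_eyes": n_subjects * 2,
        "seed": cfg.seed,
        "unit": "subject" if subject_level else "eye",
        "statistics": _study_stats(stats_df, "octa_like", "fslb_like"),
    }

    if outdir is not None:
        df.to_csv(os.path.join(outdir, "records.csv"), index=False)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        for metric in ("density_percent", "dbox"):
            a = stats_df[stats_df.modality == "octa_like"].sort_values(["subject", "eye"])[metric].to_numpy()
            b = stats_df[stats_df.modality == "fslb_like"].sort_values(["subject", "eye"])[metric].to_numpy()
            stats.plot_bland_altman(
                a, b, os.path.join(outdir, f"bland_altman_{metric}.png"),
                title=f"{metric} (octa_like - fslb_like)",
            )
    report["records"] = records
    return report
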