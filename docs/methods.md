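# Methods

`microvasq` quantifies superficial microvascular density from calibrated
2-D images of the bulbar conjunctiva (or any similar surface plexus),
compares two imaging modalities of the same tissue, and ships a
synthetic phantom generator so the whole chain is testable without
patient data. This note documents the models, the parameters that
matter, the numerical conventions, and what the synthetic results do and
do not show.

## Processing model

Each image carries a physical field of view (FOV, mm); every geometric
operation updates it explicitly. Resampling changes the grid, not the
FOV; cropping scales the FOV by the retained pixel fraction (a 1024-px
image at 8.775 mm cropped to 768 px has FOV 8.775 × 768/1024 =
6.58125 mm, reported to 3 decimals as 6.581 mm).

Two modality profiles feed one shared segmentation chain:

* **Angiography-like** (bright vessels, coarse scanning grid, native
  304 × 304 px over 8.775 × 8.775 mm²): up-sampled bilinearly to
  1024 px, center-cropped to the 768-px working window.
* **Photography-like** (dark vessels, fine grid, native 5184 × 3456 px
  over 15.74 × 10.50 mm²): green-channel grayscale, resized to width
  1024 (height 683), contrast-limited adaptive histogram equalization
  (8 × 8 tiles, clip limit 0.01), black-top-hat background removal
  (disk radius 15 px at the 1024-px scale — larger than any displayed
  vessel half-width), which also flips the image to bright-vessel
  polarity; then the same physical window is cropped and resampled to
  768 px.

The shared chain on the 768-px working grid: global histogram
equalization, Gaussian blur (σ = 4 px, truncated at 4σ, reflect
padding), an FFT bandpass keeping structures between 3 and 40 px,
Otsu binarization, and thinning to 1-px centerlines.

Numerical conventions, fixed for reproducibility:

* *Global equalization* maps level v to
  `round(255·(cdf(v) − cdf(0))/(1 − cdf(0)))` — gray level 0 is the
  anchor, so an image whose histogram is already uniform over 0..255 is
  an exact fixed point; constant images pass through unchanged.
* *Bandpass* is a difference of Gaussians in the frequency domain: a
  structure of size s px is modeled as a Gaussian of σ = s/2, the DC
  gain is exactly zero, inputs are mirror-padded to the next power of
  two, and the output is rescaled linearly to [0, 255] with no
  percentile clipping ("no saturation"). This approximates the behavior
  of the classic interactive FFT bandpass tools; it is validated by its
  measured band selectivity (a period-12 px wave keeps >0.7 of its
  amplitude, a period-200 px wave keeps <0.2), not by bit-exactness to
  any particular program.
* *Otsu* runs on the 256-bin histogram; foreground is strictly above
  the threshold; plateau ties (empty bins between separated modes)
  resolve to the lowest maximizing level. A constant image is a
  degenerate histogram and is rejected rather than guessed at.
* *Thinning* is Lee's medial-axis algorithm. It guarantees the two
  properties the pipeline relies on — strict 1-px thinness (no 2×2
  foreground block) and preservation of the 8-connected component
  count — which the classic two-subiteration parallel scheme does not
  (it can leave 2×2 blocks on staircase boundaries).

## Density readouts

* **Density (%)** = 100 × skeleton pixels / all pixels. Thinning first
  gives every vessel the same weight regardless of caliber.
* **Dbox** = box-counting fractal dimension: the OLS slope of log N(s)
  versus log(1/s), where N(s) counts the s × s boxes (tiled from the
  top-left corner; partial edge boxes included) containing at least one
  skeleton pixel. The default schedule is 15 box sizes in geometric
  progression from 104 px down to 2 px. The r² of the fit is always
  reported so poor fits are visible. A single fixed grid origin is the
  default for determinism; minimizing counts over several origins is
  available (`grid_offsets`). Known-dimension fixtures bound the
  estimator's bias: a full square fits 2.0 and a line 1.0 within 0.05
  (the ceiling in N(s) = ceil(n/s)² flattens the slope slightly below
  the nominal dimension), and a depth-4 Sierpinski carpet (243 px) fits
  log 8/log 3 ≈ 1.893 within 0.05 when the box sizes are powers of 3.

## Comparison statistics

The study design is paired (each eye imaged by both modalities).
With two within-unit levels, repeated-measures ANOVA is identical to
the paired t-test (F = t² on 1, n−1 df), which is how `paired_compare`
reports both. Differences are oriented as angiography-like minus
photography-like. Agreement is summarized by Bland–Altman limits:
mean difference ± 1.96 × sample SD (n−1) of the differences. Pearson
correlations use the exact t-based two-sided p. Eyes are treated as
units, matching the paired design's degrees of freedom; a
`subject_level` option averages the two eyes per subject first for a
conservative alternative. No multiple-testing correction is applied.
Zero difference variance with a nonzero mean difference is reported as
p = 0 with a `degenerate` flag rather than an exception.

## Synthetic phantom model

`generate_network` grows a seeded branching random walk: roots are
stratified over a jittered grid spanning the photographic FOV (a purely
uniform draw leaves empty patches no real conjunctiva has), each tip
advances ~0.15 mm per step with wrapped-normal heading jitter
(SD 0.35 rad), branches with probability 0.04 per step, tapers caliber
by 0.9 per generation, and dies at the FOV border. Defaults (35 roots,
45 steps, calibers 15–80 µm) give ≈2.5–3 mm of centerline per mm² —
the scale of a dense conjunctival plexus — with ~20 % variation across
seeds. Everything is a pure function of (config, seed).

`render_modality` draws each segment as a tube with a Gaussian
cross-section. Two physical attenuation factors act on vessels narrower
than the sampling pitch: the lateral point spread dilutes the peak by
σ_vessel/σ_eff (flux conservation, σ_eff² = σ_vessel² + σ_psf² with a
half-pixel PSF), and the resolution-cell fill fraction
min(width/pitch, 1) scales the signal a cell can register. On the
29 µm angiography pitch a 15 µm capillary therefore renders at roughly
a quarter of full contrast, while the ~3 µm photographic pitch renders
it fully — the mechanism by which a scanning angiograph under-reports
capillary density. Noise models: the angiography-like render uses
mean-preserving multiplicative exponential speckle at contrast 0.3
over a near-black background (0.05) — the regime of an exported en-face
angiogram, where averaging over repeated scans and the axial projection
suppress raw speckle contrast by roughly the square root of the number
of independent voxels — and the photography-like render uses additive
Gaussian noise (σ = 0.02), radial vignetting (strength 0.3) and dark
vessels on a bright background (0.85).

What the phantoms do **not** emulate: motion and blink artifacts,
depth-resolved layering (conjunctiva vs sclera), specular reflections,
flow-speed-dependent decorrelation, vessel tortuosity classes, and any
disease state. Passing tests therefore show that the *pipeline*
recovers and compares densities correctly under controlled conditions;
they do not validate clinical accuracy on patient images.

## Study-scale choices

The synthetic paired study uses 10 subjects × 2 eyes, each eye a fresh
network rendered through both modalities at their full native grids.
Recovery tests run noise-free on a sparser network of wide calibers
(10 roots, 90–120 µm ≥ 3 px on the coarse grid), because caliber
recovery and the merging of adjacent vessels in a dense plexus are
distinct effects and only the former is under test. The
coarse-versus-fine grid comparison is likewise run noise-free to
isolate the sampling mechanism from the noise model.

## Known limitations

* Box-size schedules and grid origins differ between box-counting
  implementations; absolute Dbox values are comparable only within one
  convention.
* The bandpass is a DoG approximation, not a port of any specific
  tool's filter; absolute thresholds downstream may shift slightly
  against other implementations.
* Registration is integer-translation only, by exhaustive normalized
  cross-correlation; both modalities are resampled to a common mm/px
  first, which this assumes is accurate.
* With vessels denser than roughly 4 mm/mm², extracted density
  saturates: the blur merges adjacent vessels and the skeleton
  under-counts length for both modalities.
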