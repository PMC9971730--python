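# Methods

This note documents the models, parameter choices and numerical decisions
behind `giqe`, and what the synthetic test bed does and does not show.

## Motion-blur model

Uniform rectilinear motion of the probe over the exposure integrates the
scene along a line, so the PSF is a normalized line segment of length `L`
pixels at angle `θ` (measured counter-clockwise from the positive x /
column axis, stored modulo 180° since a segment is symmetric under a
half-turn). Discretization: `L` taps of weight `1/L` at integer offsets
`j − ⌊(L−1)/2⌋` along the unit direction, splatted bilinearly onto the
grid and renormalized. Consequences we rely on:

- axis-aligned angles give exactly `L` entries of exactly `1/L`;
- every kernel is a convex combination (unit sum, non-negative), so flat
  fields and mean intensity are preserved;
- `θ = 90°` is a vertical `L`-pixel line — the continuous limit of the
  oblique case, which the piecewise support condition `0 ≤ x ≤ L·cosθ`
  leaves formally undefined.

Filtering is linear shift-invariant correlation with replicate padding
(the boundary treatment is not dictated by the physics; tests compare
interior pixels only). RGB channels are filtered independently.

## The five features

All features operate on Rec.601 luminance `0.299R + 0.587G + 0.114B`
except the chrominance term, which uses the LMN opponent channels
`M = 0.30R + 0.04G − 0.35B`, `N = 0.34R − 0.60G + 0.17B`. Stabilized
similarity means `s(a,b;c) = (2ab + c)/(a² + b² + c)` throughout; the
constants assume intensities on `[0, 255]`:

| constant | default | used in |
|---|---|---|
| `A1` | `0.0026·255² ≈ 169` | gradient similarity |
| `A2` | `0.00073·255² ≈ 47.5` | saliency and chrominance similarity |
| `A3` | `(0.03·255)² ≈ 58.5` | block-contrast statistic |
| `A_pc` | `0.85` | phase-congruency similarity (PC maps live in `[0,1]`) |
| `α, β` | `1` | exponents weighting the similarity terms |

**Phase congruency.** A 4-scale × 4-orientation log-Gabor bank
(octave-spaced wavelengths from 3 px, bandwidth ratio `σ_s/f_rs = 0.55`,
angular spread 0.52 rad, one-sided angular window so responses are
analytic). `PC = Σ_o |Σ_s F_{s,o}| / (Σ_{s,o} |F_{s,o}| + ε)` with
`ε = 10⁻⁴` guarding featureless regions; the resultant length equals the
classical "maximum over reference phase" definition. PC of a constant
image is 0 (log-Gabor filters have zero DC response).

**F_LSF.** Per-pixel `s(PC_r, PC_d; A_pc)^α · s(GM_r, GM_d; A1)^β`, with
GM the `/16`-normalized 3×3 Scharr magnitude, pooled with
`max(PC_r, PC_d)` weighting — the most perceptually informative pixels
dominate the pool.

**F_VSF.** Spectral-residual saliency (computed at a 64-px working width,
squared residual of the log amplitude spectrum under the original phase,
Gaussian-smoothed, min-max normalized to `[0,1]`; a constant image maps to
a uniform 0.5). The three similarities — saliency (maps rescaled by 255 so
`A2` is commensurate), gradient, and the two chrominance channels — are
each mean-pooled first and then multiplied: `F_VS · F_GM^α · F_C^β`.
Grayscale pairs use `F_C = 1`.

**F_LGF.** Both images are decomposed by the log-Gabor bank (defaults:
center frequencies 1/3, 1/6, 1/12, 1/24 cycles/px, 4 orientations); the
feature is the mean over subbands of the mean-pooled amplitude-map
similarity (stabilizer `A1`).

**F_MIF.** Scalar Gaussian-scale-mixture information model: the 3×3 local
variance, block-averaged (block size 4), plays the role of the per-block
signal variance `s_i²`; information is `½ Σ_i log₂(1 + s_i²/ε_m²)` bits
with visual-noise variance `ε_m² = 0.1`. The full-reference feature is the
fidelity ratio `info(dist)/info(ref)` clipped to `(0, 1]`; a reference
with no local information anywhere returns 1 with a logged warning
(nothing to lose). The richer vector-GSM machinery of the
information-fidelity family is deliberately reduced to the scalar case:
it keeps the feature a closed-form expression testable against explicit
determinant arithmetic.

**F_NSF.** Per-image block contrast is the Scharr gradient magnitude at
each block's central pixel. For co-located block pairs,
`R = |f_r − f_d| / max(f_r, f_d)` and `K = A3 / max(f_r, f_d)²` feed
`(2(1−R) + K)/(1 + (1−R)² + K)` (bounded by 1, equal to 1 iff `R = 0`);
blocks where both gradients vanish score 1 (K → ∞ is the natural
regularization of "no contrast to compare"). Pooling is the arithmetic
mean. An alternative reading — defining block contrast itself as a
stabilized within-block similarity in `(0,1]` — makes `K ≥ A3 ≈ 58.5`
dominate the statistic and removes essentially all discrimination, so it
was rejected.

All pooling operators are arithmetic means over pixels, blocks or
subbands.

## Regression ensemble

"Semi-full combination subspace" is implemented as exhaustive enumeration
of feature subsets of size ≥ `min_subset_size` (default 2 → 26 subsets of
the 5 features), one ε-SVR with RBF kernel per subset, unweighted mean
aggregation, output clipped to `[1, 5]`. Features are affinely rescaled to
`[0, 1]` on the training set (RBF kernels need commensurate scales); the
scaler is part of the model. The hyperparameter triple — cost
`H ∈ {1, 10, 100, 1000}`, tube `ε ∈ {0.01, 0.1, 0.5}`, kernel width
`k ∈ {2⁻⁴ … 2²}` — is selected once by 5-fold cross-validated grid search
(RMSE) on the full feature set and shared by all components; per-subset CV
scores are recorded in the model for inspection but no claim about subset
superiority is asserted. Components are stored as their explicit kernel
expansion (support vectors, dual coefficients, bias), so a model
serializes to deterministic JSON: identical data, config and seed give
byte-identical files.

The train/test split is at **source-image granularity** (all 15
distortions of a source on one side, default 60/40), so evaluation is
always on unseen content.

## Synthetic subjective study

The generator emulates the structure of a gastroscopy blur study, not its
clinical content:

- **Sources** (default 256×224, native-scale 1075×935 available by
  config): 1/f-spectrum shading and texture fields, dark-red vascular
  filaments traced as random smooth walks, vignetting, reddish hue.
  Generated images have natural-image-like radial power-spectrum slopes
  (between −1 and −3 on log-log axes) and luminance spread > 5 gray
  levels.
- **Latent quality** depends on blur length only (rotating the blur
  direction does not change diagnostic usability):
  `q(L) = 1 + 4·2^{−(L/15)^{1.5}}`, smooth and strictly decreasing,
  anchored at `q(0) = 5` and `q(15) = 3` — the clinically reported
  boundary between usable and unusable maps to the scale midpoint. The
  exponent 1.5 makes quality fall gently at small L and steeply past the
  boundary, matching how raters describe mild vs. disabling blur.
- **Panel** (15 raters): per-rater bias drawn once from `N(0, 0.2)`,
  score = `round(q + bias + N(0, 0.5))` clipped to 1..5, 2% lapse rate
  (uniform random score) modeling inattention. These defaults produce
  unimodal mid-scale MOS histograms with nonzero interquartile spread on
  mid-quality images.
- **Screening**: the deterministic 1.5·IQR box-plot whisker rule replaces
  physician-led outlier removal, for reproducibility; panels smaller than
  4 are never screened. When a panel concentrates on one value the IQR is
  0 and the rule removes every non-modal score — occasionally more than
  `⌊M/3⌋`; the conservatism of screening therefore holds in distribution
  (vast majority of images within that bound), not per image. Scores are
  screened, never whole images.
- **MOS** is the arithmetic mean of surviving scores.

Everything is a pure function of (config, seed); the benchmark at seed 42
is the package's canonical test bed.

What passing tests on this bed does **not** show: performance on real
endoscopic content (specular highlights, fluid, peristalsis, sensor
noise), on non-uniform or rotational blur, or calibration of the absolute
MOS scale against physician panels. The synthetic study shares only the
*structure* of a clinical database; correlations measured on it
characterize the pipeline's internal consistency, not clinical validity.

## Evaluation protocol

Objective scores are mapped by the five-parameter logistic
`Q(z) = β₁(1/2 − 1/(1 + e^{β₂(z−β₃)})) + β₄z + β₅` fitted by
Levenberg–Marquardt least squares. Initialization: `β₁ = range(MOS)`,
`β₂ = 4/range(objective)` with the sign of the raw correlation,
`β₃ = median(objective)`, `β₄ = 10⁻³`, `β₅ = mean(MOS)`; five jittered
restarts with fixed sub-seeds guard against local minima, and the
exponent argument is clipped to ±500 to keep the optimizer finite.
PLCC and RMSE are computed on mapped scores; SROCC and KROCC on raw
scores (rank statistics are invariant to monotone mappings — the IQA
convention). KROCC is tau-b, tie-corrected, because integer rater panels
produce ties. PSNR is capped at 100 dB for identical images; SSIM is the
standard single-scale form with an 11×11 Gaussian window (σ = 1.5) on
luminance.

## Problem sizes and determinism

Default experiments run the full 70-source × 15-distortion grid at
256×224 resolution; feature extraction caches per-image maps so each
reference is analyzed once for its 15 distorted versions. The complete
pipeline (benchmark synthesis, 1,120 image analyses, grid search,
26-component training, evaluation) completes in a few minutes on one CPU.
Every stochastic stage — scene content, panel biases, rater noise, split,
CV folds — draws from generators seeded by the single run seed.

## Known limitations

- The saliency front end is the parameter-light spectral-residual model;
  learned or biologically detailed saliency models may weight lesions
  differently.
- The information feature's scalar GSM ignores inter-block covariance.
- `F_LGF` discriminates weakly at this resolution (subband amplitudes are
  robust to blur by design — that robustness is the feature's point), so
  it contributes mostly through interactions in the ensemble.
- Blur is simulated, not optically measured; real endoscope blur includes
  rolling-shutter and non-uniform components outside the linear model.
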