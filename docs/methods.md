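# Methods

This note documents the models and procedures implemented in `aggdeblur`,
the choices made where the design was genuinely open, and what the
synthetic-fixture tests do and do not establish.

## Blur model

A motion-blur kernel is derived from a simulated camera trajectory in the
complex plane,

```
z_j = Σ_{k≤j} s_k · e^{iθ_k},   j = 1 … N,
```

with a single intensity parameter `I ∈ [0, 1]`:

- **Step lengths** `s_k ~ Beta(1 + 3I, 3 − 2I) · s_max` with
  `s_max = max_extent / N · (1 + 4I)`.  Higher intensity therefore gives
  both a right-shifted Beta shape and a larger scale — longer average
  steps.
- **Turning angles** start at `θ_0 ~ U(0, 2π)`; increments are
  `U(−πI, +πI)` with probability `0.1·I` of a sign flip (jitter).  At
  `I = 0` the path is exactly straight.
- The path is rescaled (positions and steps jointly, preserving the
  cumulative-sum identity) so `max |z_j| ≤ max_extent`, centred on its
  centroid, splatted with bilinear sub-pixel weights onto a
  `kernel_size²` grid, Gaussian-smoothed (`σ = smoothing_sigma`), and
  renormalized to unit mass.
- Convolution uses reflective padding, so constant images are exact fixed
  points and image means are preserved up to boundary effects.

Defaults: `n_steps = 2000`, `kernel_size = 31`, `smoothing_sigma = 1.0`,
`max_extent = kernel_size/2 − 2`, intended for full-resolution
(≈1920×1080) sources.

**Sampling-density caveat.**  Because `s_max ∝ 1/N`, the expected total
path length is independent of `N` while the per-step displacement shrinks
as `N` grows.  For large `N` at small kernel sizes the high-intensity
walk self-averages into a nearly isotropic blob whose spatial spread barely
depends on intensity — the intensity response of the blur degenerates.
Test and acceptance fixtures therefore sample coarsely (`n_steps = 60` at
`kernel_size = 21` on 64×64 scenes), a regime in which the measured PSF
rms spread — and the perceptual damage — increase monotonically with
intensity.  Users synthesizing blur at other scales should keep the
per-step displacement (`max_extent/N`) well above the smoothing width.

## Generator

FPN-style encoder–decoder built from Ghost convolutions:

- Stem 3×3 conv to 16 channels; four encoding stages of two Ghost blocks
  each (first block stride 2), widths 24/40/80/160 → total stride 16.
  Inputs are reflect-padded to a multiple of 16 and cropped back.
- Ghost block: primary convolution (3×3) producing half the output
  channels, depthwise 3×3 "cheap" convolution producing the other half,
  concatenation, squeeze-and-excitation (reduction 4, sigmoid gate),
  channel crop.  Unit SE excitation reduces the block exactly to a plain
  Ghost module.
- 1×1 laterals: 64 channels on the stem map, 128 on the four stage maps.
  Three top-down fusions (nearest ×2 upsample + add), each refined by an
  attention-Ghost + GHIN pair.
- GHIN: the first ⌊C/2⌋ channels are standardized per sample/channel over
  space (`ε = 1e-5`, denominator `√(σ²+ε)`); gate `S = γ·α·x̂ + β`
  multiplies the **raw** half as `y = (1+S)·x`; the remaining channels are
  untouched.  The printed equation multiplies raw `x`; the surrounding
  prose says the normalized channels — the equation is implemented.
  Initialization α=1, γ=0, β=0 makes the module the exact identity.
- Per-level two-layer Ghost heads to 64 channels, upsampled to the
  shallowest pyramid level and concatenated to 256 channels; one
  attention-Ghost+GHIN module keeping 256 channels, upsample, a second
  reducing to 64, addition of the full-resolution 64-channel stem lateral,
  a Ghost projection, a 3×3 conv to 3 channels, residual addition with the
  input and a clamp to [0, 1].  With the final conv zeroed the generator is
  the identity; at initialization it is near-identity (final weights scaled
  by 1e-2), which is what makes short fine-tuning runs stable.

The full-width configuration has 1,477,259 trainable parameters (≈1.48 M,
within 5% of the published 1.53 M count for this architecture family).
Where the published description leaves kernel sizes and decoder widths
open, choices were made among standard Ghost/FPN conventions so that the
reconstruction reproduces that published parameter count; the per-block
accounting is verified against closed-form formulas in the tests.

Discriminators: two three-layer patch critics (4×4 convs, widths 64/128,
leaky-ReLU 0.2) — a global critic on the 2×-average-pooled image and a
local critic at native resolution.  These follow common image-restoration
GAN practice; the source architecture defers their details to prior work.

## Training

- `L_content = 0.7·L_p + 0.3·L_1`; `L_p` is the mean squared distance in
  the feature space of a pluggable extractor ("Euclidean distance" read as
  mean squared L2), `L_1` the mean absolute pixel error.  The default
  extractor is the identity (no pretrained backbone is shipped); any
  callable on NCHW tensors can be substituted.
- Relativistic average least-squares adversarial loss,
  `L_D = ½[E(D_r − E D_f − 1)² + E(D_f − E D_r + 1)²]`, generator loss
  with roles swapped, summed over the two critics.  The averaged
  (relativistic-average) form is assumed; the losses depend only on score
  differences.
- `L_G = L_content + 0.005·L_adv`; Adam (default moments, no weight decay,
  no gradient clipping); 1:1 critic/generator updates; learning rate held
  at `lr_init` through `decay_start_epoch`, then linear to `lr_final` at
  the final epoch.  Published schedule: 1e-4 → 1e-6 from epoch 10 of 200,
  batch 4.
- All layers run on an in-repo numpy reverse-mode autodiff engine
  (float32, im2col convolutions); gradients are validated against central
  finite differences in the test suite.  This replaces a deep-learning
  framework, which is unavailable in the target environment.

**Scaled-down training world.**  CPU-scale verification fits reduced-width
networks (stage widths 8/12/16/24/32, critics of width 16) on 200
synthetic 64×64 pairs at intensity 0.5 for 5 epochs, identity perceptual
extractor, lr 1e-3 linearly decayed to 1e-4 from epoch 1 — the published
schedule rescaled to a 40× shorter run.  Over three seeds the median
epoch-5 content loss falls below epoch 1 and the median composite IQA of
restored held-out images exceeds that of their blurred inputs.  This
establishes that the architecture + objective learn in the right
direction at desk scale; it says nothing about full-scale restoration
quality (PSNR/SSIM of the published experiments require the original
dataset and GPU training and are out of scope).

## Image quality assessment

Seven full-reference metrics; inputs are HWC RGB in [0, 1].

- **MS-SSIM**: standard five-scale form (weights 0.0448/0.2856/0.3001/
  0.2363/0.1333), 11×11 Gaussian window (σ 1.5) that shrinks on scales
  smaller than the window so small fixtures remain scorable.
- **GMSD**: Prewitt gradient-magnitude similarity deviation on
  2×-downsampled luma, stabilizer rescaled to the unit intensity range.
- **FSIM**: phase congruency (log-Gabor quadrature filters, 4 scales × 4
  orientations, median-based noise threshold) combined with Scharr
  gradient similarity on a [0, 255] luma scale, pooled by maximum phase
  congruency.
- **VSI**: SDSP saliency (band-passed CIELAB frequency prior × center
  prior × warm-color prior), Scharr gradients and LMN color-opponent
  chrominance with the published constants.
- **NLPD**: Laplacian pyramid with local divisive normalization.  The
  binomial pyramid filter and a 5×5 amplitude pool stand in for the
  original optimized normalization filters, which are not reproduced; the
  metric retains the zero-at-identity and blur-monotone properties used
  here.
- **DISTS / LPIPS** need pretrained feature backbones: they are backend
  plugins (`iqa.register_backend`) and raise `MetricUnavailableError`
  when absent.  Tests mock them; no silent fallback exists.

Normalization to [0, 1] (1 = best): similarity metrics are clipped;
distance metrics map as `1 − clip(raw/cap)` with caps LPIPS 1.0, DISTS
1.0, GMSD 0.35, NLPD 1.0.  The source material does not state its
normalization for distance metrics — these caps are a reconstruction and
are configuration-exposed; published score-table rows are therefore used
only through the composite-mean arithmetic, never as end-to-end metric
targets.  The composite is the arithmetic mean of the seven normalized
scores; severity bands are left-closed ([0,0.6) severe, [0.6,0.7)
moderate, [0.7,0.8) mild, [0.8,1] sharp).  Group statistics: per-group
means with 95% t-distribution confidence intervals and two-sided paired
t-tests; zero-variance differences are reported as degenerate rather than
as p = 0.

## Routing

Sharpness is the variance of the 4-neighbour Laplacian of BT.601 luma at
full resolution (reflective border).  Dispatch is strict: `L < T` →
deblur, `L ≥ T` → bypass.  `T` is scene-dependent; calibration offers a
sharp-only mode (a low percentile of reference sharpness — note that by
construction about that fraction of comparable sharp images will then be
deblurred unnecessarily) and a two-sample mode placing `T` at the
geometric midpoint between the blurred maximum and the sharp minimum,
which separates the batches exactly whenever their distributions do not
overlap.

## Detection reporting

F1 = 2PR/(P+R) (0 with a warning when both are zero), FNR = 1 − recall,
relative change = 100·(after − before)/before.  Reports recompute F1/FNR
from precision and recall and flag stored cells deviating by more than
0.005 — the largest effect 3-decimal rounding can produce is ≈0.002, so
the tolerance separates rounding noise from genuine inconsistencies (the
packaged reference table contains one such row, which is flagged and left
untouched).  Percentages are printed to 1 decimal, proportions to 3.

## Synthetic scenes

`generate_synthetic_scene` emulates the statistics that matter for these
pipelines — band-passed background texture, ≥3 shaded warm-hued discs
(fruit analogue), elongated dark strokes (branches), one high-frequency
binary block (signage) — deterministically from a seed.  It does not
emulate photographic noise, depth-of-field, illumination fields or real
color distributions; green tests on fixtures establish algorithmic
correctness and direction-of-effect, not field performance.

## Known limitations

- No pretrained perceptual/learned-metric backbones are bundled: `L_p`
  defaults to pixel space and DISTS/LPIPS require user-supplied backends.
- The numpy engine is single-threaded-BLAS CPU code; full-width training
  at photographic resolution is out of its intended range.
- NLPD deviates from the published optimized normalization filters (see
  above); its absolute values should not be compared against other
  implementations, only used through the calibrated normalization.
- The blur model's intensity response requires a resolvable per-step
  displacement (see the sampling-density caveat).
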