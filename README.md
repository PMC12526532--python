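# aggdeblur

Motion blur is a dominant failure mode for fruit detection in orchards:
camera shake, wind-moved foliage and vehicle vibration smear edges and
textures, and detectors trained on sharp imagery miss heavily blurred
fruit.  `aggdeblur` is a self-contained toolkit for studying and mitigating
this problem.  It provides:

- **Trajectory-based blur synthesis.**  A camera path is simulated as a
  random walk in the complex plane, `z_j = Σ_{k≤j} s_k · e^{iθ_k}`, where a
  single *blur intensity* parameter in [0, 1] controls the step-length
  distribution (Beta) and the turning-angle dispersion.  The path is
  Gaussian-smoothed and rasterized into a unit-mass point spread function
  (PSF) that is convolved with each RGB channel of a sharp image, giving
  paired sharp/blurred datasets with 8:1:1 train/val/test splits.
- **A lightweight deblurring GAN.**  The generator is a feature-pyramid
  network over a Ghost-convolution backbone (stage widths 16/24/40/80/160),
  with each top-down fusion refined by an *attention-Ghost* block
  (Ghost convolution + squeeze-and-excitation before channel cropping) and
  a *gated half-instance normalization* (GHIN) module:
  the first half of the channels is standardized per sample and channel,
  turned into a gate `S = γ·α·x̂ + β`, applied as `y = (1+S)·x`, and
  concatenated with the untouched second half.  At the published
  initialization (α=1, γ=0, β=0) GHIN is exactly the identity.  The output
  is a residual added back onto the input image.  The full-width generator
  has ≈1.48 M trainable parameters.  Adversarial supervision comes from a
  double-scale critic pair (global half-resolution + local patch).
- **Training objective.**  `L_G = L_content + 0.005·L_adv` with
  `L_content = 0.7·L_p + 0.3·L_1` (perceptual feature distance + mean
  absolute pixel error) and a relativistic average least-squares
  adversarial loss; Adam with a linear learning-rate decay after a warm
  hold.  Because no pretrained perceptual backbone ships with this package,
  the feature extractor is pluggable and defaults to the identity.
- **Composite image-quality scoring.**  Seven full-reference metrics
  (DISTS, LPIPS, VSI, MS-SSIM, FSIM, GMSD, NLPD), each normalized to
  [0, 1] with 1 = best, averaged into a composite score `S` and mapped to
  blur-severity bands: `S < 0.6` severe, `0.6–0.7` moderate, `0.7–0.8`
  mild, `≥ 0.8` sharp.  MS-SSIM, FSIM, VSI, GMSD and NLPD are implemented
  natively; DISTS and LPIPS need a learned-feature backend and raise a
  clear error when none is registered.  Group comparisons use 95%
  t-confidence intervals and paired t-tests.
- **Blur-aware routing.**  The variance of the Laplacian, `L`, is compared
  to a threshold `T`: images with `L < T` are deblurred, the rest bypass
  straight to the downstream consumer.
- **Detection reporting.**  F1 (`2PR/(P+R)`), false-negative rate
  (`1 − recall`) and relative-change percentages between sharp / blurred /
  restored detection conditions, with consistency checks against the
  stored table values.

Everything runs on plain numpy/scipy — the network layers include their own
small reverse-mode autodiff engine, so no deep-learning framework is
required.  Synthetic orchard-like scenes (textured background, disc-shaped
fruit analogues, branch strokes, a high-frequency signage block) make every
stage testable without any image downloads.

## Worked example

```python
import numpy as np
import aggdeblur as ad
from aggdeblur.iqa import score_pair, register_backend

# learned metrics need a pretrained backend; mock them as perfect here
register_backend("DISTS", lambda r, t: 0.0)
register_backend("LPIPS", lambda r, t: 0.0)

scene = ad.generate_synthetic_scene(64, 64, seed=0)
spec = ad.BlurSpec(intensity=0.5, n_steps=60, kernel_size=21, seed=7)
blurred = ad.blur_image(scene, spec)

report = score_pair(scene, blurred)
print(f"composite S = {report.composite:.3f} ({report.severity})")
print(f"sharp L = {ad.laplacian_variance(scene):.4f}, "
      f"blurred L = {ad.laplacian_variance(blurred):.5f}")
```

prints

```
composite S = 0.854 (sharp)
sharp L = 0.0326, blurred L = 0.00026
```

The composite score of the blurred scene drops below 1 (on these small,
high-contrast fixtures moderate blur still scores in the high band — on
full-resolution photographs the same blur scores far lower), and the
Laplacian variance collapses by two orders of magnitude, which is the signal the
router uses: with a threshold calibrated between the two distributions,
`ad.route(blurred, T).route == "deblur"` and sharp frames bypass.

Training follows a statsmodels-like pattern — a model object built from
data whose `fit()` returns a results object:

```python
pairs = [(ad.blur_image(s, ad.BlurSpec(intensity=0.5, n_steps=60, seed=i)), s)
         for i, s in enumerate(ad.generate_synthetic_scene(64, 64, seed=i)
                               for i in range(40))]
model = ad.AggDeblurGAN(pairs, generator_config=ad.TINY_CONFIG)
results = model.fit(ad.TrainConfig(lr_init=1e-3, lr_final=1e-4,
                                   decay_start_epoch=1, total_epochs=5,
                                   batch_size=4, seed=0))
print(results.summary())
restored = results.restore(pairs[0][0])
```

A `click` CLI wraps the same functionality:
`aggdeblur synth | train | deblur | score | route | report`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the composite IQA scores obtained by averaging
the seven per-metric mean scores of the packaged reference score table
(restored and unrestored-blurred rows), and the trainable-parameter count
of the full-width generator in millions, writing them as JSON.
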