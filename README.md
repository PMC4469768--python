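# rgfscm

Multimodal grayscale image fusion for co-registered medical-style image
pairs (CT/MRI, ultrasound/SPECT, T1/T2), built from two ingredients:

* a **rolling guidance filter (RGF)** that separates image structure by
  spatial scale — a Gaussian pass removes structures below σ_s, then
  iterated joint bilateral passes restore the large-scale edges — used here
  to extract each source's saliency;
* a **spiking cortical model (SCM)**, a simplified pulse-coupled neural
  network whose per-pixel firing counts, driven by the normalised RGF
  coefficients, score that saliency.

Different modalities see complementary anatomy (CT renders bone, MR renders
soft tissue); pixel-level fusion combines them into a single image for
diagnosis and treatment planning. The per-pixel rule is deliberately
simple: whichever source's neurons fired more wins that pixel.

## Method

For sources A, B on [0, 1], with S the normalised RGF coefficients, each
SCM neuron evolves from rest as

    U(n) = f·U(n−1) + S ⊙ (W ⊛ Y(n−1)) + S        internal activity
    E(n) = g·E(n−1) + h·Y(n−1)                     dynamic threshold
    Y(n) = [U(n) > E(n)]                           pulse
    T(n) = T(n−1) + Y(n)                           firing count

with attenuation f = 0.8, g = 0.7, 3×3 linking kernel W, n = 40
iterations. The threshold magnitude h is **self-adaptive**: the average of
the source means minus one third of the average source standard deviation,
evaluated on the 8-bit gray scale, so the model needs no per-modality
tuning. The fused image is, per pixel, with d = T_A − T_B and T_th = 1:

    F = A         if d > T_th
    F = (A+B)/2   if d = T_th
    F = B         otherwise

Quality metrics included: fusion mutual information MI = I(A;F) + I(B;F);
the Sobel-based edge-preservation triple Q^AB/F (transferred), L^AB/F
(lost), N^AB/F (artifacts), which partitions unity; and source-averaged
PSNR, plus a Gaussian-noise robustness sweep. Ablation variants (raw
stimuli and/or constant h: `SCM`, `SCM-A`, `RGF-SCM-C`) isolate the
contribution of each ingredient.

## Worked example

No clinical images ship with the package; a deterministic phantom generator
produces registered complementary pairs (a bone-like image with a bright
elliptical rim and compact inclusions; a tissue-like image with smooth
blobs and fine texture).

```python
from rgfscm import (FusionConfig, PhantomSpec, adaptive_h, fuse_pair,
                    make_phantom_pair, metrics_report)

a, b = make_phantom_pair(PhantomSpec(seed=7))      # 128x128 registered pair
config = FusionConfig()                            # reference defaults
fused = fuse_pair(a, b, config)
report = metrics_report(a, b, fused)

print(f"adaptive h = {adaptive_h([a, b], config.h_variant):.2f}")
for name, value in report.to_dict().items():
    print(f"{name:>8s} = {value:.4f}")
```

prints

```
adaptive h = 39.75
      mi = 5.5424
   q_abf = 0.8332
   l_abf = 0.1310
   n_abf = 0.0358
psnr_avg = 13.9667
```

Reading: 5.54 bits of source information reach the fused image; 83 % of the
sources' edge information is preserved, 13 % is lost and 3.6 % of the fused
edges are supported by neither source (q + l + n = 1); the averaged PSNR
against the two (mutually different) sources is 14 dB — a hard per-pixel
selection necessarily differs from whichever source it did not pick, so
this number is meaningful in *comparisons*, e.g. across noise levels.

The same pipeline from the shell:

```sh
rgfscm phantom --seed 7 --out-a a.png --out-b b.png
rgfscm fuse a.png b.png -o fused.png --metrics-csv metrics.csv
rgfscm noise-sweep a.png b.png --levels 5,15,25,35,45 --seed 1 --csv sweep.csv
rgfscm ablation a.png b.png --variant SCM-A -o ablation.png
```

Every command logs its fully resolved parameter set to stderr; a JSON/YAML
file via `--config` overrides any default.

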