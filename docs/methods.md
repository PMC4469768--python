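# Methods

This note documents the models implemented in `rgfscm`, the parameter
choices and their rationale, the numerical conventions, and the limits of
what the synthetic experiments demonstrate.

## Rolling guidance filter

The filter runs in two stages on a [0, 1] grayscale image I:

1. **Small-structure removal.** A windowed Gaussian
   `G(p) = (1/K_p) Σ_{q∈N(p)} exp(−‖p−q‖²/2σ_s²) I(q)`,
   where N(p) is the square window of half-width r centred at p and K_p
   normalises the weights over that window.
2. **Edge recovery.** Iterated joint bilateral filtering: with J¹ = G,
   `J^{t+1}(p) = (1/K_p) Σ_q exp(−‖p−q‖²/2σ_s² − (J^t(p)−J^t(q))²/2σ_r²) I(q)`.
   The range weights always come from the current iterate J^t (the guide);
   the averaged values always come from the original input I. A constant
   guide makes all range weights equal, so the first stage is just the
   second one started from a constant image — a property the tests exploit.

Structures smaller than σ_s cannot survive stage 1 and, lacking support in
the guide, are never recovered; large edges sharpen back over a few
iterations.

**Parameters.** σ_s = 1.2 px, σ_r = 0.05 (normalised intensity),
4 bilateral passes — the reference operating point for the fusion task.
Window radius defaults to ⌈3σ_s⌉, covering ≥ 99.7 % of the Gaussian mass;
it is configurable, as is whether the Gaussian pass counts toward the
iteration budget (`count_gaussian_pass`, for compatibility with the other
iteration-counting convention).

**Numerics.** At borders the window is truncated and K_p recomputed over
in-bounds pixels only — no padding, so no invented intensities, and
constant images are exact fixpoints. Internally both filters smooth the
deviation from the image mean and add the mean back; this is algebraically
the same weighted average but makes the constant-fixpoint property hold
bit-exactly in floating point. Outputs are convex combinations of input
pixels, so the output range never exceeds the input range (up to last-ulp
rounding).

## Spiking cortical model

One neuron per pixel, iterated n = 40 times from the rest state
U = E = Y = T = 0:

    U(n) = f·U(n−1) + S ⊙ (W ⊛ Y(n−1)) + S
    E(n) = g·E(n−1) + h·Y(n−1)
    Y(n) = [U(n) > E(n)]
    T(n) = T(n−1) + Y(n)

* f = 0.8, g = 0.7: attenuation of activity and threshold per iteration.
* W: fixed 3×3 linking kernel (0.1409 edge-adjacent, 0.1091 diagonal, zero
  centre — no self-link), applied as correlation; W is symmetric so the
  correlation/convolution distinction is moot. Out-of-bounds neighbours
  contribute nothing (zero padding): a nonexistent neuron cannot pulse.
  This breaks exact spatial constancy in the one-pixel border ring for
  constant stimuli, which is why constancy is asserted on the interior.
* Update order within a step: threshold decay/recoil uses the *previous*
  pulses Y(n−1), then the new activity is formed, then the new pulses are
  emitted and counted. E(n) depending on Y(n−1) rather than Y(n) is
  implemented as specified for this model variant.
* Firing condition: U > E. Written as a sigmoid of U − E this is the
  conventional negative-exponent form; the opposite sign (fire when U < E)
  is kept behind `firing_rule="inverted"` for fidelity experiments, but
  under it a rested network with positive stimulus never fires and every
  count is zero, which collapses any count-based fusion rule.

### The adaptive threshold magnitude

`adaptive_h` sets h from the sources being fused:
`h = (1/m) Σ_i mean(I_i) − (1/3)(1/m) Σ_i std(I_i)` (population standard
deviation). Three scale readings are selectable:

* `"average"` — the statistics on [0, 1] intensities (h ≈ 0.1–0.5);
* `"sum"` — the same without the 1/m factors;
* `"average_gray"` — the same statistics on the 8-bit gray scale
  (× 255, h ≈ tens). **This is the pipeline default.**

The default matters and was chosen deliberately. The internal activity of
a sustained-firing neuron accumulates to roughly S(1 + ΣW)/(1−f) ≈ 10·S,
while the threshold of a firing neuron relaxes toward h/(1−g) ≈ 3.3·h.
With h on the [0, 1] scale (≈ 0.16 on the default phantom) every neuron
with S ≳ 0.05 out-runs its threshold and fires on *every* iteration: the
fire-count map saturates at n_iters almost everywhere, carries no saliency,
and the decision rule degenerates (measured on the default phantom: 99 % of
pixels fall to the "otherwise" branch and the fused image drops the bone
rim entirely, Q^AB/F = 0.25). With h on the gray scale (≈ 40 there, the
same order as the classical threshold magnitude ≈ 20 used with this model
on unit-range stimuli) neurons refire with a period set by their stimulus
strength, counts grade cleanly with saliency, the decision map splits
22 % / 3 % / 74 %, and the quality metrics land where a working fusion
method should (Q^AB/F = 0.83, L^AB/F = 0.13, MI = 5.5 bits on the default
phantom). The constant-h ablations default to h = 20 for the same reason.

## Fusion pipeline

`fuse_pair(A, B)`: RGF both sources → min–max normalise each coefficient
map to [0, 1] (a flat map goes to 0.5: any constant stimulus would do, the
midpoint avoids both never-firing and saturation) → run one SCM per source
with the shared adaptive h → per pixel, with d = T_A − T_B and T_th = 1,
take A if d > T_th, the average if d = T_th, else B.

The rule is implemented in its **signed** form, which is asymmetric: ties
and negative differences both go to B, so swapping the inputs can change
the output (tested, not hidden). A symmetric variant — decide on |d|,
average inside the band |d| ≤ T_th — is available via
`decision="symmetric"`. Counts are integers, so the equality branch is
well-posed for integer T_th and simply empty otherwise. Consequences that
the test suite pins down: fusing an image with itself returns it bit-exactly
(all differences are 0, the "otherwise" branch returns B = A); every fused
pixel is A's pixel, B's pixel or their average, so F stays within
[min(A,B), max(A,B)] elementwise; the three branch masks partition the
image; the pipeline is a pure function.

Inputs must be co-registered, same-size, single-channel and on [0, 1];
registration is upstream of this package.

## Quality metrics

* **MI** = I(A;F) + I(B;F) in bits, from 256-bin joint histograms on
  [0, 1] (configurable; 256 matches 8-bit provenance).
* **Q^AB/F / L^AB/F / N^AB/F**: Sobel gradient strength g and orientation
  α (folded to [−π/2, π/2)) are computed for A, B, F. Relative strength is
  min/max ratio, relative orientation 1 − |Δα|/(π/2); each is mapped
  through a sigmoid Γ/(1 + e^{κ(x−σ)}) with the published standard
  constants (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879, κ_α = −22,
  σ_α = 0.8), and their product Q^AF is averaged over pixels with
  edge-strength weights w = g. Several loss/artifact decompositions of this
  family exist; the one implemented routes each pixel's complementary
  information (1 − Q) to **artifact** where the fused gradient exceeds both
  source gradients and to **loss** elsewhere, which makes Q + L + N = 1
  exactly — the unity partition is the selection criterion and is enforced
  by test. Degenerate cases: both gradients zero → preservation counts as
  perfect; a source's zero-gradient pixel carries zero weight; fully
  edgeless inputs report (1, 0, 0).
* **PSNR**, peak 1.0 on normalised images, averaged over the two sources;
  identical images report +inf.

## Noise-robustness experiment

Zero-mean Gaussian noise is added independently to both sources, the noisy
pair is fused, and PSNR is measured against the *clean* sources. Noise
levels are σ in 8-bit gray levels (level 25 → σ = 25/255), the common
convention in this literature; a literal-variance reading
(`level_is_variance=True`) takes σ = √level. Noisy images are clipped to
[0, 1] before fusion — the only clipping in the pipeline. The seed schedule
derives one independent stream per (level, replicate, source) cell from a
single master seed, so tables are exactly reproducible.

The packaged experiment (acceptance test and `scripts/acceptance.py`) runs
levels {5, 15, 25, 35, 45} × 10 replicates on a 128×128 phantom — sizes
chosen to keep the full suite comfortably interactive while leaving the
replicate means stable — and checks the qualitative trend: mean PSNR of the
full pipeline decays monotonically with noise, and at the two heaviest
levels the saliency-filtered pipeline beats the raw-stimulus SCM variant
(the RGF stage denoises the stimulus, so the decision map stays coherent
where raw-stimulus decisions become noise-driven).

## Synthetic phantoms

`make_phantom_pair` emulates the *premise* of multimodal fusion: one
source carries large-scale high-intensity structure (elliptical rim,
compact inclusions) with a weakly varying interior, the other smooth
low-frequency blobs plus fine texture well below `structure_scale`, inside
the same geometry. Both are deterministic given a seed. What it does not
model: scanner noise statistics, partial-volume effects, bias fields,
anatomy, or inter-modality intensity relationships of real CT/MR/SPECT.
Phantom results therefore demonstrate that the mechanism works (scale
separation, saliency scoring, complementary transfer) — not clinical
performance, and no clinical benchmark values are claimed or reproduced
here.

## Known limitations

* Pairwise fusion only; no registration; 2-D single-channel images only.
* The signed decision rule's asymmetry is faithful to the method as
  specified but means A/B ordering is semantically meaningful.
* The bilateral stage is the exact O(r²) windowed sum, not an accelerated
  approximation; at the default radius 4 this is fast for typical medical
  image sizes but scales quadratically in σ_s.
* The edge-preservation triple depends on the chosen Sobel boundary
  handling (symmetric reflection); values are comparable within this
  package, as with any implementation of this metric family.
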