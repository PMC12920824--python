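# Methods

`thermoclass` classifies single-channel breast thermograms into four lesion
classes (DCIS, ILC, angiosarcoma, phyllodes tumor) with a pipeline of
equation-level image conditioning, keypoint/texture feature extraction, a
progressive residual feature network with a multi-class SVM head trained by
an in-package Adam optimizer, and a stratified cross-validation harness.
Because clinical thermogram databases are not redistributable, the package
ships a phantom generator that produces labeled synthetic thermograms with
ground truth; every stage is exercised against it.

## Phantom model

A phantom is

    I(x, y) = b + G·u(x, y) + Σ_j δ_j · exp(−r_j(x,y)² / 2s_j²) + ε(x, y),

clipped to [0, 1]: a baseline `b` (default 0.30), a linear ramp of
edge-to-edge span `G` (`background_gradient`, default 0.1 intensity units)
in a seeded random direction, `n` radially symmetric Gaussian hot spots of
radius `s_j` (pixels) and peak elevation `δ_j` (intensity units), and
i.i.d. Gaussian pixel noise of standard deviation `noise_sd` (default
0.01).  This emulates the gross structure of an infrared breast scan — a
smooth surface-temperature field with localized warm anomalies — and
deliberately omits anatomy-shaped contours, bio-heat (Pennes) physics, and
camera optics.  Consequences for interpretation: passing tests demonstrate
that the pipeline recovers count/size/contrast signatures under realistic
noise, not that it classifies clinical lesion types.

Ground truth: alongside each image the generator emits a mask of hotspot
*cores*, the region where a bump's elevation exceeds 75% of its peak.  The
75% level (rather than the conventional half-maximum) is deliberate: for a
Gaussian profile, area concentrates near the rim, so a half-maximum disk
is dominated by pixels barely `δ/2` above background and a
`background + 5·noise_sd` detection threshold could never recover 90% of
it even at `δ = 10·noise_sd`; the core mask makes detection-recall a
well-posed contract.  The RNG draw order is fixed (background direction,
then hotspots, then noise), so the clean background of any phantom can be
regenerated exactly by re-running its seed with zero hotspots and noise.

Class signatures are encoded as per-class priors over (count, radius,
elevation) — see `CLASS_PRIORS`:

| class          | hotspots | radius (px) | elevation δ |
|----------------|----------|-------------|-------------|
| DCIS           | 1        | 4–6         | 0.18–0.26   |
| ILC            | 3–4      | 3–4.5       | 0.28–0.36   |
| Angiosarcoma   | 2–3      | 10–14       | 0.40–0.48   |
| PhyllodesTumor | 7–9      | 2–3         | 0.50–0.60   |

These priors are an artifact of the generator, chosen once so that the
four classes are well separated in count, scale and contrast
simultaneously; no claim is made that real lesion classes have these
thermal signatures (the literature does not characterize them).

## Conditioning chain

1. **Grayscale** (for RGB input): BT.601 luma weights (0.299, 0.587,
   0.114) — green weighted highest.  All intensities are normalized to
   [0, 1] at load so every scale parameter below is in normalized units.
2. **Histogram equalization**: `p_i = n_i/N` over 256 bins,
   `cdf(i) = Σ_{j≤i} p_j`, pixel → cdf(bin(pixel)).
3. **Double-exponential remap (DEHE)**: the equalized value `u` is pushed
   through `g(u) = (1 − e^{−2αu}) / (2(1 − e^{−α}))` for `u ≤ ½`, mirrored
   as `g(u) = 1 − g(1 − u)` above; `g(0)=0`, `g(½)=½`, `g(1)=1`, monotone
   for all `α > 0` (default α = 2).  The curve is steepest at both ends,
   stretching dark and bright tails at once.
4. **Anisotropic (Perona–Malik) diffusion**: `∂I/∂t = ∇·(c(|∇I|)∇I)` with
   conductance `c(g) = exp(−g²/k²)`, explicit 4-neighbor scheme with
   per-direction conductance on directional differences, reflecting
   (zero-flux) borders.  Defaults `k = 0.1` (normalized intensity),
   `dt = 0.2`, 15 iterations; `dt ≤ ¼` is enforced — it makes each update
   a convex combination, giving the discrete extremum principle, and the
   symmetric pair conductance conserves total intensity exactly.
5. **Proportionate adaptive filter** (range-only bilateral):
   `W(u,v) = exp(−(I(u,v) − I(x,y))²/(2σ²))`, output `ΣWI/ΣW` over a
   (2r+1)² reflected window; defaults σ = 0.1, r = 1.  The center weight
   is always 1, so the denominator never vanishes and every output lies
   within its neighborhood's range.

**Conditioning for classification vs enhancement.**  The full chain with
DEHE is the default of `preprocess()` and is what the `preprocess` CLI
applies.  The *classification* pipeline, however, conditions with
diffusion + adaptive filtering only (`equalization="none"`): any per-image
rank equalization maps every image onto the same output intensity
distribution by construction, which is exactly what a display enhancement
should do and exactly what a classifier should not be fed, because the
absolute thermal contrast (δ) is one of the class signatures.  Both modes
are one config switch apart.

## Features

* **Keypoints**: difference-of-Gaussians pyramid (default 3 octaves,
  3 scales per octave, base σ = 1.6), 26-neighbor extrema above a contrast
  threshold (default 0.02), principal-curvature edge rejection (ratio 10),
  quadratic sub-pixel refinement, orientation from the peak of a
  Gaussian-weighted 36-bin gradient-orientation histogram.
* **Descriptors**, two kinds: (i) *histogram* — the patch is resampled on
  a grid rotated by the keypoint orientation (spacing ∝ scale), gradient
  orientations are histogrammed per subregion and concatenated,
  L2-normalized.  The default layout is 8 subregions (2×4) of 8
  orientation bins → 64 values; the conventional 4×4×8 = 128 layout is
  `n_subregions=16`.  (ii) *binary* — an integer code
  `Σ 2^i·[I(p_i) > I(q_i)]` over `n ≤ 30` offset pairs (default pairs:
  points at angles 2πi/n versus the center).  The histogram kind is the
  pipeline default; degenerate (gradient-free) patches are returned as
  zeros with an explicit flag.
* **Texture**: gray-level co-occurrence matrices at 32 levels, distance 1,
  four angles {0°, 45°, 90°, 135°}, symmetric, normalized; the correlation
  statistic `(Σ i·j·p(i,j) − μ_x μ_y)/(σ_x σ_y)` from the marginals,
  averaged over angles.  A constant image has zero marginal variance and
  is reported as undefined, never as 0.
* **First-order statistics**: population mean/variance/std/max/min,
  Shannon entropy (bits) of the 256-bin histogram, skewness and *excess*
  kurtosis (normal → 0); both are undefined for constant images.

Per-keypoint descriptors become a per-image summary by averaging the
descriptors of the strongest 25 keypoints — the aggregation is an artifact
decision, there being no canonical choice.

## Classifier

**Architecture.**  Input is the conditioned image local-mean-pooled to
16×16 (configurable); the pooled patch, not the full frame, keeps one CPU
fold in tens of seconds.  Two parallel paths of residual blocks
`H(x) = F(x, W) + x` process it:

* *progressive path*: 3 conv residual blocks with strictly increasing
  channel counts (8 → 12 → 16), each downsampling by stride 2;
* *backbone path*: 4 stages × 2 blocks (channels 8, 8, 16, 16), stride 2
  at each stage entry — a reduced, configurable stand-in for a deep
  hierarchical residual backbone.

`F` is conv3×3 → ReLU → conv3×3; the skip is the identity, or a strided
1×1 projection when shape changes.  Each path ends in global average *and*
global max pooling per channel (means capture count/area statistics, maxes
capture peak contrast), and the two paths are fused by concatenation
(default) or summation → 64-dimensional embedding.  A `dense` block flavor
(two linear maps) exposes the same residual algebra on flat vectors.

**Training.**  A linear scoring head is attached and the stack is trained
full-batch with a multi-class hinge surrogate
`mean_i Σ_{c≠y_i} max(0, 1 + s_c − s_{y_i})` plus L2 weight decay (1e-3),
using the in-package Adam optimizer: `m_t = β₁m_{t−1} + (1−β₁)g_t`,
`v_t = β₂v_{t−1} + (1−β₂)g_t²`, bias-corrected `m̂ = m/(1−β₁ᵗ)`,
`v̂ = v/(1−β₂ᵗ)`, update `θ ← θ − α·m̂/(√v̂ + ε)` with α = 0.01, β₁ = 0.9,
β₂ = 0.999, ε = 1e-8, 60 epochs.  He-scaled seeded initialization; the
whole run is a pure function of (data, config, seed), so repeated runs are
bit-identical.  The margin head cannot be trained through the SVM dual, so
the surrogate head is discarded after training and the SVM is fit on
frozen embeddings.

Because hotspot positions carry no class information, training data are
expanded with the 8 dihedral transforms (4 rotations × reflection) of each
patch — exact lattice symmetries, no interpolation — and embeddings are
averaged over the same orbit at inference, making the classifier invariant
to them.  Embeddings are standardized with training-set mean/scale before
the kernel machine.

**SVM.**  Decision function `f(x) = Σ αᵢ yᵢ K(xᵢ, x) + b` with linear,
polynomial, or RBF kernels (default RBF, γ = 1/d).  The dual is solved by
a simplified SMO: working pairs are updated jointly under the box
constraint 0 ≤ α ≤ C and the equality Σαy = 0, which pair updates preserve
exactly; tolerance 1e-4, seeded partner choice, C = 10 by default (C = 1
visibly underfits the standardized embeddings).  Multi-class is
one-vs-rest (one machine per class, prediction by largest decision value,
exact ties to the lowest class index); one-vs-one voting is available.  A
`features` pipeline mode feeds the hand-crafted feature vector directly to
the SVM, bypassing the network.

## Evaluation

* **Stratified split**: per-class target counts by largest-remainder
  apportionment of fraction × class_total (floors first, leftover units to
  the largest fractional remainders, remainder ties to the earlier
  partition in train/test/validation order).  Counts are therefore
  deterministic and seed-independent; only the record assignment is
  shuffled.  For class totals (350, 300, 250, 439) at (0.70, 0.20, 0.10)
  this yields (245/70/35), (210/60/30), (175/50/25), (307/88/44) — note
  307/88/44 for 439, where naive flooring would give 307/87/43.
* **Metrics**: accuracy = trace/total; per class one-vs-rest precision,
  sensitivity, specificity, F1.  Ratios with zero denominators are
  *undefined*, recorded as such, and excluded from macro averages (a
  silent 0 would bias them); micro averaging is available.  Macro is the
  reporting default.
* **ROC/AUC**: per-class one-vs-rest curves with tie-aware thresholds,
  trapezoidal AUC (equal to the Mann-Whitney pair-count statistic), plus
  the macro mean over classes present.
* **Cross-validation**: stratified k-fold (default k = 5) over the whole
  labeled set; every sample is held out exactly once; per-fold confusion,
  metrics, AUC and error counts, with the mean and sample (n−1) standard
  deviation of per-fold errors.

## Numerical choices and edge cases

* Intensity bin for value 1.0 is the last bin; histograms always span
  [0, 1] with 256 bins regardless of source bit depth.
* Diffusion `dt` outside (0, ¼] and non-positive `k`, `σ`, `α` are
  rejected at construction.
* Degenerate quantities (constant-image skewness/kurtosis/GLCM
  correlation, descriptor of a gradient-free patch, std of a single fold)
  are flagged (`None`/NaN-with-flag), never silently zeroed; the
  `features` pipeline mode imputes 0 only at the classifier boundary.
* Model files store float32 parameters (JSON header + little-endian
  blobs); reloaded decisions agree to float32 precision and labels
  exactly.
* All seeds derive from a single master seed via `SeedSequence`; per-image
  seeds are stable in the record index, so datasets are reproducible
  byte-for-byte.

## Problem sizes

The shipped study configuration generates 40 phantoms per class (160
total) on 64×64 canvases (the generator default is 128×128) and pools
network inputs to 16×16.  With these sizes a fivefold CV of the full
pipeline runs in ≈4 minutes on one CPU and reaches mean held-out accuracy
≈0.97 with macro AUC ≈0.999.

## Limitations

* Phantom class priors are synthetic conventions; results do not transfer
  to clinical imagery.
* The backbone is a reduced residual network (8 blocks), not a 50-layer
  one; depth is configurable but untested at large depth.
* The DoG detector implements the standard construction but is not a
  reference SIFT (no full 128-D compliance testing, no keypoint matching).
* The SMO solver targets small embedding sets (hundreds of points); it is
  not tuned for large-scale kernel problems.
* Fivefold CV uses the whole labeled set; the 70/20/10 split utility is
  provided separately and the two are deliberately not coupled.
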