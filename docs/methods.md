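# Methods

This note documents the modelling and numerical choices behind the package:
what each stage computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Preprocessing protocol

Volumes are resampled to a common grid (default 320×320×28): in-plane sizes
are bilinearly interpolated, a slice deficit is filled by appending zero
slices at the end, and a slice excess — which the protocol leaves
unspecified — is centre-cropped, mirroring the padding symmetrically. Mask
resampling reuses the volume geometry and re-binarizes at 0.5.

Intensities are clipped to the [0th, 98th] percentile interval (percentiles
by linear interpolation between order statistics, the common package
default) and mapped affinely onto [0, 4033]; the upper bound is carried as a
configuration value. A constant volume degenerates to all zeros with a
warning rather than an error, since it can legitimately appear in padded or
synthetic data. Z-normalization (zero mean, unit variance over the whole
padded grid) is applied only for network input; computing the statistics
after padding is an assumption, flagged here, since the alternative
(pre-padding statistics) differs only through the zero slices.

Bias-field correction is a pluggable hook: `n4_correct` delegates to any
injected corrector (a SimpleITK-backed N4 corrector is provided) and is an
exact pass-through when none is registered. The order of operations is fixed:
resample → bias correction → clip/standardize → z-normalize.

Train/test splits (70/30 and 50/50 conventions) are seeded permutations with
|train| = round(ratio·n); covariate balance across the split is checked with
the two-sided Mann-Whitney U-test.

## Phantoms

Each phantom is a rotated ellipsoid (semi-axes uniform in a configurable
range, default 14–24 mm, giving roughly 11–58 ml organs) optionally
perturbed by a smooth level-set field; the image is a two-level intensity
map (background 1, foreground `contrast`) multiplied by an exponentiated
low-order cosine bias field and corrupted by additive Gaussian noise (Rician
available). Covariates: age ~ Normal(70, 7) years, iPSA log-normal
(median ≈ 8 ng/ml), ISUP/ECE/PIRADS categorical with configurable
probabilities; prostate volume is read off the generated mask, so
volume-derived analyses are internally consistent.

What the phantoms do **not** emulate: zonal anatomy, lesions, partial-volume
texture, coil profiles, or inter-observer contour variability. Tests passing
on phantoms therefore demonstrate the correctness of the machinery —
metrics, losses, training dynamics, statistics — not clinical-grade accuracy
on real MRI.

`degrade_mask` produces controlled "predictions" (dilation, erosion,
in-plane shift, slice dropout) with known qualitative effects on each
metric; `inflate_to_ratio` grows or shrinks a mask to an exact voxel count
by Euclidean-distance ordering with index tie-breaks, so a 1.3× inflation
yields an ARVD of exactly 0.3.

## Metrics

Dice and ARVD follow their set definitions (ARVD's denominator is the ground
truth, so it is deliberately asymmetric). The surface distances are 2D,
slice-wise, in pixel units, because clinical contours are drawn and reviewed
per axial slice on anisotropic voxels. Surfaces use the 4-connectivity
boundary (a foreground pixel with a 4-neighbour background pixel or on the
image border). Conventions that the definition leaves open were fixed as
follows:

- A slice where exactly one contour is empty substitutes a single pixel at
  (⌊H/2⌋, ⌊W/2⌋) for the empty contour; slices where **both** are empty are
  skipped — applying the centre rule to both would contribute spurious
  zero distances.
- MSD pools distance sums and surface counts over all contributing slices
  before the single division; HD95 reduces each slice to the max of the two
  directed 95th percentiles (linear-interpolation percentile, configurable)
  and averages slice values without weighting. Whether to pool or average
  HD95 across slices is an assumption; the averaging choice is recorded
  here.
- ARVD uses voxel counts; on a shared grid the ratio is identical to
  physical volumes.

## Losses

The top-k pixel loss is the mean of the k largest per-pixel terms
−log(1 − |y − ŷ|), with |y − ŷ| clipped at 1 − 1e−7 to keep the log finite
under saturation. The mean (not the sum) is used so the loss scale is
invariant in k; ties at the k-th value are broken arbitrarily, which cannot
change the mean. With binary targets and k equal to all pixels the loss is
exactly binary cross-entropy (asserted in tests). The soft Dice loss uses a
smoothing constant s = 1 in numerator and denominator. Relativistic GAN
losses are computed via a stabilized softplus; the generator objective is
5 × Dice + 1 × adversarial.

## Architectures and compute backend

The networks run on a small reverse-mode autodiff engine over numpy
(`prostseg.nn`): im2col convolutions, transposed convolutions with kernel
equal to stride, depthwise convolutions, batch/group norm, PReLU, swish,
squeeze-excitation, dropout and stochastic depth, Adam. Everything is
float64 and driven by injected `numpy.random.Generator`s, which makes
finite-difference gradient checks tight (≤1e−5) and runs bit-reproducible.

Choices worth recording:

- **Strides and depth.** The V-net stem and all in-plane downsamples use
  stride 2; the slice axis is strided only while it remains divisible by
  two (the clinical depth of 28 supports two halvings). Transposed kernels
  equal their strides, making each upsample the exact adjoint of its
  downsample; where the depth stride is 1 the nominal 2×2×2 transposed
  kernel becomes 2×2×1.
- **Slice-wise 2D networks** are expressed as 3D convolutions with
  (k, k, 1) kernels — mathematically identical to per-slice 2D convolution
  and verified structurally in tests.
- **Fusion denominator.** Fast normalized fusion is implemented with raw
  (un-rectified) weights in the denominator, as the formula is usually
  printed for the "fast" variant; a configuration switch restores the
  rectified denominator of the original detection network. Weights are
  per-input **and** per-channel (channel+input attention) and initialized
  at one.
- **Discriminator pairing.** The discriminator scores a concatenated mask
  pair. The "real" input is the ground truth paired with itself and the
  "fake" input is the ground truth paired with the generated mask; because
  every generated mask has a corresponding ground truth, no (real, fake)
  sampling is needed.
- **Head bias prior.** Every sigmoid head is initialized with bias
  logit(0.1), encoding the prior that roughly 10% of voxels are prostate.
  Starting from a background-dominant prediction instead of a half-on one
  removes a long early plateau of the Dice-type losses; this matters most
  for the GAN generator, whose learning rate (1e−4) bounds total parameter
  displacement over a short run.
- **EfficientDet3D head.** Projection to the 48-channel space is a 1×1×1
  convolution with norm and swish; between levels the feature is resized by
  nearest-neighbour (per-axis factor ⌈target/current⌉, centre-cropped) and
  anti-aliased with a 3×3×1 depthwise convolution; each fusion is followed
  by a depthwise 3×3×3 convolution, norm, and swish. Exactly one fusion
  stage exists per level pair — stacking pyramid layers is deliberately not
  supported.
- Per-level kernel sizes in the 3D backbone follow the 2D stage pattern
  (3 for shallow levels, 5 for P5–P6); the published modification list
  fixes channels, expansion, and kernel depth but not this pattern.
- Batch normalization uses batch statistics (the recipe's batch size is 2);
  `norm="group"` is a fallback for batch-size-1 experiments.

## Training

Plain models: Adam (β₁ = 0.9, β₂ = 0.999), batch size 2, top-k loss, and a
plateau scheduler — if the per-step training loss fails to improve by
min_delta = 1e−4 for 10 consecutive steps, the learning rate steps down
0.001 → 0.0005 → 0.0001. The monitored quantity is the training loss; no
validation split exists in the protocol. GAN: one discriminator and one
generator update per combined step, separate Adam optimizers with
β₁ = 0.5, β₂ = 0.999, lr 1e−4 (generator) and 1e−3 (discriminator).
Inference binarizes the sigmoid output at 0.5 with no post-processing.

Epoch counts and plateau hyperparameters are not part of the published
recipe; the defaults above are assumptions and are configuration values.

## Augmentation

Applied in order: mixup → horizontal flip (p = 0.5) → rotation about the
depth axis (uniform in [−π/4, π/4]) → bilinear resize (scale uniform in
[0.7, 1.3]) and translation (uniform within ±10% of the extent — the
translation range is not specified anywhere, so it is a configurable
default) → elastic deformation. Labels are interpolated bilinearly and left
soft (they are soft after mixup anyway); no re-thresholding happens during
training, consistent with a soft-target loss.

The elastic deformation generates two uniform [−1, 1] noise fields at the
resolution shrunk by β, blurs them with a Gaussian of std σ (reflective
boundaries), scales by α, bilinearly upscales to full resolution, and adds
them to the coordinate mesh grids; one field is shared by all slices of a
volume (the 2D method extended to 3D by slice-shared maps — a per-slice
variant would decorrelate adjacent slices, which contradicts the smooth 3D
anatomy). The defaults α = 2000, β = 1/4, σ = 50 are calibrated to a
320×320 plane; for smaller grids `ElasticConfig.for_shape` rescales
σ linearly and α quadratically with the grid fraction, keeping the
displacement a constant fraction of the field of view.

## Statistics

Wilcoxon signed-rank (two-sided, zeros dropped; identical samples return a
flagged degenerate result), Kruskal-Wallis with tie correction, Spearman
correlation, mean ranks over model means (Dice descending, error metrics
ascending, midranks for ties), the sample (n−1) coefficient of variation,
worst-k tables, and volume-bias analysis (mean pred/true ratio plus a
signed-rank test of the paired volumes). Small-sample p-values are exact by
enumeration; larger samples use the normal approximation with tie and
continuity corrections. Ordinal covariate categories with fewer than three
members are merged into their nearest ordinal neighbour (ties toward the
lower category) before testing, generalizing the handling of sparse ECE and
PIRADS groups. No multiplicity correction is applied anywhere — a
deliberate choice that favours power over Type I control in an explorative
comparison.

## Desk-scale configurations

Structural constants (filter plans, level channels, fusion counts) are
always exposed at full scale; forward passes and training runs in the test
suite use reduced configurations so the whole suite fits on one CPU:
32×32×8 grids, V-net with base 8 filters and 2 levels, transfer model with
a 24-pixel crop and 3 pyramid levels at scale 0.12, EfficientDet3D with 3
levels at scale 0.25, and the convergence harness overfits a single phantom
(≤300 steps plain, ≤600 steps GAN). These sizes are the package's choice of
a minimal faithful configuration; all architectural invariants they certify
(shape contracts, sigmoid range, structural counts, convergence) are
scale-free.

## Known limitations

- The phantom cohort cannot validate clinical accuracy claims; headline
  scores on real data are out of scope by construction.
- ImageNet-pretrained encoder weights are supported only through the
  injection interface; no weight files ship with the package.
- The N4 algorithm itself is external; the package only guarantees the
  hook's contract.
- The compute backend is CPU-only and unbatched beyond the recipe's batch
  size 2; full-scale (320×320×28) training is architecturally supported but
  not practical on one CPU.
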