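# Methods

## Model

voxreg performs pairwise deformable registration of single-channel 3-D
volumes. A fully convolutional network $f_\theta$ maps the channel-wise
concatenation of a fixed image $I_f$ and a moving image $I_m$ (both
preprocessed to a common grid, intensities in $[0,1]$) to a dense
displacement field $s = f_\theta(I_f, I_m)$ with one 3-vector per voxel, in
voxel units. The spatial mapping is $\phi(x) = x + s(x)$, applied by
trilinear interpolation of $I_m$ at the mapped coordinates; out-of-grid
samples replicate the border voxel (clamping), which avoids injecting
artificial zeros into similarity windows near the volume edge.

Training is unsupervised: parameters minimise

    Loss = -NCC_w(I_f, I_m ∘ φ) + λ · L_smooth(s)

**Data term.** NCC_w is the windowed squared normalized cross-correlation:
for every voxel, the squared Pearson correlation of the two images over the
centred `w³` box (default `w = 9`), stabilised as
`cc = (cross² + ε) / (var_f · var_w + ε)` with `ε = 1e-5` in both numerator
and denominator. Placing ε symmetrically makes degenerate flat-vs-flat
windows (ubiquitous in the zero background of skull-stripped volumes) score
1 — a matched pair of featureless windows — instead of 0 or an unstable
ratio; by Cauchy–Schwarz the score stays in $[0,1]$. Window statistics use
only in-volume samples (the box is truncated at the border, with per-voxel
sample counts), which makes the score exactly invariant to affine intensity
maps `b → αa + β` everywhere, including border voxels. The similarity is the
mean of `cc` over all voxels; the squared form is additionally invariant to
contrast inversion, appropriate for mono-modality registration.

**Smoothness term.** L_smooth penalises first spatial differences of the
field: for each axis, the squared forward differences of all three
displacement components are summed per position and averaged over positions,
and the three axis means are averaged. It is zero iff the field is constant
and homogeneous of degree 2. Both terms are means, not sums, so λ is
resolution-independent; the λ grid of interest is {0, 0.1, 0.2, 0.5, 1},
with λ = 1 the default.

## Architectures

All variants are fully convolutional (3³ kernels, padding 1), take 2
channels in and emit 3 channels at input resolution, and use LeakyReLU
(slope 0.2) hidden activations. Upsampling is 2× nearest-neighbour followed
by a stride-1 convolution; skip tensors are concatenated *before* the
convolution. The final "flow head" convolution has linear activation and is
zero-initialised (weights and bias), so an untrained network predicts the
identity transform — the standard stabilisation for unsupervised
registration.

* `convunet_dir` — encoder of 4 stride-2 convolutions (filters 16, 32, 32,
  32), a 2-convolution bottleneck (32, 32), a decoder of 4
  upsample–concat–convolve levels (32, 32, 32, 32; the last level
  concatenates the 2-channel input itself), 3 extra convolutions
  (16, 16, 16), and the flow head: 336,019 parameters. The per-level filter
  counts are configurable (`NetworkConfig`); these defaults mirror the
  VoxelMorph family scale.
* `vm1` — encoder (16, 32, 32, 32), decoder (32, 32, 32, 32, 8, 8) with the
  classic skip pattern: 259,675 parameters.
* `vm2` — same encoder, decoder (32, 32, 32, 32, 32, 16, 16) with an extra
  half-resolution convolution: 300,547 parameters.

Input shapes must be divisible by 16 (four resolution halvings). Parameter
counts are independent of input shape; the baseline counts are pinned
exactly by tests against layer-by-layer arithmetic (Σ 27·c_in·c_out + c_out).

The layer library (`voxreg.nn`) is a small NumPy implementation:
convolutions are evaluated as 27 shifted channel-matmuls (BLAS-friendly,
memory-light), and every primitive — convolution, activation, upsampling,
concatenation, trilinear warping, windowed NCC, diffusion penalty — carries
a hand-derived reverse-mode gradient, each verified against central finite
differences in the test suite. Optimisation is Adam with framework-standard
moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8); learning rate 1e-4 and batch size
1 by default (gradients are averaged when batch_size > 1). Training is fully
seeded (weight initialisation and epoch shuffling) and keeps the best
validation-loss weights (best training loss when no validation pairs are
supplied); per-epoch similarity/smoothness/total losses are recorded and
written to CSV.

## Preprocessing and data handling

Volumes are NIfTI-1; displacement fields are 4-D NIfTI with the
(dx, dy, dz) components on the last axis, voxel units, axes ordered (x, y,
z), 0-based. `preprocess_volume` applies, in order: centred crop on the
non-zero bounding box (peripheral voxels of a skull-stripped scan carry no
information; geometric centre as fallback), align-corners trilinear resize
(nearest for masks), per-volume z-score, and min–max rescale to [0, 1], so
every non-constant volume spans exactly [0, 1]. Normalisation statistics are
per volume, not per dataset — each scan is harmonised independently of
scanner and protocol. A constant volume maps to zeros (documented
degenerate case; a peak-to-peak guard absorbs resampling round-off).
`split_dataset` assigns round-half-up fractions to validation and test with
the remainder to training — 160 subjects at 64/16/20 give exactly
102/26/32 — deterministically in the seed.

## Synthetic phantoms

The generator emulates what the pipeline needs from skull-stripped glioma
MR data, not its full appearance: an exactly-zero background, an ellipsoidal
"brain" (semi-axes 0.33–0.42 of the grid, ~15–30% volume fraction), a few
internal tissue ellipsoids of distinct intensity in [0.35, 1] on a 0.55
base, one low-intensity (0.22) spherical lesion, and optional Gaussian noise
(default sd 0.02) clipped to [0, 1] inside the brain. With no structures and
no noise the volume is binary-valued. All generation is bit-reproducible in
the seed.

Ground-truth deformations are Gaussian-smoothed white noise (component-wise,
sd `smooth_sigma`, default 6 voxels), rescaled so the peak displacement
magnitude equals `amplitude`, and tapered to exactly zero on a 2-voxel
boundary shell so no sample leaves the grid; the taper is gradual (≤4 voxels)
to keep the field's local Lipschitz constant below 1. The moving image is
the fixed image warped by the *inverse* of this field — computed by damped
fixed-point iteration (`invert_field`, 20 iterations, damping 0.5) — so the
stored `true_field` is, by construction, the displacement that registers
moving onto fixed, and endpoint error against a predicted field is
well-defined. Warping the moving image by the true field recovers the fixed
image with mean absolute error ≲ 0.015 at zero noise; the residual is
trilinear-interpolation blur at the phantom's sharp edges, which also caps
the recovered local NCC at ≈ 0.93 (a perfectly matched *smooth* image pair
would approach 1).

What the phantoms do not model: tumor mass effect, resection cavities,
intensity non-uniformity, anatomy-shaped structures, or inter-subject
variability. Passing the end-to-end tests therefore shows that the
optimisation machinery works — the loss is minimised by fields that
genuinely align structure — not that clinical-grade accuracy is achieved on
real scans, which requires training at full 128³ resolution on real data.

## Desk-scale study conditions

The end-to-end checks (tests and `scripts/acceptance.py`) train
`convunet_dir` on 8 synthetic 32³ pairs (peak displacement 3 voxels, noise
sd 0.02) with one validation pair and one held-out pair, 30 epochs of Adam
at 1e-4, batch size 1, at λ = 1 and λ = 0 under identical seeds — sizes
chosen so a full run takes a few CPU-minutes. Measured outcomes: training
loss strictly decreases; held-out brain-mask Dice rises after registration;
mean endpoint error over the brain mask falls below the mean true
displacement magnitude there (i.e., beats predicting zero deformation); and
λ = 1 yields predicted fields with an order-of-magnitude smaller diffusion
penalty than λ = 0. Endpoint error is compared over the brain mask because
the displacement field is unidentifiable in the signal-free background —
an unsupervised intensity loss carries no information there, and the
metric's own definition takes a mask for exactly this reason.

## Numerical choices and edge cases

* Dice of two empty masks is 1.0 by convention (the 0/0 limit of perfect
  agreement); empty vs non-empty is 0. Non-binary inputs are rejected.
* SSIM uses k1 = 0.01, k2 = 0.03, data range 1.0 (canonical constants),
  biased (maximum-likelihood) variances, uniform 7³ windows, mean over
  fully interior windows; `mode="global"` evaluates the single-window
  closed form. The windowed form matches
  `skimage.metrics.structural_similarity(..., gaussian_weights=False,
  use_sample_covariance=False)` to ~1e-9.
* Mask warping is nearest-neighbour by default (`method="threshold"`
  offers trilinear + 0.5 re-binarisation).
* The public `warp_volume` delegates to
  `scipy.ndimage.map_coordinates(order=1, mode="nearest")`; the training
  path uses the package's own differentiable sampler, and a test pins both
  to agree within 1e-5 (float32).
* Local-variance clamping (`max(var, 0)`) guards against float cancellation
  in the NCC moments; the gradient is masked accordingly.
* Non-finite training losses abort with a diagnostic rather than continuing.
* Networks are float32; the public loss/metric functions compute in float64.

## Known limitations

* CPU-only and single-threaded BLAS-scale performance: 128³ training is
  possible but slow; the intended desk-scale regime is ≤ 64³.
* Small-deformation parameterisation: no diffeomorphic integration or
  inverse-consistency guarantee; large-amplitude fields can fold.
* The squared-correlation data term ignores absolute intensity scale, so
  registration quality is only measurable through overlap/structure
  metrics, not intensity error.
* `invert_field` assumes local deformation gradients < 1; stronger fields
  than the generator produces would need more damping or more iterations.
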