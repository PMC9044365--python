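# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, and what the synthetic experiments do and
do not demonstrate.

## Acquisition model and signal processing

A multi-coil Cartesian acquisition of a real non-negative image *x* is
modelled per coil as `kᵢ = F(Sᵢ x) + αᵢ`, with *F* the centered,
orthonormally scaled 2-D DFT, *Sᵢ* a smooth complex sensitivity map, and
*αᵢ* i.i.d. complex Gaussian noise (independent real and imaginary parts of
standard deviation `sd`).  Choices:

- **FFT convention** — centered (DC at the array centre via pre/post
  `fftshift`) with `norm="ortho"`.  Orthonormal scaling makes Parseval's
  identity hold without size factors and keeps forward/inverse symmetric;
  this is the parallel-imaging literature's convention.
- **Noise** — the physical measurement noise is thermal and enters k-space
  additively per coil; i.i.d. complex Gaussian is the standard model.  The
  generator default is noiseless (`noise_sd = 0`), and noise is switched on
  explicitly where an experiment wants it.
- **Under-sampling** — columns (the trailing axis) are the phase-encoding
  direction.  Masks always keep a fully sampled centre block of
  `round(center_fraction · columns)` consecutive columns (defaults: 0.08 at
  4-fold, 0.04 at 8-fold, the public accelerated-MRI convention).  Random
  masks use *exact-count* sampling — exactly `round(columns/acceleration)`
  ones, the non-central ones drawn uniformly without replacement — rather
  than per-column Bernoulli, so the sampled-column count is deterministic
  and testable; the expected sampling density is identical.  Equispaced
  masks place non-central ones at stride = acceleration from a seeded
  offset.
- **Centre crop** — leading margin `floor((in − out)/2)`; an odd margin
  drops the extra row/column from the trailing side.
- **RSS combination** — per-pixel `sqrt(Σᵢ |xᵢ|²)`; invariant to per-coil
  global phase, which is why no phase calibration is needed for the
  network input.

The zero-filled reconstruction (mask → per-coil inverse FFT → RSS → centre
crop) is both the aliased baseline and the single-channel network input.

## Synthetic data generator

Phantoms are sums of `n_ellipses` randomly placed, rotated,
positive-intensity ellipses clipped to [0, 1].  Centres stay within 10% of
the image centre and semi-axes span 16–32% of the image size, so every
ellipse covers the centre pixel, none reaches the corners, and overlapping
ellipses build internal structure with sharp boundaries — the high-frequency
content that makes column under-sampling alias visibly.  Two contrast
styles: `pd_like` (clean) and `pdfs_like`, which multiplies by seeded
log-normal speckle (default sd 0.2) to emulate the grainy appearance of
fat-suppressed sequences.  The speckle parameters are qualitative knobs, not
claims about any scanner.

Coil maps place the default 15 coils at equal angles (random seeded start
angle) on a ring of radius 0.42·min(size) around the centre; each magnitude
is a broad Gaussian (σ = 0.4·max(size)) of distance to the coil and each
phase a gentle random linear ramp.  The set is jointly normalised so
`Σᵢ |Sᵢ|² = 1` at every pixel, which makes the noiseless fully sampled
pipeline exactly invertible through RSS and gives each coil a distinct peak
location — both properties the tests rely on.

What the generator does **not** emulate: knee anatomy, k-space trajectories
other than Cartesian column masking, coil coupling/correlated noise,
multi-vendor contrast variation, or intensity scales of raw scanner data.
Passing tests therefore demonstrate the correctness and trainability of the
pipeline, not clinical reconstruction quality.

## Network

Input: one standardised (zero-mean, unit-variance per slice) aliased
magnitude image; the inverse affine is applied to the output before losses
and metrics, so reconstructions live in original intensity units.  The model
is fully convolutional; spatial dims must be divisible by 2⁴ and at least
48×48 (so the largest pooling window fits at the fourth level).

- **Encoder level** — two 3×3 convolutions, each followed by instance
  normalisation (affine), LeakyReLU (slope 0.2) and dropout (default rate
  0.0); levels joined by 2×2 average pooling.  Instance norm is the
  encoder–decoder reconstruction convention; slope and dropout are
  configurable.
- **Multi-level pooling module** (levels 1–4) — residual multi-kernel
  pooling: max pooling at windows 2, 3, 5, 6 (stride = window, trailing
  remainder dropped), a 1×1 convolution to one channel per branch, bilinear
  upsampling back, concatenation after the untouched input (C → C+4);
  then a Zoom-In/Zoom-Out group of three convolutions — 3×3 to the hidden
  width, a stride-2 3×3 (Zoom-In), bilinear ×2 upsampling plus a 3×3 back to
  C+4 (Zoom-Out) — a 3×3 projection back to C, and a residual addition of
  the module input.  Composition order (RMP first, then zoom, then
  projection) is fixed for reproducibility.
- **Decoder level** — pixel shuffle (r = 2) of the lower level, a 3×3
  channel-adjustment convolution, concatenation with the same-level module
  output, and an encoder-structure block.  The output head is a linear 3×3
  convolution to one channel (no clamping; non-negativity is enforced only
  when producing magnitude images for metrics).

**Channel widths.** The four upper levels use 32, 64, 128, 256 (scaled from
`first_channels`).  Two widths are not pinned by the architecture's public
description and were reconstructed from its documented total size of 8 M
parameters: the bottleneck width (chosen 384 = 12·`first_channels`) and the
Zoom-In/Zoom-Out hidden width (chosen as half the block's input width).
With these the default model has exactly 7,886,593 trainable parameters,
which rounds to 8 M; the natural alternative (bottleneck 512 with full-width
zoom convolutions) gives 10.7 M and cannot round to 8.  This schedule should
be read as a size-consistent reconstruction, not ground truth.

Weights use He-normal initialisation with the LeakyReLU gain; biases and
instance-norm offsets start at zero, scales at one.  With dropout 0 the
model is deterministic given its seed, in train and eval mode alike.

## Training and evaluation

Training minimises the **mean** absolute error (L1) between the
de-standardised network output and the ground truth.  The mean (rather than
an unreduced sum) makes the learning rate transfer across image sizes.  The
optimiser is RMSProp with lr 0.001, decay 0.99, eps 1e-8, no momentum
(these engine defaults are part of the package's reproducibility contract);
sample order is reshuffled each epoch from the training seed.  The
full-scale recipe is 100 epochs at lr 0.001; desk-scale experiments use the
same learning rate with fewer steps.

Metrics follow the accelerated-MRI conventions, since their exact formulas
are not universal:

- **NMSE** = ‖gt − pred‖² / ‖gt‖² (undefined, and rejected, for an all-zero
  reference).
- **PSNR** = 10·log₁₀(data_range² / MSE), +∞ for identical images.
- **SSIM** — uniform 7×7 window, K₁ = 0.01, K₂ = 0.03, sample-covariance
  normalisation N/(N−1), averaged over the interior where the window fits.
  The implementation is cross-checked in the tests against scikit-image's
  `structural_similarity` to < 1e-6.
- **data_range** = maximum of the ground-truth volume; metrics are computed
  per slice, averaged within a volume, then across volumes.

## Desk-scale experiment sizes

The end-to-end learning check trains the reduced model (8 first-level
channels, 0.5 M parameters) on twenty 64×64 15-coil slices at 4-fold random
masking for 10 epochs (200 RMSProp steps) and evaluates on four held-out
slices, repeated for three seeds — about 15 seconds per seed on one CPU
core.  Across seeds the held-out PSNR gain over the zero-filled baseline
averages well above 1 dB (typically 2–4.5 dB) and the epoch-mean loss
decreases monotonically in practice.  These sizes were chosen so the whole
suite runs in about a minute; the experiment shows the architecture learns
to de-alias, not that it reaches any published metric level, which would
require the full-scale knee dataset and long training.

## Known limitations

- CPU-only: the numpy engine is fast enough for desk-scale work (a 320×320
  forward pass of the full 8 M-parameter model takes ~10 s) but not for
  full-dataset training.
- No estimation of coil sensitivities from data (the simulator knows its own
  maps; SENSE/GRAPPA-style calibrated reconstruction is out of scope).
- The L1 subgradient at exact ties is taken as 0.
- `round()` uses banker's rounding for mask budgets; at realistic column
  counts and accelerations this never differs from arithmetic rounding by
  more than the documented contract (`round(columns/acceleration)` ones).
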