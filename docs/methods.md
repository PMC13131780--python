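# Methods

This note documents the models, procedures, and numerical choices behind
`swinpick`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Cryo-electron tomography produces 3D density volumes of vitrified cells at
very low signal-to-noise ratio (often below 0.1) with missing-wedge
anisotropy. Particle picking — localizing macromolecule centroids, and
optionally classifying them — is the rate-limiting step before subtomogram
averaging. `swinpick` treats picking as voxel-wise semantic segmentation
followed by deterministic coordinate extraction: a 3D Swin-Transformer U-Net
labels every voxel with a particle class (or background), and connected
components of the stitched label volume yield centroids.

## Preprocessing

- **Resampling.** Trilinear interpolation in physical coordinates onto an
  isotropic target spacing (default 1 Å per voxel). Output dimensions are
  `round(dim * voxel / target)` per axis; sampling outside the source grid
  clamps to the edge so borders are not contaminated with zeros. A volume
  already at the target spacing passes through exactly.
- **Intensity normalization.** `V' = clip(V / p95(V), 0, 1)`, where `p95` is
  the 95th percentile of the volume's finite voxels. The percentile basis is
  configurable to nonzero voxels only (`nonzero_only`), for reconstructions
  padded with zero slabs; the all-voxels default is deterministic and
  mask-free. A non-positive `p95` (e.g. an all-zero volume) is a hard error
  rather than a silent degenerate output.
- **Coordinate alignment.** SHREC-style reconstructions are taller than
  their ground-truth model volume; annotation z-coordinates are shifted into
  reconstruction coordinates (+156 voxels for SHREC2020, +166 for
  SHREC2021, 0 otherwise). Offsets apply to coordinate tables only — masks
  are assumed co-registered after standardization.
- **Label construction.** Per-dataset class IDs are remapped into a unified
  ID space by pure value substitution; membrane/vesicle IDs drop to
  background. Instance occupancy shapes are preserved exactly — supervision
  uses the true 3D segmentation footprint, never synthetic spheres or
  Gaussians around centroids. Binary masks collapse all particle classes
  to 1.

All in-memory volumes use canonical `(z, y, x)` axis order with 0-based
indices; the MRC header's column/row/section mapping is applied only at the
I/O boundary and restored on write. Coordinate tables are CSV with columns
`class_id, x, y, z`, 0-based floating-point voxel coordinates. (SHREC ground
truth may use a different origin convention; anyone comparing against it
should check for an off-by-one.)

## Feature channels

The network input is a 4-channel stack computed on the full normalized
tomogram (so window borders see true context), then windowed:

1. the normalized density itself;
2. **Sobel gradient magnitude**: the `(-1, 0, 1)` derivative stencil with
   `(1, 2, 1)` smoothing on the two orthogonal axes, divided by 32 so a
   unit-slope ramp responds with exactly 1 per voxel, then divided by the
   per-axis voxel size to express gradients per Å;
3. **combined multi-scale top-hat**: white (`I − opening`) and black
   (`closing − I`) top-hats with discrete balls of radius
   s ∈ {1, 2, 4, 8} voxels, each response weighted by `s^1/2`, aggregated by
   voxel-wise maximum over scales and polarities;
4. **multi-scale DoG blobness**: `G(·; k·s) − G(·; s)` with k = √2 per scale,
   multiplied by `s²` (the scale-normalized Laplacian approximation, on by
   default), keeping at each voxel the signed response of the scale with the
   largest absolute magnitude. On ties the smallest scale wins (ties occur
   essentially only on constant regions, where every response is 0).

Derived maps 3 and 4 are clipped to their [0.01, 99.99] percentile interval
to tame outliers; clipping can be disabled. All filters use replicate
("nearest") boundary handling. The DoG ratio k is configurable (k = 2 is a
common alternative convention).

## Windowing

Volumes are tiled by disjoint cubic cores (default 48³) with a fixed context
margin per face (default 8), giving 64³ windows; windows are zero-padded
where they leave the volume, and boundary cores record truncated extents.
Training optionally drops (input, mask) window pairs whose mask is entirely
background; inference always keeps full coverage. Because cores are disjoint
and exhaustive, stitching writes each output voxel exactly once from its
window's core — the split/stitch round trip is exactly the identity, and no
padded voxel ever influences the output. Core and pad are configurable; the
window must stay divisible by 16, the encoder's total downscale factor.

## Network

A 3D Swin-Transformer U-Net over channel-last tokens:

- **Stem:** per-voxel linear embedding of the 4 input channels to
  `hidden_dim` (default 32).
- **Encoder:** four stages of patch merging (non-overlapping 2³ blocks
  flattened to tokens of length `8C`, linearly projected to `2C`,
  layer-normalized) followed by an even number of Swin blocks per stage
  (default depths (2, 6, 6, 2), heads (3, 6, 12, 24), 32 per-head channels).
  A 64³ window reaches a 4³ bottleneck at width `16 × hidden_dim`.
- **Swin block:** pre-norm residual attention then pre-norm residual MLP
  (hidden width 4C, GELU, dropout). Attention is restricted to 2×2×2 token
  windows; blocks alternate regular and cyclically shifted windows
  (shift = window/2). Attention logits carry a learnable relative position
  bias indexed by the 3D offset between tokens ((2·2−1)³ = 27 table entries
  per head for the default window).
- **Shift masking.** After the cyclic shift, pairs of tokens that originate
  on opposite sides of a volume boundary (one wrapped, one not, on any axis)
  receive a −10⁴ additive logit, i.e. < 1e−6 attention weight. Tokens that
  are spatially contiguous in the original volume may attend to each other
  even across the regular window partition — that is the purpose of the
  shifted pass.
- **Decoder:** mirrored patch expansion (linear projection to `C/2 · s³`,
  block rearrangement, layer norm), additive skip fusion
  `LayerNorm(F_dec + F_enc)` with the same-resolution encoder output, and
  mirrored block stacks. The final expansion returns to the input
  resolution and fuses with the stem features; a layer norm, GELU, and
  per-voxel linear map (a 1×1×1 convolution) produce the K class logits.

The network, and the reverse-mode automatic differentiation underneath it,
are implemented in NumPy within this package. Weights initialize from a
seeded N(0, 0.02²); layer norms at identity; bias tables at zero.

## Training

Class-weighted cross-entropy, mean-reduced over voxels, with
inverse-frequency weights `w_k ∝ N_total / (K · max(N_k, 1))` normalized to
mean 1 (so the learning-rate scale does not depend on the weighting); the
`max(·, 1)` guard keeps absent classes finite. Weights default to corpus
voxel counts and can be supplied explicitly. Optimization is Adam
(default learning rate 1e−4, batch 2) with global-norm gradient clipping at
τ = 1: gradients are rescaled to norm τ when they exceed it, preserving
direction. A single seed drives initialization, shuffling, and dropout;
identical seeds reproduce loss curves bit-for-bit. Every epoch writes a
self-describing checkpoint (weights, Adam state, loss/validation history,
best-validation record, full config snapshot) that loads and resumes.

## Inference and detection

Window logits become softmax posteriors; a voxel keeps
`argmax_c p_c` only if `max_c p_c ≥ τ`, else background (τ ∈ [0, 1],
default 0.5). Stitched label volumes are post-processed per class:
connected components under 18-connectivity (face + edge neighbours),
removal of components below a minimum voxel count (inclusive bound,
default 5 at 1 Å scale), and unweighted centroid extraction.

Evaluation matches predicted to reference centroids by Hungarian one-to-one
assignment on Euclidean distance, with entries above the cutoff d_max
(default 5 voxels) invalidated by a large constant (10⁶ · d_max);
assignments landing on invalid entries do not count. TP = matched pairs
within d_max, FP = predictions − TP, FN = references − TP;
precision/recall/F1/miss-rate follow, with zero-denominator ratios reported
as undefined rather than 0, and AD is the mean matched distance. Multiclass
evaluation matches within class; binary evaluation pools coordinates.
One-to-one assignment cannot produce multiple hits per reference; a
"multiple hits" tally is therefore structurally 0 here. Distances are in
voxel units (the cutoff is specified in voxels).

## Synthetic data

The simulator emulates the input triplet of a picking pipeline: a density
volume with particles of several size classes at known centroids, the
occupancy mask, and the coordinate table. Particles are solid spheres
(occupancy = mask exactly; a Gaussian-profile option exists for softer
contrast) placed by rejection sampling under a minimum pairwise center
distance; additive i.i.d. Gaussian noise sets the contrast regime; an
optional Fourier wedge (coefficients zeroed where the angle from the x–y
plane toward z, about the y tilt axis, exceeds the half-angle) reproduces
z-elongation. A seed makes generation bit-reproducible.

Defaults: 64³ volumes at 1 Å, two classes (radius 3, 10 copies; radius 5,
6 copies; amplitude 1), noise σ = 1 (amplitude²/σ² ≈ 1, an "easy" contrast
regime), minimum center distance 14 voxels. σ ≈ 3 approximates the sub-0.1
SNR of real tomograms. What the simulator does **not** model: structured
cellular background, membranes and filaments, CTF and dose effects,
reconstruction artifacts, anisotropic resolution (unless the wedge is
enabled), and realistic particle shape/orientation variety. Passing the
synthetic benchmarks therefore demonstrates that the pipeline's machinery —
features, windowing, network, training loop, stitching, detection — is
correct and trainable, not that the defaults transfer to experimental
tomograms.

## Reduced CPU benchmark

Training the full-size model is a GPU-scale exercise; the repository's
self-contained benchmark uses a reduced preset that keeps the full
architecture (4 merge/expand stages, alternating regular/shifted attention,
additive skips) at CPU-friendly widths: hidden 16, depths (2, 2, 2, 2),
heads (1, 2, 4, 8), head dimension 16, no dropout, 32³ windows (24-voxel
cores, 4-voxel context). Nine simulated 64³ volumes are used: six for
training (≈150 windows after background filtering), one for validation, two
held out for testing. Training runs 20 epochs of Adam at learning rate
1e−3, batch 2 (a higher rate than the full-size default, appropriate for
the small model and short schedule), checkpointing every epoch.

The three free post-training choices — which checkpoint to deploy, the
confidence threshold τ, and the minimum component size — are selected on
the validation volume only: every 4th checkpoint is scored over a small
grid (τ ∈ {0.5, 0.8, 0.95}, min-size ∈ {30, 60} voxels, both far below the
smallest particle's 123-voxel footprint) and the combination with the best
pooled validation F1 wins. Ties break toward the later epoch (no evidence
of degradation), then higher τ, then smaller min-size: detection quality at
this scale is epoch-volatile, and the τ preference reflects that confident
prediction cores also separate touching particles, the dominant error mode.
Test volumes are then scored once, pooled, by Hungarian matching at
d_max = 5.

Known failure mode: two same-class spheres near the minimum center distance
can merge into one predicted component, costing one FN (and sometimes an
FP); higher τ erodes predictions toward their confident cores and mitigates
this. Residual errors of the benchmark are dominated by such merges.

## Numerical choices and edge cases

- Percentile normalization is exactly idempotent only when the normalized
  volume's p95 reaches the clip value 1 (i.e. ≥ 5% of voxels clip).
- DoG scale ties keep the smallest scale; argmax in detection keeps the
  lowest class index on exactly equal posteriors.
- Label volumes write as MRC mode 0/1 (exact integers); densities as
  mode 2 (float32).
- Component size filtering is inclusive (`size ≥ min_size` survives).
- Empty prediction or reference sets are legal everywhere; ratios with zero
  denominators are `None`, never 0, and AD is absent when TP = 0.
- The stitching contract rejects overlapping or incomplete core coverage
  instead of silently blending.

## Limitations

- No CTF/deconvolution/denoising of inputs; no membrane or filament
  handling; no orientation estimation; no instance splitting of touching
  same-class particles (a merged pair yields one centroid).
- The NumPy training loop is single-process and CPU-bound; it is sized for
  correctness demonstrations, not for SHREC-scale training.
- Multi-GPU data parallelism, mixed precision, and pretrained weights are
  out of scope.
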