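# Methods

This note describes the models, algorithms, and numerical choices behind
`doseup`, a package for super-resolving 2D dose measurements taken with a
checkerboard ionization-chamber array.

## Problem

Planar dose verification in radiotherapy compares a measured 2D dose
distribution against a predicted one, usually with the gamma index. Chamber
arrays measure in real time but sample the plane coarsely: the modeled
device places 1405 chambers on a 53×53 grid with 5 mm pitch in a
checkerboard pattern (chambers on nodes with even row+column sum, so all
four corners are active). The nearest-neighbor distance is diagonal,
5·√2 ≈ 7.1 mm, and the axial chamber-to-chamber distance is 10 mm. Each
chamber has a 4.4 mm square sensitive area whose finite size averages the
local dose (the volume-averaging effect). The task is to reconstruct a
159×159 dose map at 1.67 mm pitch from such a sparse, blurred, noisy
measurement — a factor-3 super-resolution with half the low-resolution
nodes missing.

## Measurement forward model

A high-resolution slice (159×159 at 5/3 mm) maps to an array reading by:

1. **3×3 average pooling** onto the 53×53 chamber grid. Block centers are
   collocated with chamber centers, i.e. chamber (i, j) reads the mean of
   the 3×3 block centered at high-resolution pixel (3i+1, 3j+1).
2. **Additive Gaussian noise** with standard deviation 0.5 % of the slice
   maximum (the statistical noise floor of a high-quality Monte Carlo dose
   calculation), clamped at zero.
3. **Checkerboard masking**: nodes without a chamber read exactly zero.

## Bilinear baseline

The conventional reconstruction chain fills each missing node with the mean
of its available axial chamber neighbors (up to four; diagonal neighbors
are never used), then bilinearly upsamples the dense 53×53 grid by a factor
3. The upsampling keeps output pixel (3i+1, 3j+1) collocated with input
pixel (i, j), so both grids share physical center and extent; the fringe
beyond the hull of input centers replicates edge values.

## Synthetic training data

Real training data would require Monte Carlo simulations of MLC-shaped
fields. The package instead ships a desk-scale analytic surrogate that
reproduces the statistical recipe of such a dataset:

- **Machine parameters** per simulation: field-shape strategy mixed
  67/22/11 % (spot / rectangular / random leaf ends); gantry 20 % at 0°,
  else uniform ±18°; collimator drawn from five equally likely branches
  (uniform ±180°; exactly 0°; one of {−90°, 90°, 180°}; one of
  {±45°, ±135°}; normal with σ = 11.25° around a random multiple of 45°);
  couch 90 % at 0°, else the gantry procedure; monitor units uniform
  50–150; nominal energy from a generalized-extreme-value law
  (location 7, scale 6, shape 0.1) truncated to 4–25 MV by inverse-CDF
  restriction; source-surface distance 800 mm; source-detector distance
  uniform 800–1200 mm snapped to the 5/3 mm depth raster; maximum field
  size 330 mm.
- **Rendering**: the binary MLC-aperture fluence (evaluated in the MLC
  plane after undoing collimator rotation and SDD/SSD magnification;
  closed leaf pairs transmit nothing) is convolved with a two-component
  Gaussian kernel — an energy-dependent penumbra core (σ 2–6 mm) and a
  broad low-amplitude scatter tail (8 %, σ 15 mm) — scaled by
  MU × 0.01 Gy/MU, and modulated by a smooth random phantom-heterogeneity
  factor (bounded to ±30 %) plus a small gantry/couch-dependent tilt.
  Each simulation renders a stack of slices stepped 5/3 mm in depth.
- **Pair extraction**: a uniformly placed 159×159 submatrix of a random
  slice, one of the eight square symmetries as augmentation, and the
  forward model above as the input. Pairs carry their simulation
  identifier; train/validation splits are made on simulations, never on
  pairs, so no field geometry leaks across the split.

## Network

A DenseNet-style fully convolutional model maps the 1-channel masked
measurement to the 1-channel high-resolution map: a 3×3 stem to 16
channels; a dense block of 16 layers (each ReLU → 3×3 convolution
producing 8 new channels, concatenated: 16 → 24 → … → 144); a 3×3
transposed convolution with stride 3 (kernel equals stride, so output
blocks are disjoint) tripling the resolution; a second dense block of 4
layers; and a 1×1 head. Weights use He initialization.

Training minimizes MSE plus an equivariance penalty: for a square symmetry
g drawn per batch, the features of the transformed input must equal the
transformed features of the original input, compared at every dense-layer
output and at the network output. The optimizer is AdamW (decoupled weight
decay 1e-2) under cosine annealing with warm restarts: cycles of 16, 32,
64 epochs (restarts at epochs 16 and 48, 112 epochs total), lr from 1e-3
to 1e-6. Measurement noise is redrawn from the noiseless pooled target
every epoch, turning the noise into augmentation.

The numerical backend is a small reverse-mode automatic-differentiation
engine over float32 NHWC arrays (`doseup._autodiff`), with the 3×3
convolution implemented as a single GEMM over the padded input producing
all nine tap contributions. Every operation's backward pass is verified
against central finite differences in the test suite.

## Gamma analysis

For every non-suppressed reference point, gamma is the minimum over
evaluated positions of √((ΔD/δD)² + (d/DTA)²), with δD a percentage of the
local reference dose (local criterion) or of the reference maximum
(global). Points below the threshold (percent of the reference maximum),
and zero-dose points under the local criterion, are excluded from the
statistics. The evaluated distribution is bilinearly interpolated onto a
10× sub-grid; the search visits sub-grid offsets in order of increasing
distance within 3×DTA and terminates early once the distance term alone
exceeds every remaining candidate minimum. Reference positions snap to the
nearest sub-grid node (≤ half a fine pixel). Gamma ≤ 1 passes.

## Film calibration

Radiochromic film scans (16-bit red channel, 72 dpi, pixel pitch
25.4/72 ≈ 0.353 mm) are mapped to the abscissa t = log₁₀(px / 2¹⁶) — zero
at full transmission, negative for darkened film — and a cubic
D(t) = p₁t³ + p₂t² + p₃t + p₄ fitted on replicate-averaged calibration
exposures converts t to dose. Out-of-domain t values are clipped to the
calibration domain and negative fitted doses are clamped at zero.

## Scaled study sizes

The full 53×53 → 159×159 geometry with the 16+4-layer network is too
expensive for a single-CPU run, so the package defines a reduced profile
that we use for the end-to-end study: 27×27 → 81×81 geometry, fields
confined to 90 mm, a 4+2-layer network (channel widths 16 → 48 before
upsampling, 48 → 64 before the head), 200 simulations with 3 pairs each
(510 training / 90 validation pairs), 15 training epochs at batch size 16.
These sizes are our own choice for CPU-scale experiments; all sampling
distributions and the loss are unchanged from the full recipe. Evaluation
compares the trained network against the bilinear baseline on 50 held-out
fields carrying measurable dose (target maximum above 0.05 Gy), scored
with gamma 2 %/2 mm, local criterion, 10 % threshold.

## Limitations

- The dose renderer is an analytic surrogate, not a transport calculation;
  absolute dose levels and penumbra shapes are plausible rather than
  physically accurate.
- The equivariance penalty uses zero-padded convolutions, so exact
  equivariance is only achievable up to boundary effects.
- The gamma engine discretizes the search to a sub-grid (10× by default);
  gamma values carry a discretization error of order one fine pixel in the
  distance term.
- Training runs entirely on the CPU in float32; large-scale configurations
  are supported by the code but not practical without hours of compute.
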