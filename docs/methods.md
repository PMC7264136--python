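# Methods

## The metric

A binary edge image is computed per axial slice; every 8-connected
component of edge pixels counts as one *edge* — a continuous line with no
breaks. Diagonal pixel runs are visually continuous lines, so
8-connectivity is the default (4-connectivity is exposed for sensitivity
analysis; it fragments diagonals). For a paired MAR-off/MAR-on
acquisition of the same object the package reports, per slice, the count
difference `d_i = off_i − on_i` (summarized as mean ± sample SD, n−1
denominator), and per pair the edge reduction ratio
`100·(E_off − E_on)/E_off` on stack totals. Both surfaces exist because
they answer different questions: the ratio is one number per
condition, the per-slice differences carry the variability needed for
between-condition tests. No anatomical masking is applied: all
components are counted, and the pairing makes anatomy approximately
cancel in differences (exactly, in the simulator).

## The modified Canny detector

Stages, in order: impulse denoising → Gaussian smoothing → Sobel
gradient → magnitude noise gate → non-maximum suppression → automatic
threshold resolution → hysteresis tracking. Numerical conventions are
pinned so an independent implementation can reproduce results exactly:

* **Denoising** (`denoise_method`, default `median3`): 3×3 median with
  half-sample reflected borders. A count-based metric is maximally
  sensitive to speckle — a single salt pixel is a whole extra component —
  so noise removal is an explicit pipeline stage rather than
  preprocessing.
* **Smoothing** (`gaussian_sigma`, default 1.4 px): separable truncated
  Gaussian, radius `ceil(3σ)`, kernel normalized to unit sum, reflected
  borders (constant images are fixed points; no spurious border edges).
* **Gradient**: 3×3 Sobel pair; magnitude is the Euclidean norm,
  direction `atan2(gy, gx)` in (−π, π]. Magnitudes below 1e-9 are clamped
  to exactly zero (numerically flat).
* **Noise gate** (`noise_floor_k`, default 3.0; 0 disables): in a flat
  region with additive Gaussian noise the gradient magnitude is
  Rayleigh-distributed, so the noise scale is estimated robustly as
  `median(magnitude)/√(2 ln 2)` — edges occupy a minority of pixels in an
  axial slice, leaving the median inside the noise bulk — and magnitudes
  below `k` noise-sigmas are zeroed. This is the pipeline's in-process
  noise removal: the automatic thresholds below are quantiles of the
  *positive* magnitudes, a population that noise would otherwise flood
  (measured on the phantom at noise σ=5: ~300 spurious components per
  slice without the gate, zero with it). On noise-free images the median
  magnitude is zero and the gate is inert.
* **Non-maximum suppression**: gradient direction quantized into four
  sectors with boundaries at odd multiples of 22.5°; a pixel survives if
  its magnitude is ≥ both neighbours along the quantized direction
  (plateau ties kept — deterministic, and hysteresis resolves thick
  crests); border pixels compare only in-grid neighbours.
* **Automatic thresholds** (`threshold_mode=auto`, defaults
  `high_percentile=0.7`, `low_high_ratio=0.4`): `high` is the 0.7
  quantile of the positive magnitudes of the *raw* (gated) magnitude
  grid, `low = 0.4·high`. The quantile uses linear interpolation between
  order statistics at plotting position `h = q·n` (the type-4 scheme):
  for magnitudes 1..100 at q=0.7 this yields exactly 70. Resolving on the
  raw grid rather than the NMS-thinned grid matters: the thinned
  population contains only ridge crests, which pushes the 0.7 quantile to
  crest level and silently drops mid-contrast structures; the raw
  population includes the smoothing skirts and gives a stable, lower
  threshold. Resolved thresholds are materialized into
  `EdgeMap.params_used` for auditability. Fixed thresholds are available
  for cross-machine comparisons.
* **Hysteresis**: strong ≥ high; weak in [low, high); final edges are the
  8-connected components of weak∪strong pixels containing at least one
  strong pixel.

The detector is deterministic, equivariant under 90° rotation, and
invariant under positive rescaling of binary-valued images (thresholds
scale with the quantile); these properties are tested.

## The synthetic phantom

Each slice: background plateau, a horseshoe arch (annulus sector, gap
opening upward), and one dense insert disk, with a fixed one-pixel linear
anti-aliasing ramp at every boundary (stair-casing would shatter one band
boundary into many components and destroy ground truth). Streaks are
radial ribbons emanating from the insert centre at seeded random angles
(spacing construction: minimum gaps plus Dirichlet-distributed surplus
plus a random rotation — always feasible, no rejection loop), alternating
bright (+100) and dark (−60) amplitude, clipped to [0, 255]. Streak
angles are shared across slices: a rigid prosthesis casts consistent
streaks through contiguous axial slices. MAR is modelled as streak-subset
removal — the MAR-on stack keeps the first `k_on` of the `k_off` angles
with identical geometry — which gives exact combinatorial ground truth.

Default geometry (256×256, 10 slices): background 60, arch 120 between
radii 78–104 with a 100° anterior gap, insert 250 at radius 8 in the arch
interior, streaks from radius 24 to 64. These values are chosen so that
every drawn structure produces one isolated closed contour: the insert
sits in the open interior rather than on the arch band, and streak
ribbons end before the arch, so no contours ever 8-connect. The
background sits at 60 rather than near-black because dark bands are
subtractive and clip at zero: a near-black background would cap dark-band
contrast at a level no thresholding could separate from the floor,
making half the ground-truth streaks undetectable by construction.
Amplitudes (+100/−60) put both polarities in the same contrast range as
the anatomy. A noise-free (or σ=5) default pair therefore measures
exactly `k+2` components per slice — `k` streaks plus the arch and insert
contours — and the measured ratio for the canonical `k_off=10, k_on=4`
pair is exactly 50.0% against a true streak reduction of 60%: the two
shared anatomy components dilute the ratio, the same role anatomy plays
in real scans. What the simulator does *not* emulate: polychromatic
forward projection, beam hardening and cupping, scatter, detector
physics, or streaks that cross anatomy — so passing tests demonstrate
metric correctness on controllable truth, not reconstruction realism.

Gaussian read-out noise (`add_noise`) is seeded and clipped; all
generator outputs are pure functions of their arguments, so one seed
reproduces a pair bit-exactly.

## Statistics

Slice counts from different acquisitions form unbalanced groups with
unequal variances, so everything is Welch-based: Welch's one-way ANOVA
(weights `n_i/s_i²`, Welch-adjusted fractional df2), Games–Howell
pairwise comparisons (per-pair Welch–Satterthwaite df, statistic on the
studentized-range scale, p from the studentized-range distribution with
k groups), and two-sided Welch t-tests (a pooled Student option is
exposed for sensitivity checks only). All tests are two-sided at
α = 0.05 by default; sample variance uses n−1 throughout. Shapiro–Wilk
(Royston AS R94 approximation) is always computed for 3 ≤ n ≤ 5000 and
reported with an advisory flag marking the conventional n ≤ 30 gate; it
is never used as a behavioural switch, since silently changing the test
family on a normality p-value makes analyses irreproducible. The
studentized-range CDF is evaluated by numerical quadrature (via SciPy);
the test suite cross-checks it against an independent fixed-grid
Gauss–Legendre double integral and against `pingouin`.

The factorial layer reproduces the 2×2 design structure of voxel size
(0.2/0.3 mm) × tube voltage (70/100 kVp): for each voxel size the two
voltages are compared and for each voltage the two voxel sizes, four
margin tests in total.

## Validation strategy and problem sizes

Every pipeline stage is verified against a brute-force per-pixel oracle
(median sort, dense 2-D convolution, explicit Sobel stencils, per-pixel
sector NMS, BFS hysteresis flood) on ≥100 random grids up to 64×64, exact
or within 1e-9. Component counting is verified exhaustively on all 512
3×3 binary maps plus ≥300 random 64×64 maps against a BFS flood fill.
Ground-truth recovery runs 20 seeded pairs at the default 256×256×10
size; Welch-ANOVA type-I error is calibrated on 10,000 null simulations
(k=4, unequal n and variances, 5% ± 1% at α=0.05); Shapiro–Wilk is
checked against values frozen from R's `shapiro.test` and its null
p-value distribution against uniformity. These sizes keep the full suite
within a few minutes on one core while leaving each check statistically
meaningful.

## Known limitations

* The study that motivated the metric reports none of its Canny
  parameters, so numerical agreement with any particular scanner
  workflow is not claimed — only qualitative behaviour.
* The automatic threshold adapts per slice; comparisons across machines
  should consider fixed thresholds.
* The noise-scale estimate assumes edges are a minority of pixels; on
  pathological inputs that are mostly texture the gate overestimates the
  floor (disable with `noise_floor_k=0`).
* DICOM input is mapped through rescale slope/intercept and per-stack
  min–max to 8 bits; Hounsfield calibration and non-axial reformats are
  out of scope.
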