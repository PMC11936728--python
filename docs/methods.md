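# Methods

`capflow` implements the quantitative chain used to characterize
capillary flow disturbances in the mouse cortex before symptomatic
amyloid pathology: stall statistics from OCT-angiography time series,
single-capillary velocimetry from two-photon line scans, transit-time
deconvolution from dye-dilution curves, phosphorescence-lifetime
oximetry, and vessel/plaque morphometrics. Every stage can be exercised
against synthetic inputs with known ground truth, so the pipeline is
validated by parameter recovery rather than by re-analysis of raw
microscopy.

## Stall detection and statistics (`stalls`)

OCT-A contrast is decorrelation-based: signal requires moving
scatterers, so a capillary whose red cells halt vanishes from the
angiogram for as long as the stall lasts. Given a volume time series
(60 volumes of 8.5 s in the standard protocol) and a label mask of
capillary segments, per-segment mean-intensity time courses are
thresholded at `threshold x median` of each segment's own trace
(default 0.5). This replaces the interactive rater inspection used at
acquisition with a reproducible rule; the threshold is relative, so it
is invariant to global intensity scaling.

From the stall-o-gram (binary segments x volumes raster) the four
summary statistics are:

* **total stalls** — segments with at least one stalled frame;
* **incidence rate** — stalling segments / segments examined, %;
* **point prevalence** — mean over volumes of (stalled segments /
  segments examined), %. A raw mean count per volume is also emitted,
  because "episodes per volume" admits both readings;
* **cumulative stall time** — stalled frames / total volumes per
  stalling segment, %, with a pooled mean.

Events separated by a single flowing frame count as distinct events;
stalls shorter than one volume (8.5 s) are invisible by construction.
Both limits mirror the acquisition's temporal resolution.

## Line-scan velocimetry, flux, diameter (`linescan`)

With plasma labelled and red cells unlabelled, an axial line scan
yields a space-time image in which each cell traces a dark streak whose
slope is its velocity. Per 150 ms window (stepped by 50 ms) the streak
angle is the Radon-projection angle of maximal variance, scanned
coarsely at 1°, refined at 0.1°, and interpolated parabolically around
the peak. The parabolic vertex is quantized at 1e-4 degrees — below
that the estimator carries no information, and quantization lets
symmetric peaks (stationary cells) resolve to exactly zero velocity. A
streak advancing s pixels per line corresponds to v = s·pixel/period
(µm/ms ≡ mm/s). Windows whose peak-to-mean projection-variance ratio
falls below 1.5 carry no streak contrast and are flagged invalid
(NaN). Because the statistic is a variance, the estimate is invariant
to intensity scaling and contrast polarity.

Transverse scans cross the lumen: a passing cell darkens the whole
lumen for `cell length / velocity` seconds. Per-line mean intensity is
split by deterministic 2-means (centers seeded at the min and max —
no named algorithm exists for this step, so the simplest reproducible
one is used); flux is the rate of absent-to-present transitions. If
the class separation is under 4x the pooled within-class SD the trace
is treated as unimodal: zero flux, low confidence. Diameter is the
FWHM of the window-averaged spatial profile over cell-free lines, with
the baseline taken as the median of the outermost 10% of columns and
crossings located by linear interpolation. Linear density is mean flux
over mean velocity (cells/mm); COV is SD/mean over valid windows.

## Transit-time deconvolution (`dilution`)

The venous output function is modeled as the arterial input function
convolved with an f-scaled gamma transport density h(t; α, β):

    VOF(t) = f · (AIF ⊛ h)(t),   MTT = α·β,   CTH = √α·β,
    RTH = CTH/MTT = 1/√α.

Curves are normalized to the AIF's post-bolus baseline (final 20% of
the 10 s curve-matching window) and fitted by bounded least squares
inside that window. Numerical choices: the kernel is truncated at the
99.9% gamma quantile and discretized with trapezoid end-weights; a
fixed multi-start grid over α (2, 8, 32) with β seeded from the
AIF-to-VOF peak lag makes the optimization deterministic; α is capped
at 500 to represent the plug-flow (delta-kernel) limit without
overflow.

An explicit vascular delay (kernel argument t − delay, bounds
[0, 3] s) is available but **pinned at zero by default**: on noisy
curves the delay and the gamma mean are only weakly identifiable —
their sum is stable while the split wanders — which inflates the
variance of MTT estimates for short transit times. With the plain
gamma model, recovery on synthetic pairs at SNR 20 (α ∈ 2–8,
β ∈ 0.25–1 s, ≈7 Hz sampling) achieves median MTT error ≤ 2.6% and
CTH error ≤ 7.9%; noiseless pairs invert exactly.

QC rejects fits with R² < 0.9 and curves with ≥ 3 consecutive samples
pinned at their maximum (detector saturation). The time-shift check
overlays the AIF with the VOF shifted back by the fitted MTT and
reports the residual cross-correlation lag, computed on the windowed
transient so the recirculation plateau does not dominate.

## Phosphorescence oximetry (`oximetry`)

Photon-decay histograms (290 µs collection window, ~15,000 averaged
sweeps) are fitted with a·exp(−t/τ) + b by nonlinear least squares,
initialized from a log-linear regression of the background-subtracted
counts. A histogram whose initial amplitude sits within 3 SD of the
tail noise is rejected as having no decay. Lifetimes convert to pO₂
through a required calibration — Stern–Volmer parameters
(1/τ = 1/τ₀ + k_q·pO₂) or a monotone (τ, pO₂) titration table; no
probe constants are hard-coded because the calibration is an
independent experiment. pO₂ converts to saturation through a Hill
curve; the default parameters (p50 = 40.2 mmHg, h = 2.59) are
literature values for mouse hemoglobin, marked as such, and recorded
with every output. OEF pairs mean arterial and venous saturations:
(Sa − Sv)/Sa. Manual vessel diameter is the mean FWHM of five
transversal intensity lines.

## Morphometrics (`morpho`)

Segment diameters follow the skeleton-to-boundary definition: the
anisotropic Euclidean distance transform of the vessel mask is sampled
at each segment's centerline voxels; diameter = 2 x mean distance and
the SD is 2 x SD of the same distances (the factor of 2 keeps the SD
on the diameter scale). Distance is measured to the nearest background
voxel center; for a degenerate one-voxel-wide line this convention
reports two voxels rather than one — on real rasterized tubes it is
accurate to within half a voxel. Capillaries are segments with mean
diameter ≤ 9.2 µm (8 pixels at 1.15 µm). Tortuosity is centerline arc
length over endpoint chord; length density is total capillary length
per analyzed volume (µm/µL); blood volume fraction is vessel voxel
volume over analyzed volume. Plaques are 26-connected 3-D components
with physical volumes, count density per mm³, burden %, and
configurable size-class edges (the class boundaries are not published,
so they are required configuration). Segmentation validation uses
voxel-wise Dice, precision and recall, with the two-empty-masks case
defined as perfect agreement. Region volumes are voxel counts times
the nominal voxel volume (e.g. 150 x 150 x 200 µm = 0.0045 mm³).

## Statistics utilities (`stats`)

Outliers are removed where |z| > 3.29, with z computed on the full
sample in a single pass (the rule is not re-iterated). Cohen's d uses
the pooled-SD denominator (recorded in the output; Glass's Δ is not
used) with conventional magnitude edges 0.2/0.5/0.8. Benjamini–
Hochberg adjustment delegates to statsmodels and is cross-checked
against a hand-computed step-up oracle in the tests. Sample-size
inflation for an anticipated completion rate is ceil(n/rate), e.g.
6 completers at 60% success → 10 enrolled. Mixed-model fitting and
marginal-means contrasts are deliberately out of scope — standard
statistics packages do that; this module prepares their inputs.

## Synthetic data (`synthdata`)

The generators reproduce the statistical structure each analysis
assumes, with one top-level seed split into independent streams:

* **stall series** — segments as short line segments on a
  non-overlapping grid; a stalled frame multiplies segment intensity
  by zero before additive Gaussian noise (SD 1/SNR). Partial-frame
  stalls are not modeled, matching the volume-integrated acquisition.
  The rasterized stall-o-gram equals the event list exactly
  (overlapping events merge).
* **line scans** — dark cells in bright plasma (the label stains
  plasma, not cells; a polarity switch is available); cell length
  6 µm by default; arrival times are jittered but non-overlapping and
  a requested flux with cell occupancy ≥ 0.95 raises an error. The
  transverse record contains exactly round(flux x duration) epochs.
* **bolus pairs** — the AIF is a gamma-variate bolus arriving 7 s
  into a 30 s record at ≈7 Hz plus a recirculation plateau (scaled
  gamma CDF), so post-bolus normalization has a nonzero target; the
  VOF is the exact forward model. The ground-truth transport has no
  separate delay term (the transport function is the plain gamma).
* **decays** — expected counts A·exp(−t/τ) + b per sweep over 290 µs;
  Poisson noise scaled by the number of averaged sweeps (15,000 by
  default).
* **volumes** — tubes rasterized from centerline polylines with
  physical radii (accurate to half a voxel), per-segment skeleton
  labels, spherical plaques, and a table of analytic diameter, length,
  tortuosity and volume.

What the generators do **not** emulate: optical point-spread and
speckle, angiogram texture, motion artifacts, hematocrit-dependent
contrast, probe photobleaching, or vessel-wall signal. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated noise models, not robustness to every artifact of
real microscopy.

## Problem sizes and noise levels used in validation

Recovery checks run at the study's stated conditions wherever one is
stated: 60 volumes x 8.5 s for stall series; 0.23 µm pixels, 0.5–2 ms
line periods, 150/50 ms windows for line scans (scan durations of
0.9–2 s keep dozens of windows per scan); α ∈ {2, 4, 8},
β ∈ {0.25, 0.5, 1} s at ≈7 Hz and SNR 20 with 20 replicates per cell
for the transport fit; τ ∈ [20, 60] µs at 15,000-sweep averaging for
lifetimes; 40 x 64 x 64 volumes with radius-3-voxel tubes and 5/8 µm
plaque spheres for morphometrics. Exactness checks (stall statistics,
median filter, MIP) compare against brute-force loop oracles on
hundreds of random instances.

## Known limitations

* Stall detection assumes the label mask is given; segmentation of the
  angiogram itself is out of scope.
* The relative-threshold stall rule needs at least a majority of
  flowing frames per segment for the median to represent perfused
  intensity.
* The transport-function fit assumes a single well-mixed pathway; a
  free delay is available but degrades MTT identifiability on noisy
  curves (see above).
* Velocity windows containing a stall yield no streak contrast and are
  flagged invalid rather than zero — distinguishing true zero flow
  from absent contrast requires the stall analysis.
* The EDT diameter convention overestimates the caliber of structures
  approaching one voxel in width.
* Skeletonization is expected as input (produced upstream by a CNN
  segmentation tool); the package only post-processes it.
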