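# Methods

This note records the models behind `paskin`, the parameters that
matter, the design choices made where the design was genuinely open, and
what validation on synthetic scans does and does not establish.

## Scan model and coordinates

A scan is a stack of `K` co-registered PA/US frame pairs indexed
`(frame Y, axial Z, lateral X)`, all indices 0-based, depth windows
half-open `[start, stop)`.  The handheld scanner steps a linear array
elevationally with a Scotch yoke, so frame `k` sits at

    y_k = (L/2) · (1 − cos(π k / (K−1))),   k = 0 … K−1,

uniform-in-angle samples of a cosine ramp over the sweep `L`: strictly
increasing, symmetric (`y_k + y_{K−1−k} = L`), densest at the sweep
ends, mean spacing `L/(K−1)`.  Defaults: `K = 83`, `L = 25.0` mm,
128 elements at 0.3 mm pitch, PA excitation at 680 nm.  The axial
sampling of reconstructed frames is not fixed by the hardware
description; it is exposed as `axial_spacing_mm` (default 0.05 mm,
120 samples = 6 mm depth), comfortably finer than the ~0.1 mm
system resolution.  Amplitudes are stored as float32 with no log
compression anywhere in the quantitative path.

## Processing chain

**Surface detection.**  Per US frame, candidates are pixels at or above
`us_threshold_frac` (default 0.5) of the frame maximum, evaluated on a
3×3 median-filtered copy of the frame so single-pixel speckle spikes
neither become candidates nor inflate the reference maximum — the
threshold stays *relative*, hence invariant to per-frame gain.
8-connected candidate components smaller than `min_component_px` are
discarded; the surface of each lateral column is the shallowest
surviving candidate.  Columns with no candidate, or jumping more than
`max_jump_px` (default 10) from the median-filtered contour, are
re-interpolated linearly from valid neighbours (nearest value at the
edges).  Frames with no signal are flagged invalid and excluded.

**Skin-layer window.**  The depth range that the original workflow chose
per person is an explicit parameter here: `window_mm` (default 1.0 mm,
i.e. `round(window_mm / axial_spacing_mm)` samples) below the detected
surface.  This retains the epidermal band and superficial dermis and
removes deeper vessels; a vessel at 1.5 mm is fully excluded by the
default window.

**Projection and resampling.**  `amplitude(X,Y) = max_Z PA` and
`depth(X,Y) = (argmax_Z − surface) · dz`, ties broken toward the
shallowest sample; all-zero columns get amplitude 0, depth 0, and a
validity flag.  Depth is referenced to the *detected surface per pixel*
rather than the transducer face — a deliberate strengthening that
removes probe tilt and surface curvature from the depth metric.  Both
maps are resampled with the same separable 1D linear interpolation,
first along Y (sinusoidal positions) then along X (element pitch), to a
uniform 0.1 mm grid spanning exactly the native extent (251 rows for a
25 mm sweep).  Linear interpolation reproduces linear fields exactly and
cannot overshoot.

**ROI.**  Metrics are confined to a region of interest.  For phantoms
the default is a rectangle inset `roi_margin_mm` (2.0 mm) from the grid
edges; for tape-marked clinical scans `detect_tape_roi` keeps the
largest region above 5 % of the map maximum (the tape suppresses both
PA and US signal), with a manual-mask override.

**Segmentation.**  The MAP is saturated at the ROI's (1, 99) percentiles
and mapped affinely to [0, 1] (absorbing any positive affine rescaling
of the raw amplitudes), blurred with a Gaussian of `blur_sigma_px = 2`
px (0.2 mm, normalised convolution so non-ROI pixels do not bleed in),
and thresholded by Otsu's method on a 256-bin histogram over [0, 1],
ties resolved toward the smallest edge.  The *low*-amplitude class is
the lesion by construction.  Components of either class smaller than
`min_component_px` (default 100 px = 1 mm²) are reassigned to the other
class (outlier removal and hole filling, two passes); multiple lesion
components are allowed, as IGH presents as multiple macules.  Boundaries
are ordered counter-clockwise from sub-pixel contours snapped to the
boundary pixel set (lesion pixels 4-adjacent to normal skin); outward
unit normals come from the negated gradient of the smoothed lesion mask.
Blur precedes thresholding; the alternative order was considered and
rejected because the blur exists precisely to keep Otsu from tracing an
overfitted boundary.

*Lesion-free gate.*  Otsu always splits a histogram, including pure
noise.  A scan is flagged lesion-free when the blurred-map class
contrast (normal mean − lesion mean) falls below `min_contrast = 0.4`
normalised units.  On phantoms, contrast-free scans (uniform pigment)
measure ≈ 0.21 and real lesions ≈ 0.85, so the gate sits between the two
regimes with a wide margin on both sides.

**Metrics.**  As defined in the README.  Numerical details: the local
SD uses the sample SD (ddof = 1) computed by moment filters; interior
lesion pixels are those whose full 5×5 window lies inside the lesion
*and* contains no boundary pixel — the stated exclusion of
boundary-contaminated windows, applied literally.  Boundary-slope
samples use nearest-pixel rounding at ±5 px along the normal
(sub-pixel interpolation adds nothing at a 0.1 mm grid); pairs whose
inward sample is not lesion or whose outward sample is not normal skin
are dropped; components pool their samples before trimming; the
inter-quartile trim keeps ranks `i` with `0.25 ≤ i/(n−1) ≤ 0.75`
inclusive.  The 15 % depth tails take `⌈0.15 n⌉` values (the rounding is
unspecified upstream; ceiling guarantees a non-empty tail).  The slope
metric is positive when normal skin outranks the lesion, and
antisymmetric under swapping the lesion/normal roles.

**Statistics.**  Two-sided Wilcoxon rank-sum per metric.  Pooled
`n ≤ 12`: exact, by complete enumeration of all `C(n, n₁)` assignments
of the pooled mid-ranks (ties exact).  Larger: normal approximation
with tie-corrected variance and a 0.5 continuity correction (the
correction is configurable; with it, the approximation agrees with the
exact test to ≲0.01 at n = 6+6).  Two-sided p = min(1, 2·smaller tail).
No multiple-testing correction is applied across the four metrics; the
reports say so in their footer.

## Phantom generator

The phantom emulates the *statistical* structure the pipeline assumes —
not acoustics (no wave propagation, fluence, reconstruction or motion
artefacts).  Scene, per scan, all deterministic given one seed:

- **Surface**: depth 2.0 mm with a smooth cosine undulation of 0.6 mm
  peak-to-peak.  US shows a one-sided Gaussian interface echo
  (σ = 0.1 mm, starting at the interface) with Rayleigh speckle beneath
  it, echo peak 3× the speckle mean — only the contour's detectability
  matters downstream.  The true surface index is the first axial sample
  at or below the interface.
- **Epidermal band**: Gaussian in depth (FWHM = 0.2 mm thickness,
  peak at surface + half thickness) with amplitude
  `melanin_amplitude · pigment(X, Y)`.
- **Lesion**: ellipse (default semi-axes 8 × 6 mm) on the (X, Y) plane.
  `pigment = r + (1 − r) · σ(d/s)` with residual fraction `r`, signed
  radial distance `d` to the ellipse (negative inside), and logistic
  scale `s` chosen so the 10–90 % transition width equals
  `border_width_mm`.  The edge model is a modelling choice; only the
  existence of a slope difference between phenotypes is clinically
  established.
- **Skip areas**: a Poisson process over the lesion area
  (`island_density_per_cm2`), Gaussian bumps of amplitude
  `island_amplitude_frac` and σ drawn around `island_radius_mm`
  (defaults 0.35 mm, matching reported island scales of ~100 µm to
  several times larger), strictly masked to the lesion interior.
  Pigment is clipped to [0, 1], so raising `r` can never lower any
  pixel.
- **Vessel**: a Gaussian stripe (σ = 0.06 mm) at `vessel_depth_mm`
  below the surface with amplitude `vessel_amplitude_frac` (default
  0.2, depth 0.6 mm — a superficial dermal plexus *inside* the 1 mm
  window so that pigment loss can unmask it; set 1.5 mm to model a
  deep vessel the window removes).
- **Noise**: additive Gaussian, SD `noise_sd_frac · melanin_amplitude`
  (default 0.02), clipped at zero; `noise_sd_frac = 0` also disables
  speckle, giving fully deterministic scenes for exact tests.

**Phenotype templates.**  `vitiligo_like_config()`: residual 0.08,
border width 4.0 mm, no islands — the vessel becomes the PA peak inside
the lesion (relative depth ≈ 0.5 mm) and the wide ramp flattens the
boundary slope.  `igh_like_config()`: residual 0.35, border width
0.3 mm, islands at 6 /cm² — the epidermal band stays above the vessel
(relative depth ≈ 0.05 mm), the sharp ramp steepens the slope, and
islands raise the local SD.  The residual fractions are modelling
choices that realise the documented qualitative physiology (vitiligo:
near-total melanocyte loss; IGH: partial), not measured clinical
quantities.  Cohorts derive per-scan seeds from a master seed via
seed-sequence spawning and jitter lesion centre (±1.5 mm) and semi-axes
(±15 %).

**What phantom validation shows — and does not.**  Passing tests show
the chain recovers known geometry (surface to ≤1 px, boundary to
≤0.3 mm Hausdorff, lesion area to ≤15 %), that the metric estimators
agree with brute-force oracles to 1e-9, and that the metrics move in the
clinically expected directions as the generative parameters move.  They
do not show clinical accuracy: real scans add reconstruction artefacts,
fluence inhomogeneity, motion, hair and body-site variation in skin
anatomy that the phantom deliberately omits.

## Simulated-cohort statistics

Per-group clinical metric summaries exist only as printed means/SDs at
n = 36 (vitiligo) and 17 (IGH).  `scripts/acceptance.py` treats those
summaries as generative parameters: 200 replicate cohorts are drawn per
metric as independent normals at the printed parameters and group sizes,
each tested with the package's rank-sum implementation, and the median
p reported.  This checks that the statistical machinery reproduces the
reported significance pattern at the reported effect sizes — slope and
depth far below 0.001, local SD below 0.05 — not that the pipeline
reproduces the clinical measurements themselves.  Null calibration
(both groups from one distribution, 2000 replicates at 36/17) holds the
type-I error at 0.05 within [0.035, 0.065].

## Problem sizes

Tests run phantoms at two scales: the full default geometry
(83 × 120 × 128, used for the cohort-separation test at 10 + 10 scans)
and a reduced geometry (31 × 100 × 96 over a 12 mm sweep) for unit-level
pipeline tests.  Both exercise identical code paths; the reduced scale
keeps per-test phantom synthesis near 0.1 s.

## Known limitations

- The ellipse signed distance is the radial-ray approximation, exact on
  circles and slightly biased at high eccentricity; border-width
  effects below ~0.1 mm are not resolvable on the 0.1 mm grid anyway.
- Per-scan percentile normalisation (as in the clinical workflow) makes
  the mean-amplitude metric relative: scans are not comparable on an
  absolute melanin scale, and between-group mean-amplitude differences
  are attenuated when the lesion itself sets the low percentile.
- `detect_tape_roi` assumes a connected bright interior; unusual tape
  layouts need the manual mask.
- Multispectral unmixing of melanin vs haemoglobin, absolute melanin
  quantification, and diagnostic classification are out of scope.
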