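# Methods

`gastromotil` quantifies regional gastric motility from free-breathing
dynamic 2-D image series of the stomach. The pipeline has five measurement
stages — motion correction, wall geometry, contraction mapping, wave
metrics, statistics — plus a synthetic phantom that provides ground truth
for every stage. This note records the models, the parameters that matter,
the numerical choices, and the known limitations.

## Coordinate and unit conventions

Images are `(T, H, W)` grayscale stacks with a pixel size in mm and a frame
interval in seconds. Pixel coordinates are 0-based with origin at the
top-left, `x` = column, `y` = row; physical mm = pixel × pixel size. All
contour and centerline coordinates are mm; landmarks are pixels. Arc-length
fractions along either curvature run from the distal end (`s = 0`, pylorus)
to the proximal end (`s = 1`); speeds are mm/s, sizes mm, frequencies
cycles/min, GMI mm²/s.

## Motion correction and DVARS

Breathing moves the stomach roughly rigidly within the imaging plane. Four
landmarks per frame (in practice placed on the liver and gall bladder)
define a per-frame rigid transform to the frame-1 landmarks by least
squares:

    argmin_{Δx, Δy, θ}  Σᵢ ‖T(P_{t,i}) − P_{1,i}‖²

The transform model is "rotate by θ about the image centre, then translate
by (Δx, Δy)". Rotating about the origin plus translation spans the same
family of maps — the parameterisations differ by a reparameterised
translation which the optimiser absorbs — but the centred form is
well-conditioned for small angles. The optimiser is a Nelder–Mead simplex
started at (0, 0, 0) (parameter tolerance 1e-9 px); if the residual exceeds
1e-6 the search restarts once from the closed-form Procrustes (SVD)
solution and the better optimum is kept, so noiseless rigid displacements
are recovered to the closed-form answer. Images are resampled bilinearly
with zero fill outside the source frame; landmark and contour coordinates
are transformed analytically, so they carry no resampling error.

Residual instability is scored with DVARS along a probe line of n pixels
crossing the stomach:

    DVARS = 1/(T−1) Σ_{t=2..T} sqrt( 1/n Σ_p (I_{p,t} − I_{p,t−1})² )

The default probe is the vertical line through the mean column of the
frame-1 contour, spanning the contour's rows; any pixel list can be
supplied, and the value is invariant to pixel ordering. No frames are
excluded. Optionally, pixels zero-filled by the resampling can be dropped
from the line.

## Wall geometry and centerline

Each curvature polyline is interpolated with a natural cubic spline
(chord-length parameterised), its arc length integrated on a 20 000-point
sample, and resampled to 200 equally spaced wall-points. Wall-points of
equal index on the two curvatures are paired — after equal-arc-length
resampling, index pairing is the only parameter-free correspondence — and
each pair's midpoint becomes a candidate middle-point. A candidate is valid
when the circle centred on it with diameter 90 % of the pair distance lies
entirely inside the closed stomach outline (centre inside the polygon and
boundary clearance ≥ radius, computed analytically with exact polygon
distance rather than sampling). The most distal and proximal midpoints are
always kept so the axis spans the organ. Frames whose segmentation violates
the geometric invariants are dropped from the pooled fit with a warning.

Valid middle-points pooled over all frames are summarised by one
time-independent 5th-order polynomial. The regression frame is chosen by
residual among (a) image axes `y(x)`, (b) swapped axes `x(y)`, and (c) the
cloud's principal-axis (PCA) frame: PCA handles arbitrary organ
orientations, while the axis-aligned frames reproduce exactly polynomial
clouds to machine precision (a rotated polynomial is not a polynomial in
the rotated abscissa). The fitted curve is discretised to 200 points at
equal arc length (2·10⁵-sample inversion; points are evaluated exactly on
the polynomial).

A 5th-order polynomial approximates a strongly curved arc with an
equioscillating residual below ~1 mm that concentrates at the domain ends;
the fitted tips can overshoot the organ's end caps by 1–2 mm. Those ends
lie in the two excluded boundary regions (below), so the overshoot does not
touch any reported metric.

## Contraction maps

For each curvature, `Dc(n, t)` is the distance from wall-point n at frame t
to centerline point n (index pairing; a perpendicular-projection mode
exists for sensitivity analysis). Then

    reference(n)    = (1/T) Σ_t Dc(n, t)
    size(n, t)      = reference(n) − Dc(n, t)
    occlusion(n, t) = 100 · size(n, t) / reference(n)

Positive size is inward motion (contraction), negative is distension. Two
exact consequences are used as self-checks: the per-point time mean of size
is zero, and scaling all geometry by k scales size by k while leaving
occlusion unchanged.

Because the reference is an unconditional time mean that includes
contracted frames, the peak of `size` under-states the true indentation
depth by `depth × occupancy`, where occupancy is the fraction of time a
wave occupies a site (for a Gaussian wave train: σ√(2π)·f/(60·v) ≈ 0.25 at
the defaults). This is a property of the definition and is deliberately not
"corrected" in the maps; the metrics stage offers a bias-free depth
estimate instead (below).

Maps are rendered as greyscale rasters (rows = time, columns = normalized
curvature length), symmetric about zero at the 99th percentile of |size| so
subjects are comparable, darker = stronger contraction; the annotated
variant overlays the region grid, the excluded end regions, and wave
tracks.

## Wave tracking and regional metrics

A contraction wave appears on the map as a dark band. Tracks are lists of
(s, t) marks — normally placed by a reader, supplied as CSV — interpolated
by monotone piecewise-cubic (PCHIP) interpolation: exact at the marks,
monotone between them, with a warned piecewise-linear fallback for
non-monotone times, and no extrapolation beyond the marked span.

The s-axis is divided into 20 contiguous regions; regions 1 and 20 are
excluded (boundary effects at the strongly curved organ ends), leaving 18
analyzed regions. Per region:

* **speed** = region_width / |t₂ − t₁| where region_width is the
  time-mean curvature length / 20 and t₁, t₂ are the track's boundary
  crossing times; only regions whose both boundaries lie inside the marked
  span are estimated, and speeds from multiple waves are averaged;
* **frequency** = 60 / mean gap between consecutive track crossings at the
  region centre (≥ 2 crossings required; otherwise missing, never zero);
* **size / occlusion** = per wave, the peak map value along the track
  within the region, averaged over waves (a time-mean-of-positives
  alternative is available by flag);
* **GMI** = mean regional speed × mean regional size, computed for the
  distal (regions 2–10) and proximal (regions 11–19) halves of each
  curvature and overall. The distal/proximal split point is a convention of
  this package.

For phantom self-tests (no human reader available) an automatic ridge
marker detects per-station temporal peaks above 50 % of the map maximum,
refines their times by 3-point parabolic interpolation (sub-frame
accuracy, important because a region crossing spans only a few frames),
chains them across stations from the proximal end by nearest-time matching
with short linear extrapolation, and down-samples each chain to 10 marks.

The whole-map indentation depth is reported two ways: the raw `size` peak
(biased as described), and a peak-to-trough estimate — the maximum over
stations of max_t − min_t of the size trace. The distension floor at a
station equals minus the same occupancy bias, so the peak-to-trough
amplitude cancels it using only the map itself.

## Statistics

Shapiro–Wilk screens normality per group (constant samples are warned and
treated as non-normal); Kruskal–Wallis with Dunn rank z-tests
(tie-corrected, Bonferroni-adjusted) compares the three image variants'
DVARS; Welch's two-sample t-test (pooled-variance by flag) contrasts the
curvatures; one-way ANOVA with Tukey HSD compares GMI region groups; and
distal-to-proximal trends are a degree-1 fit of the regional means against
region index (degree configurable) with its slope p-value plus the Spearman
rank correlation. α = 0.05 throughout. Standard tests delegate to scipy;
Dunn's post-hoc is implemented here because no common scientific Python
package ships it. The suite cross-checks every operation against R's
`stats` package on seeded data.

## The phantom

The phantom emulates exactly the features the pipeline measures, with
analytic ground truth:

* **Geometry**: a tube around a circular-arc (or straight) medial axis.
  Defaults: axis length 243 mm, arc radius 113 mm, constant lumen radius
  20 mm, giving wall arc lengths of 200 mm (lesser, inner bank) and 286 mm
  (greater, outer bank) — the cohort-mean wall lengths the pipeline is
  calibrated against. A constant-radius open arc cannot simultaneously
  match those wall lengths and a shorter medial axis the way a closed
  J-shaped stomach does; the wall lengths were chosen as the binding
  calibration, so the phantom's axis is 243 mm. A linear taper or arbitrary
  radius profile is supported.
* **Peristalsis**: a train of Gaussian indentations (amplitude 5 mm,
  σ = 6 mm along the wall, i.e. ~14 mm FWHM) spawned every 60/f s and
  travelling distally at v = 3 mm/s, f = 3 cycles/min by default. Crests
  are parameterised by each wall's own arc length, so the configured speed
  is exactly what the per-curvature speed metric estimates. The summed bump
  field is clipped at 1 so the displacement never exceeds the amplitude,
  and the amplitude must stay below the minimum radius so the lumen never
  self-intersects.
* **Breathing**: planar rigid motion, amplitude × sin(2πt/period) in
  translation and rotation about the image centre, default (2 mm, 10 mm,
  2°) at a 4 s period — a typical shallow-breathing in-plane excursion,
  chosen here since no reference value exists for the coronal plane — with
  every transform recorded. Four landmarks placed off-lumen co-move
  rigidly. Through-plane motion is deliberately not simulated: the rigid
  2-D correction model could not remove it, and the phantom only generates
  what the model can represent.
* **Rendering**: the lumen polygon is filled by area sampling (8×
  supersampled scanline fill, block-averaged), so sub-pixel wall motion
  (mm-scale contractions at ~1 mm pixels) is visible in the intensities;
  landmarks are stamped as Gaussian blobs; seeded Gaussian noise
  (σ = 2 intensity units against an 80-unit lumen/background contrast) is
  added last. The full output is a pure function of the configuration,
  including the seed.

What the phantom does **not** emulate: MR signal physics (no TrueFISP
contrast, B0 or flip-angle effects), through-plane or non-rigid motion,
segmentation error (its contours are exact), antral tapering by default,
and reader variability in wave marking. Tests passing on the phantom
therefore validate the measurement chain — not robustness to segmentation
noise or to out-of-plane physiology.

### Known measurement biases (quantified on the phantom)

Two small systematic errors follow from the measurement definitions
themselves and are visible with the phantom's known ground truth:

* **Speed**: region width uses the time-mean wall length, which includes
  the extra path length of the indentations (slope term ≈ A²√π/(8σ) per
  crest, plus a first-order radial term of opposite sign on the two banks
  of a curved organ). At the defaults this over-reads speed by ~1–4 %
  (inner bank worst); across the tested speed/frequency grid the median
  regional error stays below 5 %.
* **Depth**: the raw size peak under-reads by the occupancy bias (~17–29 %
  across the grid), matching its analytic expectation; the peak-to-trough
  estimate recovers the configured amplitude within a few per cent.

## Problem sizes

The default phantom is the full study scale (100 frames, 272×144 px,
243 mm axis). The test suite uses this scale where the measurement is the
point (parameter-recovery sweep, zero-mean identity, centerline fidelity)
and a reduced configuration (`PhantomConfig.test_scale()`: 120 mm tube,
50 frames, 152×80 px) for rendering-heavy checks; both sizes are exercised
end to end. The parameter-recovery sweep runs on the contours-only path —
rasterisation and re-segmentation are identity operations for those
metrics, since the phantom's contours are exact.
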