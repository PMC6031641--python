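# Methods

`clemquant` quantifies genetically encoded particle tags (ferritin-core
"FerriTag"-style labels, ~7 nm electron-dense dots) in segmented electron
micrographs, together with the live-cell kinetics of tag recruitment. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Coordinate model and geometry kernel

Annotations are 2-D and per-section: pixel coordinates (0-based, x right,
y down in raster order) are scaled once to nanometres by `nm_per_px`.
A membrane is a directed polyline; "cytoplasmic side" is declared per
contour (`side_convention`, default: the left of the travel direction).
Closest approach uses exact point-to-segment projection; at a vertex foot
shared by two segments the side is decided by the sum of the two
normalized cross products (angle-bisector rule), which is stable at
corners. Coat and pit marks are stored as arc-length intervals so they
survive resampling of the polyline.

The `z` column of the point-file dialect is treated as a serial-section /
image index; sections are analysed independently (per-micrograph), and no
3-D reconstruction across sections is attempted.

## Compartments, areas, densities

A particle is *extracellular* if its nearest membrane point lies on the
non-cytoplasmic side; *membrane-proximal* if cytoplasmic and within the
50-nm zone (closed boundary: exactly 50 nm is proximal), subdivided into
*coated* vs *uncoated* by whether the nearest-foot arc position falls in a
coat interval (closed at interval ends); *cytoplasm* otherwise.
Extracellular particles are counted but excluded from all densities.

Areas: the extracellular / cytoplasm / proximal-band partition is exact
polygon geometry (frame split by the contour, single-sided 50-nm buffer).
The coated/uncoated split of the band follows the *same nearest-foot rule
as particle classification*, which near junctions is a bisector rather
than a buffer cap; it is integrated by classifying a quadrature grid
(default step 0.5 nm, error about 1% of a pit band, set by
`quadrature_step_nm`). Keeping the area rule identical to the particle
rule is what makes density estimates internally consistent. Volumes are
areas x section thickness (default 70 nm); densities are pooled counts
over pooled volumes per condition, while per-image densities feed the
one-way ANOVA + Tukey HSD comparison between conditions.

## Stereology and the RLI test

An 8 x 6 line grid is registered to the image perimeter, giving 6 x 4 = 24
interior points per image; each point is classified with the particle
rule. Compartment fractions pooled over an experiment's images, restricted
and renormalized to intracellular compartments, scale to the observed
particle total to give expected counts (which therefore sum exactly to the
observed total). Relative labeling intensity is observed/expected per
compartment. The test statistic is the Yates-corrected chi-squared of the
2 x 2 table {observed, expected} x {cytoplasm, coated} with margin-derived
cell expectations and the correction clamped at zero, df = 1, upper tail
via the complementary error function. This reproduces the published
seven-experiment table's statistics from its printed counts within 0.2%
for the three largest experiments (about 1.4% for one control row, from
the one-decimal rounding of printed expected counts).

### Null calibration and a conservatism caveat

`simulate_null_experiments` runs the whole pipeline on experiments in
which particles follow exactly the spatial law the grid samples: fresh
membrane geometry per image whose vertical position is uniform over two
horizontal-line spacings and whose pit positions are uniform over one
vertical-line spacing (jittered slots, coat bands kept disjoint and inside
the grid-covered window), with particles rained uniformly over that
window. Three design details are load-bearing and were each verified to
remove a measurable bias: geometry translation must be uniform over whole
grid periods (otherwise fixed grid lines alias against the membrane);
particle counts must not be conditioned per image (fixing a per-image
count estimates E[a_c/a_intra] where the grid estimates E[a_c]/E[a_intra]);
and coat bands of adjacent pits must not overlap (the translation-averaging
identity fails on intersection terms). Under this matched null the
ensemble RLI — total observed over globally-pooled-fraction expectation —
is 1 within Monte-Carlo error in every compartment. The *per-experiment*
RLI ratio is biased upward by roughly 7–12% for the membrane compartments
at the published experiment sizes (a small-sample ratio bias: the
denominator is the experiment's own clustered grid total), which is why
the calibration summary pools.

The rejection rate of the Yates test at alpha = 0.05 under this null is
about 0.005–0.013, far below nominal. The reason is structural: the 2 x 2
table scales the expected row to the observed total, so the homogeneity
statistic treats it as a sample of size n, while it actually derives from
24 x N_image grid points — about 4x more than n at the published designs —
so the null variance is overestimated by roughly (1 + n/m)/2, and the
Yates correction at expected coated counts of 0.5–34 adds more. Without
the Yates correction the same tables reject at about 0.024. The practical
reading: the published test is conservative in its own regime, so its
reported significances are if anything understated; but its p-values
should not be read as calibrated type-I error. A nominal 5% rate would
require grid points comparable in number to particles.

## Labeling resolution

`measure_distances` records closest-approach proximities of
cytoplasmic-side particles. `simulate_detected_distances` models one
detection: tag length L from the length-state law (default: continuous
uniform on 7–18 nm, the published range of length states; a discrete
state count is available), orientation uniform in solid angle within a
cone about the membrane normal (membrane-excluded by construction;
`perpendicular` and `hemisphere-uniform` laws are also available),
particle placed in 3-D on a flat membrane, accepted if its center falls
in a uniformly positioned 70-nm section, and the in-plane perpendicular
distance of the projected center recorded. Simulated distances can never
exceed the 22 nm fully extended co-linear arrangement.

For lengths uniform on [7, 18] and cone half-angle a, the detected
distance L·cos(theta) has a closed-form density whose FWHM is
11·sqrt(cos a) nm. The default half-angle of 35 deg is calibrated so the
simulated spread reproduces the ~10 nm FWHM labeling resolution; the
resulting median (~11.3 nm) sits somewhat above the measured 9.5–9.8 nm
— with the length range fixed at 7–18 nm, a single cone law cannot match
both, and the spread is the quantity this package treats as the
resolution. This is a known limitation of the one-parameter orientation
law; the experimental median would be matched by a wider cone (~57 deg)
at the cost of a narrower (~8 nm) FWHM.

FWHM is computed on a Gaussian kernel density estimate (Silverman
bandwidth by default, recorded; grid of 2048 points padded by three
bandwidths) between the outermost half-maximum crossings, linearly
interpolated — a histogram-free definition insensitive to bin edges.

Per-particle SNR is |mean(disc) − mean(annulus)| / SD(annulus), with
defaults r_signal = 3.5 nm (half the nominal 7-nm particle), annulus
7–14 nm, converted to pixels by the image calibration; it is reported as
missing when the annulus SD is zero.

## Pit mapping

Within a contour carrying pit marks, a cytoplasmic particle is *pit* if
its nearest-foot arc position falls inside the closed pit interval, else
*distal*, with the normalized position s = (foot − pit start)/(pit
length) and, for distal particles, a signed arc offset to the nearest pit
edge. The idealized projection places pit particles on a 100-nm-diameter
semicircle at arc fraction s, pushed outward (cytoplasmically) by their
measured proximity, distal particles on flat flanks at their arc offset,
and mirrors every point about the pit axis (each particle appears exactly
twice; proximities are preserved exactly by construction). Group
proximities are compared by Welch's unequal-variance t-test; per-image
frequencies are emitted both raw and per unit analyzed arc length, since
either normalization is defensible.

## Synthetic scenes

`generate_scene` emulates one micrograph: a membrane polyline crossing
the frame (default 1024 x 768 px at 2 nm/px), with semicircular 50-nm-
radius pit invaginations joined to the flat by tangent-continuous fillets
whose 50-nm radius equals the proximal-zone width — so the nearest-foot
map is one-to-one across the whole band (and a fortiori for tag reaches
<= 22 nm), and the coated band of a pit is exactly the half-annulus of
its arc. Volumetric particles are a homogeneous Poisson process per
compartment (defaults: cytoplasm and uncoated membrane 72.5, coated
1308.6 particles/um^3 — the measured density regime); band particles are
generated by thinning a single band-wide process using the classifier
itself, so generated region labels and downstream classification agree
exactly. Membrane-anchored particles are Poisson along coat or distal
arcs and displaced along the local cytoplasmic normal by a draw from a
tag-geometry model; pit-anchored tags default to an extended regime and
distal tags to a kinked (shorter) one, so the pit-mapping stage can be
exercised against a known ~10 nm proximity offset.

`generate_kinetics_stack` emulates two-channel spot stacks: persistent
Gaussian spots in the reference channel (amplitude 50 over background 20),
a shared-profile step of configurable amplitude at the stimulus onset in
the response channel (background 10), and additive Gaussian noise
(default SD 1). The expected background-subtracted channel-ratio step is
amplitude / reference-amplitude.

What these emulations do *not* contain: EM texture and segmentation
error, analyst variability in pit marking, vesicular membranes, particle
detection error, photobleaching, or spot movement. Passing tests
establish that the estimators recover known ground truth under the
stated geometric and counting models — not that segmentation or detection
of real images is accurate, which is outside this package's scope (inputs
are annotations, not pixels).

## Kinetics analysis

Spots are re-detected per frame on the binarized (Otsu by default)
reference channel, components below 4 px discarded; no tracking is
needed because the per-frame summary is a median over spots. Background
per channel and frame is the histogram mode (256 bins) of non-spot
pixels, robust to sparse bright spots. Each spot contributes
(mean ch2 − bg2)/(mean ch1 − bg1); spots with non-positive denominator
are skipped and counted. Each cell's trace is shifted so its pre-onset
median is exactly zero, then averaged across cells (mean ± s.e.m.). The
randomized control permutes response-channel pixels within each frame
(seeded; shuffling frames or spot assignments would be alternatives, and
pixel permutation is the configurable default) and repeats the identical
analysis; a genuine recruitment signal vanishes because spatial
coincidence with the reference spots is destroyed.

## Numerical and interface choices

- Quadrature step 0.5 nm for coated-area integration (about 1% of a pit
  band); computed in float32 after centering, via GEMM-based projections.
- Pit arcs discretized at 64 segments (chord error < 0.1 nm).
- Proximity exactly 0 reports side "on membrane" and classifies
  cytoplasmic.
- Degenerate inputs raise: contours with all-identical vertices,
  zero-margin contingency tables (naming the degenerate margin), groups
  of fewer than two observations.
- All randomness flows through `numpy` Generators; every public
  simulation takes a seed and is bit-reproducible for a fixed seed.
- File formats are plain text: a whitespace "object contour x y z" point
  dialect, flat key=value metadata, CSV tables, multi-page TIFF for
  stacks.

## Known limitations

- Open membrane contours must cross the frame for the area partition;
  closed vesicular contours are not yet supported in `region_polygons`
  (classification and distance measurement handle any polyline).
- The simulated detection geometry uses a flat membrane; curvature of
  real pit membranes shortens in-plane distances slightly for pit-anchored
  tags.
- The tag-geometry default is calibrated to the distribution spread, not
  the median (see above).
- Serial sections are treated independently; structures spanning sections
  are counted once per section, as in per-micrograph reporting.
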