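# Methods

`dermadose` compares in-vivo film measurements of breast skin dose with
treatment-planning-system (TPS) calculations. Everything runs on a synthetic
study by default — real DICOM-RT and scanned-film inputs use the same module
functions through `dermadose.io` — so each stage can be validated against
known ground truth. This note records the models, conventions and numerical
choices.

## Synthetic phantom

The phantom emulates a breast supported by a carbon-fibre cradle tilted 12°
from the superior-inferior axis. The body is a half-cylinder (default radius
4 cm, flat face up) whose axis follows the cradle tilt; a 0.3 cm shell
conforming to the curved underside over a fixed angular arc represents the
cradle. The contact arc is sized so that the unfolded contact region has the
target area (default 170 cm²) over an axial band of
`lateral_extent + inferior_extent` = 11 + 14 = 25 cm; the upper 11 cm of the
unfolded map is the lateral (beam entrance) region and the lower 14 cm the
inferior (scatter exit) region. The body overhangs the cradle axially
(1.2 cm) so the contact region is the curved band only, never the cylinder
end caps. The cradle band is bounded by axial CT planes, so every CT slice
carries a complete contact arc.

CT voxels default to 0.12 × 0.12 × 0.25 cm. HU values: air −1000, body 0
(water-equivalent; only the cradle band is prescribed by thresholding
practice), cradle −700 — inside the −800…−600 segmentation band.

## Parametric dose engines

No radiation transport is performed. Dose grids (default 0.1 cm isotropic;
the cohort places its last sixth of cases on 0.15 cm, echoing clinical
calculation-grid practice) follow a closed-form buildup model. With `d` the
depth below the body surface (anisotropic Euclidean distance transform of
the body mask on the dose lattice):

    D(d) = Rx · [S + (1 − S)(1 − e^(−d/λ))] · (1 − k·e^(−d/λ)·[scatter])
           + Rx·(b_s/100)·[first voxel layer] + Rx·(b_g/100)

* `S` — surface dose fraction (unitless, 0–1),
* `λ` — buildup length (cm): depth scale over which dose approaches Rx,
* `k` — lateral-scatter deficit (fraction) applied only on the inferior
  (scatter exit) region,
* `b_s` — surface bias (% of prescription) confined to the first voxel
  layer (body boundary voxels and the exterior, so trilinear samples near
  the surface see it consistently),
* `b_g` — uniform global bias (% of prescription), the knob used for
  controlled bias-injection experiments.

Outside the body `d = 0`, i.e. the surface dose extends into air; this keeps
trilinear sampling at surface-voxel centres free of air-gap artefacts, which
would otherwise affect truth and calculation maps identically anyway.

Three default profiles define the study conditions: `truth`
(S = 0.84, λ = 1.0) is what the film measures; `aaa_like`
(S = 0.79, λ = 1.2, b_s = −1 %, k = 5 %) underestimates surface dose with a
larger deficit on the scatter surface; `axb_like`
(S = 0.86, λ = 1.0, b_s = +0.5 %, k = 1 %) slightly overestimates. These
magnitudes are generator conventions chosen to reproduce the qualitative
under/over-estimation sign pattern of the two clinical algorithm families;
they are configurable and are not asserted as physics.

## Film measurement model and processing

Per-fraction film maps are the truth surface map plus a systematic offset,
an optional sinusoidal ridge along the across-slice direction (emulating the
periodic reconstruction artefacts a tilted cradle produces at CT slice
spacing; default period 1.2 cm ≈ 0.25 cm / sin 12°), i.i.d. Gaussian noise
(default SD 7.5 % of prescription, matching the measured-minus-calculated
spread the method is designed to resolve) and a small random rigid
misalignment (default ≤ 0.08 cm, ≤ 0.5°) to exercise registration. Three
fractions per case.

Processing chain: calibrate → trim → filter → register → average.

* Calibration uses the rational one-scan form X(D) = (a + bD)/(c + D) on the
  green channel; the fit is solved linearly in (a, b, c) and refined by
  Levenberg-Marquardt. Out-of-range responses are masked invalid, not
  clipped.
* Trimming erodes the valid mask by 2 pixels (Chebyshev distance), removing
  cutting artefacts.
* Filtering applies a 5×5 adaptive local mean/variance (Wiener-type) filter
  then a 5×5 median filter; the order is configurable since either order is
  defensible. Windows replicate the edge pixel so constant maps are exact
  fixed points; invalid pixels are pre-filled with their nearest valid
  neighbour so masked regions never bleed in.
* Registration is rigid (rotation + translation, no scale): a coarse
  rotation sweep with subpixel phase-correlation translation estimates,
  scored and refined by Nelder-Mead on masked normalised cross-correlation
  with bilinear resampling. The first fraction is the fixed reference; the
  averaged map is then registered once to the unfolded TPS map and the same
  transform reused for both algorithm profiles.
* Averaging is the pixel-wise mean where all fractions are valid; the valid
  mask never grows at any stage.

## Structures

Body and cradle are HU thresholds (inclusive bounds on both ends for
determinism). The body default is HU ≥ −300 with largest-component
filtering; the config validator warns when a body band spans only air (a
band quoted as "−1000 to −3071" is a known description erratum). The
surface-voxel (contact) contour is the body's outer boundary layer (3D
erosion residue) intersected with the one-voxel-dilated cradle — a literal
AND of the disjoint masks would be empty, and restricting to the boundary
keeps the contour one voxel thick along the surface normal. Fragmentary
leading/trailing slices arising from diagonal 3D adjacency past the cradle
edge are trimmed (configurable).

Skin rinds (0.2 and 0.5 cm) are body voxels within the given distance of
the contact contour, measured by anisotropic Euclidean distance transform —
a box-element erosion would be wrong at 0.25 cm slice spacing. Building
rinds from the contact contour confines them to the contact footprint by
construction. Invariants maintained: surface ⊆ rind(0.2) ⊆ rind(0.5) ⊆ body.

## Surface unfolding

Within each CT slice, contact voxels are ordered by polar angle about the
least-squares (Kasa) circle centre of the slice contour — monotone along a
circular arc, and degenerating gracefully for straight contours — with the
angular branch cut placed in the largest gap. Where the digitised contour
is locally two voxels thick, the outermost voxel per angular step is kept.
A 5-point moving average along the chain suppresses the voxel staircase
that would otherwise inflate arc lengths by ~20 %; with smoothing the
unfolded arc width matches the analytic value within a voxel and the
unfolded contact area is ≈ 180 cm² for the 170 cm² target (the residual
comes from anchor-path jitter and the one-voxel contact overshoot at the
band edges).

The 2D coordinates preserve 3D distances the way a developable surface
unrolls: the in-slice coordinate is cumulative 3D arc length from the slice
anchor (the lateral-end contour start; configurable) and the across-slice
coordinate is cumulative anchor-to-anchor 3D distance, which honours the
12° tilt. For developable inputs consecutive-point distances are preserved
to machine precision; distortion for non-developable inputs is queryable
via `isometry_error`, never silently dropped. Scattered unfolded points are
rasterised to the film lattice (2.54/72 cm) by Delaunay-based linear
interpolation; pixels outside the convex support are invalid, and each
valid pixel records its nearest source sample for provenance.

## DVH and Dx%

DVHs use equal voxel weighting over trilinear voxel-centre dose samples
(doses as percent of prescription), cumulative bins of 0.5 % width. The
curve stores the fraction receiving at least — and strictly more than —
each edge, so point masses sitting exactly on an edge are distinguished
from continuous mass in the following bin. Dx% follows the hottest-volume
convention (minimum dose of the hottest x%): the largest dose at which the
cumulative curve still reaches x/100, linearly interpolated on strictly
decreasing segments and exact for uniform-dose structures.

## Gamma analysis

γ(r) = min over evaluated positions e within 3×DTA of
sqrt(|e−r|²/DTA² + (D_eval(e) − D_ref(r))²/tol²), with the measured film as
reference and global normalisation (maps are already percent of
prescription). Default criteria: DTA 0.5 cm with 7 % and 10 % tolerances
and no low-dose threshold. The evaluated map is upsampled ×3 by bilinear
interpolation (samples coincident with coarse pixels keep the exact pixel
value so zero-weight invalid neighbours cannot invalidate them). Candidates
are visited in order of increasing distance with an exact early
termination — the sweep stops only when the pure distance term exceeds
every pixel's current best — so the result equals exhaustive minimisation.
Both tolerances share one sweep, which also guarantees per-pixel pass
monotonicity between 7 % and 10 %. Pixels whose search neighbourhood is
entirely invalid are excluded from pass-rate denominators. In the pipeline,
maps are resampled to 0.1 cm for the gamma stage; at a 0.5 cm DTA this
sampling is comfortably fine while keeping the candidate set tractable.
Local normalisation is deliberately not implemented.

## Difference statistics

Differences are calculated − measured (TPS − film), pooled across cases
into 1 %-wide bins centred on integers, and fitted with
A·exp(−(x−μ)²/2σ²) by nonlinear least squares initialised from the
histogram moments; R² is computed against bin counts. Histograms too
narrow to fit (fewer than five occupied bins, e.g. noise-free runs) fall
back to histogram moments. The between-algorithm test defaults to a paired
t-test on per-case mean differences — pooled pixels are spatially
autocorrelated, which inflates the effective n — with Welch's t on the
pooled pixels available as the literal pixel-pool variant; the variant is
always recorded in the result. A spatial mixed-effects model would be the
more defensible test and is out of scope.

## Cohort and report

The default synthetic cohort has 18 cases with per-case randomised breast
radius (3.4–4.6 cm) and prescription (42.5 Gy/16 fx or 50 Gy/25 fx). The
report bundle mirrors the study's summary shapes: D50% mean ± SD per
algorithm × structure; rind-induced dose increases combined with the
pooled-fit means into calculated-minus-measured cells per region; gamma
pass-rate mean ± SD per criteria × algorithm × region; the histogram panel
figure; and a run log with seed, config hash and versions. Every cell is
recomputable from persisted per-case artifacts. All randomness derives from
one seed through `numpy.random.SeedSequence` spawning, and reruns are
byte-identical.

Problem sizes used by the test suite: unit tests run on a reduced phantom
(2 cm radius, 6 cm band, 0.2 cm CT voxels); the cohort-level checks use the
full 18-case default cohort for DVH ordering and 3-case cohorts for the
end-to-end sign-pattern check; the gamma oracle comparison uses fifty
32×32 map pairs. The acceptance script runs the complete 18-case cohort end
to end.

## Known limitations

* The dose model is a parametric buildup curve, not transport: absolute
  magnitudes of algorithm differences are conventions, only their signs and
  orderings are meaningful claims.
* The phantom is a generic half-cylinder — breast shape variation, skin
  folds and cradle curvature changes are not modelled, so passing tests
  demonstrate correctness of the analysis machinery, not clinical accuracy
  on real anatomy.
* Film emulation is Gaussian plus offset/ridge; it omits scanner lateral
  response, film-darkening kinetics (the ≥ 48 h scan delay is metadata
  only) and multichannel dosimetry.
* Digitisation still inflates the unfolded area by ~6 % after smoothing.
* Pooled-pixel statistics ignore spatial autocorrelation (hence the paired
  per-case default for the t-test).
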