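# Methods

`phenostereo` measures crop height at millimetre resolution from a *pair* of
nadir drone photographs taken a metre or so apart during a single flight.
The two exposures of one monocular camera form a stereo pair whose baseline
is recovered from the RTK-GNSS fix attached to each shot.  Because the
baseline is not a fixed rig parameter, the pair must be calibrated
(rectified) anew every time; that in-flight calibration, and the accounting
that turns integer disparities into heights and growth ratios, are the
substance of the package.

## Geometry and units

For a rectified pair with baseline `b` (m) and focal length `f` (px), a
point of disparity `d` (px) lies at depth `l = f b / d`.  A plant's height
is the depth difference between its top and the surrounding ground,

    p_h = f b / d_g − f b / d_p ,

and the depth change per one-level disparity change at level `d` is
`l_d /(d+1)`.  With `f ≈ 3000 px` (quarter-scale sensor), `b = 0.81 m` and
an altitude of 4.1 m, the ground sits near level 593 and one level is worth
about 7 mm of height; the published field readings (levels 1374→1573 and
1957→2320 spanning a 570 mm plant) correspond to 2.9 mm and 1.6 mm per
level.  Long baselines are the whole game: resolution is proportional to
the disparity count across the plant.

The baseline itself is the great-circle distance between the two GNSS
fixes.  With half-angle (haversine) arguments the numerically correct
inverse is `arcsin`; `arccos` of the same radicand is hopelessly
ill-conditioned at metre separations and would not reproduce the printed
baseline table, so the haversine form is used throughout (mean Earth radius
6 371 000 m, configurable).  Printed logs quantize latitude to 1e−8 deg
(~1 mm) and longitude to 1e−7 deg (~9 mm), so recomputed baselines carry
up to ~2 cm of rounding slack on multi-metre pairs.

## Dense matching

Block matching uses zero-mean normalized cross-correlation (ZNCC) over
(2r+1)² windows, r = 7 by default, with integer candidate disparities in a
span of 128 levels centred on the GNSS-predicted ground disparity
`f b / Z`.  ZNCC's invariance to gain and offset is what makes soil and
canopy texture matchable across exposures.  Scores are computed for all
pixels at once with box filters (algebraically identical to per-window
evaluation; the test suite checks pixel-for-pixel agreement with a brute
force triple loop).  Three validity rules mark pixels black:

* best score below the acceptance threshold (0.6 by default) or zero
  texture variance in either window;
* a candidate range truncated by the image border (`require_full_range`) —
  the best of a partial search is not trustworthy;
* left-right inconsistency: the match is recomputed with the right image as
  reference (free, from the same score volume) and must agree within one
  level.  This is what actually blackens occlusion bands: windows
  straddling a plant's strong silhouette edge otherwise correlate
  confidently at wrong disparities ("foreground fattening").

Ties go to the smaller disparity, making maps bit-reproducible.

## Two-phase calibration

Phase 1 (rough): Harris corners on the left image are ZNCC-matched into the
right image, the horizontal search covering the GNSS-predicted disparity
range widened by ~f·tan 2° for uncalibrated rotations, the vertical by
±130 px.  A similarity transform (rotation, scale, translation) is fitted
in complex form.  Plain robust regression is not enough here: corners on
raised plants carry a *different* disparity than ground corners and form a
coherent second mode, so a deterministic two-point consensus search (all
corner pairs ≥100 px apart; inliers within 2 px) selects the dominant
ground mode before the final least squares.  The result is only a guide —
it centres the phase-2 search bands — so centi-degree accuracy is not
needed.

Phase 2 (precise) matches *lines*, not points.  Left scanlines `y = C_i`
(13 rows by default, evenly spaced with a 40 px margin) are sampled every
4 px; each sample is ZNCC-matched in a band `±S_R` (20 px) around the
phase-1 prediction, with the horizontal search narrowed to ±28 px since
phase 1 pins the mean disparity.  Sample points whose band is clipped by
the image border are skipped: their true partner may be outside the frame
and matching there can only lock onto spurious texture.  Matches are
refined to sub-pixel by a symmetric Lucas–Kanade step (both windows
interpolated by half the offset with a Catmull-Rom kernel, ≤15 iterations).
The symmetry matters: one-sided interpolation low-passes only the shifted
window and systematically attenuates the recovered fractional offset, and
because every point of a row shares the same fractional phase the bias does
not average out along the line — it masquerades as a tilt.

Each row's accepted points are fitted by a least-squares line
`y = a_i x + b_i` with two MAD-rejection passes (the first elimination
stage), and rows whose points scatter far off any line — typically rows
crossing raised vegetation, whose guided search misses the plant's
disparity — are dropped by comparing each row's residual RMS to the median
(the second elimination stage, applied once more after two outer
iterations).

The staged one-parameter solves then read the alignment off the line pairs
(principal-point-centred coordinates):

* `beta` (about y): slopes vary with intercepts,
  `beta = atan(f (a_i − a_j)/(b_i − b_j))`, combined over all index pairs
  by a least-squares slope through the origin;
* `gamma` (about z): common slope, `atan(mean a_i)`;
* `alpha` (about x): unequal line spacing.  The closed three-intercept
  formula (`solve_alpha`) is exposed as printed, but the pipeline estimates
  the increment by regressing `b_i − C_i` on `[1, C_i, C_i²/f]` — the
  row-wise least-squares form of the same spacing criterion.  The
  regression form is preferred for two numerical reasons found during
  development: second differences of integer pixel rows are off by a whole
  pixel about the half-integer image centre (which the f/D ≈ 60 leverage
  amplifies into degrees), and triples become ill-conditioned when border
  rows are dropped;
* `Δy`, `Δz`: the mean intercept is shifted onto the mean row, then a
  least-squares scale about the centre maps intercepts onto rows; a
  point-level refit over all matched points re-solves both after the plane
  step.

Matched-point depths (from their disparities) are fitted by a least-squares
plane `z = a x + b y + c` with two trimming passes (points on vegetation
sit decimetres off the plane and must not vote).  The plane's gradient
gives the left-image tilt, `beta_b = atan(a)`,
`alpha_b = atan(−b cos beta_b)`.

Because each one-parameter solve overfits the residual left by the others,
the cycle estimate → apply → re-measure is iterated from the original
coordinates, corrections accumulating, until the row SSE changes by less
than 0.01 px² (at most 20 iterations); the final increments are reported as
the overfitting amounts.  The rectified right image is produced by inverse
warping; pixels from outside the source frame are NaN so the matcher
invalidates windows touching them rather than correlating against an
artificial border.

A warning about the near-degeneracy that dominates the error budget:
over the ±1.5° range, a rotation about x is almost exactly a vertical
shift (`f tan alpha`) plus a quadratic of amplitude `C² tan(alpha)/f` —
about 1.5 px at the image border per degree.  `alpha` and `Δy` are
therefore separable only through that quadratic, and every 0.01° of
`alpha` error leaks ~0.5 px into `Δy`.  The sub-pixel bias control and the
row count both exist to serve this separation.

## Synthetic acquisitions

The renderer emulates the flight geometry so every stage is testable with
exact ground truth: a flat (optionally gently undulating) ground plane with
band-limited value-noise albedo (texel 5 mm, smoothed, contrast ~35 grey
levels — soil-like, locally textured everywhere, as ZNCC needs), box-shaped
plant proxies with their own texture, dim low-variance side walls, and two
pinhole cameras at ±b/2 with commanded rotations, vertical image shift and
left-camera tilt.  Visibility is resolved per ray (tallest surface first),
so occlusion behind plant boxes is physically real.  Rendering supersamples
2× per axis and box-downsamples; Gaussian sensor noise (σ = 1 grey level)
is added.  GNSS fixes are laid out along a constant heading and rounded
like a shooting log (8/7 decimals).  The default image is 1368×912, a
quarter-scale of the 5472×3648 sensor, with f = 3000 px; flights are
4.1–18.7 m altitude with 0.3–1.5 m baselines, matching the two field
regimes.

The right camera's commanded perturbation is constructed so that a perfect
calibration with exactly the commanded parameters rectifies the pair —
"recovered = commanded" is therefore well-defined to machine precision,
and the renderer serves as the oracle for the calibration tests (the
renderer casts rays through a full 3-D scene; the calibration estimates
from pixel matching; they share only the rotation convention).

What the synthetic scenes do *not* model: radiometric effects (shadows,
BRDF, vignetting), wind motion and rolling shutter, real canopy geometry
(boxes have flat tops; buckwheat does not), and RTK noise beyond log
rounding.  Passing tests therefore demonstrate the correctness and
internal accuracy of the algorithms under the stated geometry, not field
accuracy against hand measurements — the published field errors (tens of
mm) are dominated by centimetre GNSS positioning and root-finding on
uneven ground, which a desk-scale rig cannot reproduce.

## Height and growth measurement

`measure_plant` splits a region's valid disparities into plant/ground at
the midpoint between the *supported* extremes and reads `d_p` and `d_g` as
the highest/lowest level holding at least 1% of its class (robust mode;
raw min/max reproduces manual readings).  Support filtering exists because
occlusion edges yield thin smears of confident wrong matches over many
levels — extreme percentiles land on them, well-populated plateaus do not.
Matches scoring below 0.75 are ignored in robust mode.  Regions whose
"plant" class is under 2% of the valid pixels are treated as flat ground.

Growth between observation days needs no baselines at all: scaling the
second day's map so the ground disparities agree, the height ratio reduces
to `r = (1 − d_g′/d_p′)/(1 − d_g/d_p)`.  As printed, the source formulas
repeat a `1/d_g(t1)` term where the height arithmetic requires
`1/d_g − 1/d_p`; the implementation uses the only reading consistent with
the height formula, and the identity between the scaled-map ratio and the
disparity-only form is verified numerically over random epochs.  The
detectable relative growth per disparity level is `1/(d_p − d_g)` — 0.28%
for the 1957→2320 reading.

## Problem sizes and numerical choices

Synthetic validation runs at quarter scale: calibration recovery is
checked over 20 seeded renders (commanded angles uniform in ±1.5°, shift
±8 px, tilt ±0.8°), end-to-end height accuracy over 10 seeded plant scenes
(heights 0.25–0.60 m, tolerance two per-level resolution steps, the
GNSS-rounded baseline in the loop), and baseline independence of the
growth ratio over paired renders at 0.5 m and 1.0 m from 8.2 m altitude.
Oracle equivalence of the dense matcher is exhaustive on ≤64×64 images.
Disparity search spans widen to 256 levels when a plant's top must fit in
the range.  All randomness is seeded; reruns are byte-identical.

Known limitations: rotations beyond ~2° break the small-angle staged
solves (and the gimbal assumption); scenes without metre-scale flat ground
majorities defeat the plane fit and the phase-1 consensus; multi-image
chaining across a flight strip is out of scope; disparities are integer
levels by design, so single-pair height resolution is the per-level step,
not better.
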