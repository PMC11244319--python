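# Methods

## Scene geometry and rectification

A tray is defined by four colored fiducials at the corners of a square;
one cultivar occupies each quadrant. Detection matches pixels in HSV
space by a circular hue window (default red, hue tolerance 0.07) with
saturation ≥ 0.45 and value ≥ 0.25, labels the mask 8-connected, drops
components under 5 px as speckle, and requires exactly four remaining
components; anything else is a detection failure that names the count
found, since guessing which blobs are pins would silently corrupt the
geometry. The four centroids are ordered top-left, top-right,
bottom-right, bottom-left by angle about their common centroid — an
ordering that is invariant to rotating the capture by any multiple of
90°, so a camera mounted upside down still yields consistent quadrant
labels. Red and blue pins are treated identically (no orientation
encoding); the pin color is a parameter.

Rectification estimates the projective transform mapping the four
centroids to the corner pixels of a `side_px × side_px` square and warps
with bilinear interpolation. Bilinear is used because it is the standard
area-stable choice: on noiseless axis-aligned scenes the warp reduces to
an exact crop, and tests hold total foreground area change under 2% for
stretching warps. `side_px` must be even so the square splits into four
equal, non-overlapping tiles whose reassembly is pixel-identical to the
input. Quadrant numbering is row-major from the top-left (1 TL, 2 TR,
3 BL, 4 BR) — the field layout does not dictate an arrangement, so this
is a documented convention rather than a discovery.

## Segmentation, counting, calibration

Grayscale conversion uses the Rec. 601 luma weights (0.299, 0.587,
0.114), rounded half-up. Three segmentation modes cover the two imaging
styles:

- **otsu** (default for fluorescence-style images, where plants are the
  bright class): histogram-based maximization of between-class variance.
  The implementation searches all 256 split points; when several attain
  the maximum (a plateau, guaranteed for strictly two-valued images) the
  plateau midpoint is returned so the threshold sits between the modes.
  A constant image has no meaningful split and yields an empty mask with
  a degenerate flag instead of an arbitrary threshold.
- **fixed**: a user-supplied threshold, for controlled lighting.
- **excess_green**: `2G − R − B > 20` on RGB input. The margin of 20
  keeps gray background (index exactly 0) and red fiducials (index < 0)
  out of the foreground under moderate noise.

Plants are connected components of the binary mask with area ≥
`min_area_px` (default 5 px, suppressing salt noise while keeping any
plausible seedling) using 8-connectivity by default (cotyledon links are
often one diagonal pixel wide). Touching plants merge into one component
and are counted as one — an acknowledged limitation of top-view imaging
rather than a defect; the overlap case is exercised explicitly in tests.
Reported area sums retained components only, so the area and the count
always describe the same objects.

Pixel area converts to projected canopy size by `y = x / (a/b)²` where
`a` px and `b` cm measure the same reference object: `a/b` is the
resolution in px/cm, and dividing by its square converts px to cm². The
conversion is linear in `x` and invariant to imaging resolution (doubling
the resolution quadruples `x` and doubles `a`, leaving `y` unchanged up
to rasterization error, bounded at 2% in tests).

Germination per quadrant is `100 · min(count, n_sown) / n_sown`. Counts
above `n_sown` are clutter or split blobs: the percentage is capped at
100 and the record flagged, never silently accepted.

## Germination series

Daily values form a cumulative series by running maximum: germination is
biologically irreversible, so a day-over-day dip can only be a detection
artifact (occlusion, threshold flicker), and smoothing it keeps the curve
monotone. The raw series is retained alongside for auditability. The
"desired germination" day is the first observed whole day at or above the
threshold (inclusive), defaulting to 90%; a series that never reaches it
returns an explicit not-reached sentinel, never an extrapolated day. A
continuous crossing computed from a fitted curve is available separately
(`fitted_crossing_day`) for users who prefer interpolation. Germination
curve fits constrain the asymptote to (0, 100].

## Growth model and fitting

Shoot dry weight y (g) versus projected canopy size x (cm²) follows the
three-parameter logistic `y = a / (1 + exp(−b (x − c)))`: a is the
maximum attainable dry weight (g), b the steepness (units 1/cm², the
only dimensionally consistent reading), c the canopy size at half-maximal
growth rate (cm²). Evaluation clips the exponent to ±500, so predictions
are finite and strictly inside (0, a) for all inputs.

Fitting minimizes Σ(y − ŷ)² with SciPy's bounded trust-region
least-squares (`trf`), default bounds a > 0, b > 0, c free, `xtol = ftol
= gtol = 1e-10`, `max_nfev = 5000`. The start is a stable heuristic —
a₀ = 1.05·max(y), c₀ = the x whose y is nearest a₀/2, b₀ = 4/range(x) —
followed by up to two seeded multiplicative-jitter restarts if the first
attempt does not converge; non-convergence is reported as a status flag
with the best iterate, never a silent success. Fits are performed on the
original gram scale by default: the published asymptotes are printed in
grams, which is consistent with an untransformed response. A
log-transformed mode (`y' = ln(y + ε)`, inverse applied to predictions)
is provided because combined multi-harvest data are strongly
heteroscedastic; neither mode is asserted to be "the" canonical fit.

Goodness of fit: R² = 1 − SSres/SStot; RMSE = √(SSres/n) (the 1/n
convention, documented so the df choice is auditable); p-value from an
F-test of the 3-parameter model against the intercept-only model
(df = 2, n − 3). When all observations are identical SStot = 0, R² is
undefined and the summary carries a degenerate flag rather than a number.
Fitting is invariant to observation order, and a constrained model can
never beat the data's own least-squares optimum, so the fitted R² is
never below the intercept-only model's zero.

## Synthetic data generator

The generator emulates the study conditions, not photorealism: a square
tray bounded by four saturated fiducial discs (default pure red, radius
5 px) on a dim gray background, green disc-shaped seedlings confined to
their quadrants, optional additive Gaussian noise clipped to [0, 255],
and a single integer seed driving every stochastic draw so renders are
bit-reproducible. Discs are used because they have a closed-form
rasterization oracle (all pixels within Euclidean distance r of the
center), making per-quadrant ground-truth areas exact at zero noise.

Time series follow per-plant schedules: a germination day (default
layout draws days 3–5, matching the gradual emergence over days three to
five typical of lettuce trays, with clear plastic domes removed around
day three) and logistic radius growth r(t) = r_max/(1 + exp(−0.9(t −
t_emerge − 3))), i.e. roughly 90% of final radius six days after
emergence — a rate chosen once as realistic for seedling canopies and
not revisited. The rendered radius is floored at 2 px after emergence:
a just-emerged cotyledon spans a few millimetres, and a 2 px disc
rasterizes to at least 12 pixels at any sub-pixel center, so an emerged
seedling always survives the 5-px speck filter. Captures default to four
times a day (00:00, 05:00, 12:00, 15:00); emergence is gated on the
nominal day while radius is evaluated at the fractional time, so
within-day captures show slight growth and exercise daily averaging.
Per-plant spatial jitter is a parameter (default ±1.5 px) rather than a
fixed constant, since no canonical layout exists.

What the generator does **not** emulate — leaf shape and texture, lens
distortion, uneven illumination, soil clutter, plants spilling across
quadrant boundaries — bounds what passing tests show: they verify the
measurement chain's correctness (geometry, counting, calibration,
bookkeeping) exactly, not robustness to field imagery.

## Pipeline conventions

The batch runner is deliberately not a daemon: scheduled capture times
live in filenames (`tray_dNN_HHMM.png`) and config, keeping runs hermetic
and reruns byte-identical for identical inputs and seed. Per-image
failures (unreadable file, wrong marker count) are logged with the file
name and skipped; one bad capture never aborts a batch. Records are
written as UTF-8 comma-separated CSV with a header and ISO-8601
timestamps; canopy sizes are rounded to 2 decimals in the CSV while full
precision flows internally. Repeated within-day captures are collapsed by
arithmetic mean with the number of captures recorded; a day with no
captures propagates a missing marker, never a zero. Cloud upload is
modeled as a local outbox: an idempotent, checksum-verified mirror of the
output directory with a JSON manifest of what each run copied, which any
external sync agent can watch.

## Problem sizes and numerical tolerances

Default simulated batches are 260 px trays, 4 plants per quadrant, 7
days × 4 captures (112 records), sizes at which the whole suite and the
acceptance script complete in seconds. Parameter-recovery simulations
use 200 pairs with residual σ equal to each study's reported RMSE
(0.27 g multi-harvest, 0.01 g seedling stage); recovery is asserted
within 10% relative error, noiseless recovery within 1e-6 relative, and
the midpoint identity y(c) = a/2 to 1e-12 relative. Marker centroids on
synthetic discs are accurate to within 1 px; rectification-induced area
change on axis-aligned scenes is zero by construction and under 2% for
stretching warps.

## Known limitations

Touching plants are counted as one; counts above the sown number are
capped, flagged, and left to the analyst; top-view area hides height, so
dry-weight prediction degrades once plants grow vertically or overlap;
the Otsu plateau tie-break is a convention (any plateau member maximizes
between-class variance equally); and the growth model is a single
logistic — multi-phase growth or cultivar-specific curves require
fitting per group, which the CSV schema (cultivar and day columns)
supports but the package does not automate.
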