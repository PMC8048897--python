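# Methods

## Quantities and conventions

All fractions (RBT, RBA, BFI, carbon fraction) are stored as proportions in
[0, 1]; percent appears only at the formatting layer, rounded half away from
zero to the configured number of decimals (1 for percent columns by default).
Units are fixed and never inferred: diameters/thicknesses cm, heights m, basal
area m², volume m³, biomass kg, density kg/m³, carbon kgC.

`StemGeometry` rejects `bt_max ≥ dob/2`: at equality the under-bark diameter is
zero and RBT is undefined; beyond it the geometry is unphysical.

## Maximum and fissure-corrected thickness

`BT_max` is measured ridge-to-wood. Two estimators are provided: the mean of
dedicated ridge readings (averaged per quadrant first, so quadrants weigh
equally when labelled), and, for smooth bark without distinct ridges, the mean
of the three largest of ≥ 10 readings. `BT_f` is the plain mean of readings
taken at random or systematic points over the whole surface; reading sets
flagged `ridge_only` are rejected there, because sampling only ridges
reproduces `BT_max` and biases BFI toward 1. Sample SD uses the n−1
denominator; CV = 100·SD/mean.

If noise pushes `BT_f` above `BT_max`, BFI is clamped to 1.0 with a logged
warning (physically BFI ≤ 1); clamping can be disabled. An optional constant
gauge-bias correction (default 0 cm; spring gauges typically read ~0.05 cm
thick) is subtracted from readings, floored at zero. No calibration model
beyond this constant is attempted.

## Sampling-error model

The relative error of a mean of n readings is `CV · t / √n`, with `t` the
0.975 quantile (two-tailed 95%) of Student's t with n − 1 degrees of freedom —
the convention under which the published error grids reproduce exactly at
whole-percent rounding. `required_n` inverts this by linear scan from n = 2
(the smallest n with a defined t); with CV = 0 it returns 2. The absolute
error column of `error_table` is defined self-consistently as
`percent · mean / 100`; the percent column is the normative one, since no
single formula reproduces all published absolute cells.

`compare_methods` applies a standard paired t-test to method differences
matched by section; zero-variance differences return p = 1 (zero mean) or NaN
(constant offset) rather than a spurious significance.

## Contour (CM) and digitized (DM) reference methods

DM divides the solid bark polygon area (outer minus wood contour, shoelace
areas via shapely, invalid/self-intersecting polygons rejected rather than
repaired) by the idealized annulus from the tape DoB. The under-bark diameter
entering that annulus is not uniquely defined by the protocol; the default is
the wood polygon's area-equivalent diameter `2·√(A_wood/π)`, with
`tape_dob − 2·BT_max` available behind a flag. An optional uniform resampling
helper (default 0.05 cm spacing) is provided for noisy digitizations; contours
are not smoothed by default.

CM converts a contour-gauge trace to polar form: the profile envelope (its
highest point, a bark ridge) is pinned to the tape radius DoB/2, so heights
become outer radii. The wood line is reconstructed from the three thickness
anchors — outer radius minus anchor thickness at the start, centre and end of
the profile — interpolated linearly in arc position between them. This encodes
the smooth-bole assumption: the wood surface is not irregular the way the bark
surface is, so fissures in the trace reduce solid area instead of being copied
into the wood line. Where a fissure undercuts the reconstructed wood line the
(outer² − wood²) integrand is truncated at zero with a warning. The
denominator is the idealized annulus with `DuB = tape_dob − 2·(mean anchor
thickness)`, scaled by `arc_span/360`. Arc positions are mapped linearly onto
the stated arc span, which makes a constant-height slab evaluate to exactly 1.

## Synthetic sections

The simulator emulates four bark morphologies with non-overlapping rectangular
or triangular notches on a uniform annulus. It is a fixture convention, not a
model of real bark: real fissures are irregular in depth, width and wall
shape, can run oblique to the stem axis, and real sections are non-circular.
Passing tests therefore demonstrate correctness of the estimator pipeline
under the stated geometry, not field accuracy.

Placement is rejection sampling of fissure centres (retry cap 1000; an
unsatisfiable spec fails explicitly, naming the seed). Ground truth uses
fixed-order Gauss–Legendre panels aligned to fissure edges (131072 panels
total, fixed, so truth values are deterministic); because the thickness
profile is piecewise polynomial in angle, the solid-area integral
`∫ (r_w·BT + BT²/2) dθ` and the thickness mean/variance are exact to machine
precision. Two truths are exposed deliberately: the thickness-ratio BFI (what
BGM estimates) and the area-ratio BFI (what DM measures). Their gap is the
intrinsic approximation of the thickness index — area-weighting favours the
outer, thicker shell — and is always ≥ 0, shrinking as bt_max/wood_radius → 0
(below 0.01 once bark is thinner than a twentieth of the wood radius).

Default morphology presets (rectangular fixed-size fissures, so BFI and CV are
closed forms independent of the seeded placement):

| preset            | wood r (cm) | BT_max | fissures (depth × width) | BFI (thickness) | CV |
|-------------------|------------|--------|--------------------------|-----------------|------|
| deep_fissured     | 11.05      | 3.1    | 4 × (1.556 × 59°)        | 0.671           | 35.5% |
| smooth            | 9.15       | 1.0    | 3 × (0.55 × 10.9°)       | 0.950           | 16.6% |
| scaly_shallow     | 11.6       | 1.1    | 6 × (0.32 × 20.6°)       | 0.900           | 15.4% |
| fibrous_fissured  | 13.1       | 0.9    | 5 × (0.78 × 12°)         | 0.856           | 37.7% |

Seeds are fixed per preset (20210114–20210117); the subsampling and validation
utilities default to seed 20210114. Fissure widths are multiples of 0.1° so an
exhaustive systematic scan at 0.1° spacing integrates the step profile without
edge misassignment.

`validate_bgm` simulates replicate gauge campaigns per n (200 by default; the
property checks in the test suite use 200–500 replicates at n ∈ {5, 15, 30},
sizes at which the whole suite runs in seconds). Its "empirical relative
error" is `100 · t_{0.975, n−1} · SD(replicate BT_f estimates) / true mean` —
the simulated counterpart of the planning formula, using the same t convention
with the replicate SD in place of CV/√n.

## Numerical choices and edge cases

- Polygonization (`to_profile`) inserts fissure-edge vertices exactly,
  emitting both wall endpoints for rectangular notches, so the digitized BFI
  differs from truth only through circle-chord error (~10⁻⁶ at 10
  vertices/degree).
- `bt_f` of a single reading reports SD = CV = 0 rather than NaN.
- Table comparisons round half away from zero to the printed decimals
  (`formatting.round_half_away`), matching how field tables are printed.
- CSV delimiter detection is limited to comma/semicolon/tab; decimal separator
  is always '.'. Malformed measurement files report *all* offending lines at
  once with file line numbers.
- CLI outputs are fixed-decimal formatted, so re-runs are byte-identical.

## Known limitations

- Bark thickness and texture are assumed proportional along the stem; no
  taper or half-butt correction, and no along-stem (3-D) bark volume
  integration.
- No bark-thickness model is bundled (coefficients are species-specific);
  `geometry_from_model` accepts any user-supplied DBH → BT_max function.
- Extracting contours from photographs is out of scope; polygons/traces are
  the input boundary.
- The simulator does not model bark shedding, fire scars or along-stem
  variation.
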