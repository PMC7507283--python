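# Methods

## Measurement model

A seedling's shoot biomass is proxied by projected green area. Each plant is
captured in three views — one from above, two from the side at 90° to each
other — in front of a dark background with a scale marker of known physical
length in frame. Whole-plant area by imaging is the plain sum

    WPA_i = A_top + A_side0 + A_side90   [mm²],

with no overlap correction between views: leaves hidden behind other leaves
or seen edge-on are simply not counted, which is one reason WPA_i and the
destructive scan area WPA_s can rank genotypes slightly differently. The
destructive counterpart scans excised leaves and stems on a flatbed and sums
per-object areas, `WPA_s = Σ areas`.

Top-view shape descriptors summarise canopy architecture: convex hull area
(ground cover / leaf spread), caliper length (maximum Feret diameter, canopy
span), compactness (projected area ÷ hull area; low = open, spread canopy),
and an elongation descriptor. Elongation is reported twice — the best-fit
moments-ellipse eccentricity in [0, 1) and the ellipse major-axis length in
mm — because published "eccentricity" values for this assay are on a length
scale (hundreds of mm) and are not compatible with the dimensionless
definition; users map whichever column their convention requires. Neither
variant is asserted against published eccentricity columns.

## Segmentation

Pixels are classified by hue/saturation/brightness after channel
normalization to [0, 1] (so thresholds are bit-depth independent). Defaults:
hue ∈ [60°, 180°], saturation ≥ 0.15, brightness ≥ 0.10 — a generic
green-on-dark setting, config-overridable and always logged, since published
protocols of this kind choose thresholds interactively per session. Flatbed
scans use the same hue band with a brightness *ceiling* (0.97) instead,
excluding the near-white platen.

Cleanup is morphological opening (disk radius 1 px) followed by removal of
8-connected components below 25 px. Both steps are anti-extensive (they only
remove pixels), so cleaned ⊆ thresholded always holds; widening any
threshold interval can only grow the raw mask. Segmentation contains no
randomness.

Calibration precedence: an explicit mm-per-pixel flag wins over marker
points; automatic ruler detection is out of scope. Coordinates are
row-major, origin top-left.

## Geometry conventions

Foreground pixels are treated as unit squares. The convex hull is computed
over pixel **corners** (centers ± ½), not centers. This choice is what makes
the documented invariants identities rather than approximations:
`projected_area ≤ convex_hull_area` holds exactly, compactness never
exceeds 1, a filled square has hull area equal to its pixel area, and a
single-pixel mask has hull area = pixel area instead of a degenerate 0. The
cost is a ≤ 1-px-per-side outward bias on hull area and caliper relative to
idealized continuous shapes; tests on closed-form shapes (disk, square,
ellipse) carry tolerances sized to that bias.

Caliper length is the rotating-calipers diameter of the corner-point hull
(antipodal-pair sweep, O(h) in hull vertices). Because the oracle — the
exhaustive maximum pairwise distance over the same corner set — evaluates
the same floating-point distances, agreement is exact, and is asserted
exactly on masks up to 2000 px.

Eccentricity and major-axis length come from the second central moments of
the full foreground (all components treated as one region), via
scikit-image's regionprops.

Empty masks yield zeroed trait records with an `empty` flag rather than
errors: two-week-old seedlings can legitimately segment to nothing under
strict thresholds, and batch runs must proceed.

## Growth rates

AGR, RGR (natural log) and CGR are computed between exactly two dates.
The spacing divisor defaults to P = 1 m²: the published CGR values for this
assay (e.g. 212.36 for LB-46 whole-plant area) are consistent only with
P = 1, while the stated 20 cm × 15 cm plant spacing would give P = 0.03 m².
Both are supported; P is a plain flag. Rates are computed from genotype
means of the measured value at each date — the convention under which the
published numbers are recoverable — and replicate-level computation works
identically.

## Statistics

Correlation/regression run on genotype means by default (n = 7 here);
missing values are handled pairwise-complete. One-way fixed-effects ANOVA
accepts either raw replicate vectors or mean ± SE ± n summaries; within-group
sums of squares are reconstructed via SD = SE·√n, so summary-based results
equal raw-data results exactly (cross-checked against scipy's f_oneway).
Significance codes follow the source tables: ** p < 0.001, * p < 0.05, NS
otherwise. p-values come from the F survival function; no multiple-testing
correction is applied (none is used in this assay's convention).

PCA defaults to the covariance of unscaled means — consistent with PC1
being dominated by large-valued area traits (PC1 ≈ 99% on the imaging
table) — with a correlation-scaled mode available. Components are ordered by
decreasing eigenvalue; each loading column is signed so its
largest-magnitude entry is positive, making score plots reproducible.
"Regression coefficient (%)" columns in the source material are not assumed
to equal 100·r² (they do for some rows only); the package reports R² and
does not attempt to reproduce that column. Published replicate-level
correlations (e.g. leaf number 0.955 at 28 DAS vs 0.944 from means) cannot
be recovered from genotype means and are not asserted; the third decimal of
the printed third-leaf-length correlation (0.892 vs 0.8915 from 2-dp means)
falls in the same category.

Ranking is a stable descending sort with ties broken by genotype label.

## Synthetic scenes

The generator builds a parametric seedling in 3-D millimetre coordinates —
tillers as near-vertical stems, leaves as arcs that rise at a take-off
angle and droop along their length, with an elliptical blade-width profile
blunted to a 1 mm minimum tip width — and projects the same model
orthographically into the three views, so per-view silhouettes are mutually
consistent (foreshortening included). Each view is rasterized once into a
binary truth mask; the rendering colors exactly those pixels green
(hue 100–140°, saturation 0.65, brightness 0.45–0.60) on a 0.05-brightness
background, adds a white marker bar of known mm length, small green salt
specks, and Gaussian channel noise (σ = 0.01 by default — mild, matching
controlled imaging under artificial light).

Ground truth (per-view areas, top-view hull/caliper/eccentricity) is
computed from the truth masks using the geometry module's own definitions,
so end-to-end tests isolate segmentation fidelity; closed-form checks
(ellipse area πab) use degenerate parameter settings (straight horizontal
blade, zero tip width). Defaults: 512×512 px views at 0.25 mm/px, 4 leaves
50–150 mm long and 2–4 mm wide, 35° droop — a ~3-week-old seedling at a
working distance comparable to a consumer DSLR setup.

What the generator does **not** emulate: pot and soil texture, shadows and
specular highlights, leaf translucency and color gradients, anti-aliased
edges, perspective distortion, wind motion. Passing the synthetic end-to-end
checks (IoU ≥ 0.99, area within 2% at default noise) therefore validates
the operator chain — thresholding, cleanup, calibration, geometry — not
robustness to field imaging conditions, where thresholds must be tuned per
session.

All randomness flows from one `numpy` generator seeded per scene;
regeneration is bit-exact.

## Embedded tables

Genotype-mean trait tables (mean, SE, ANOVA code; n = 5 replicates) for the
seven genotypes at 14 and 28 DAS are embedded as immutable fixtures: manual
sampling (11 traits at 14 DAS, 15 at 28 DAS) and imaging (17 and 29 traits).
A SHA-256 checksum over the canonical serialization is asserted in the test
suite to prevent silent edits. Where the extracted source text ran numbers
together, parses were disambiguated by internal consistency (the
compactness = area/hull identity, which holds in all 14 genotype × date
cells, and printed correlations).

## Numerical choices and degenerate inputs

- Rounding for comparisons against printed values: half away from zero at
  the printed precision, applied only in tests.
- Coincident marker points, empty/inverted threshold intervals, missing
  views, non-positive values for RGR, zero-variance correlation inputs and
  all-constant PCA matrices raise typed errors; empty masks do not.
- Opening's border behaviour is clamped (`mask &= raw`) to guarantee the
  subset invariant regardless of pad conventions.
- Problem sizes in the default test run and acceptance script (512×512
  scenes, ≤ 2000-px caliper-oracle masks, 3 scenes) keep the full suite in
  the tens of seconds while exercising every operator at realistic scale.

## Known limitations

- No overlap correction across views; WPA_i underestimates dense canopies.
- Hue thresholding assumes green tissue; chlorotic or senescent leaves need
  widened bounds.
- The hull/caliper corner convention biases outward by up to one pixel per
  side relative to continuous-shape ideals — negligible at thousands of
  pixels, visible in percent terms for very small masks.
- Growth rates use exactly two time points; no functional growth-curve
  fitting.
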