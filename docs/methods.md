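# Methods

## Age designation and counting

The core procedure turns an annual land-cover class sequence into a
regenerating-forest age. The condensed class vocabulary is
{UNDISTURBED, DEGRADED, NONFOREST, REGROWTH, PLANTATION, WATER, NODATA};
a configurable code table maps a real product's raw integers onto it, since
annual-change products carry richer sub-classes (degradation stages,
regrowth sub-types) whose collapse is a user decision, not something the
code should hard-wire.

A pixel is designated regenerating in year *T* when three conditions hold:
its class in *T* is REGROWTH; its terminal consecutive REGROWTH run has
length ≥ `min_regrowth_years` (default 3); and the most recent NONFOREST
block before that run lasted ≥ `min_nonforest_years` (default 3). The
3-year gap is the annual-resolution operationalisation of "more than 2.5
years without detectable tree cover": the smallest integer number of annual
observations exceeding 2.5. Age is the terminal run length counting the
first regrowth year, so a window of 34 annual layers yields ages in
{0} ∪ [3, 34]. This is the only counting convention consistent with a
maximum of 34 over 34 layers.

**Left-censoring.** A run (or its most recent preceding NONFOREST block)
that touches the first window year has its deforestation episode before the
window. Requiring an observed 3-year gap there would cap ages at
window − 3 and contradict the attainable 3–34 range, so the gap requirement
is waived for left-censored runs: in the source products the regrowth class
itself already encodes that a prior deforestation occurred. The acceptance
suite verifies the attained range by exhaustive enumeration of all 3¹²
{UNDISTURBED, NONFOREST, REGROWTH} sequences over a 12-year window plus the
full-window extreme constructions.

**Resets.** Any class other than REGROWTH — including DEGRADED, WATER and
NODATA — resets the counter to zero (NODATA is an observation gap, but
treating it as neutral would silently bridge unobserved clearances; resetting
is the conservative choice and is logged). A configurable
`neutral_classes` set lets users declare classes (typically DEGRADED) that
freeze the run instead of resetting it, since source products differ on
whether degradation interrupts regrowth.

The per-pixel rule is implemented twice on purpose: a scalar direct scan
(`designate_regrowth`) and a vectorised single-pass recursion over years
(`compute_age`), which tracks the current regrowth run, the current and most
recent NONFOREST block, and the censoring flags. The tests require exact
agreement between the two on random stacks and on every hypothesis-generated
sequence; the cumulative series (`compute_age_series`) is the same recursion
emitting one layer per year.

## Raster and vector I/O

GeoTIFFs are read and written with `tifffile`. Georeferencing (a six-term
affine transform and a CRS identifier) is stored in the standard
ModelPixelScale/ModelTiepoint tags plus a JSON ImageDescription that is
authoritative on read; nodata uses the GDAL_NODATA ASCII tag, with 0 as the
age map's nodata value. The canonical layout is one single-band GeoTIFF per
year (a multiband reader is a convenience). Pixel area is taken from
configuration in hectares rather than derived from the CRS, because
synthetic grids use abstract planar coordinates; a helper computes it from a
projected transform when one is present. Alignment between the stack and any
mask/predictor raster is validated (shape, transform, CRS) as a report
rather than an exception, so callers can decide severity. Country polygons
travel as GeoJSON handled with `shapely`.

## Synthetic landscape

The generator defines the study conditions for every desk-scale run. Each
pixel follows a Markov chain with one piece of memory:

* UNDISTURBED → NONFOREST with annual hazard 0.02, or → DEGRADED with 0.01;
* DEGRADED → NONFOREST with 0.05;
* NONFOREST → PLANTATION with 0.002 (absorbing, recorded in the mask), or
  → REGROWTH with 0.15 — but only after ≥ 3 consecutive NONFOREST years,
  so the designation rule has both eligible and ineligible pixels to
  discriminate;
* REGROWTH → NONFOREST with base hazard 0.12;
* WATER (1% of pixels) is static.

The re-clearance base hazard of 0.12 makes the expected regrowth spell
roughly geometric with median near 5 years, matching the field observation
that most regenerating tropical forest is very young; hazards of 0.02/yr for
deforestation are typical humid-tropics magnitudes. Spatial structure enters
through log-normal modifier fields (white noise convolved with a Gaussian
kernel, length scale 5 px, σ = 0.5) multiplying the deforestation and
re-clearance hazards — this heterogeneity is what creates persistent pockets
of old regrowth, and it shifts the realised mean age above the homogeneous-
hazard expectation, as in real landscapes.

Predictor rasters are smoothed standard-normal fields mapped through the
normal CDF onto each predictor's range. The default set is 8 of the study's
32 predictors; those flagged causal multiply the re-clearance hazard by
exp(effect × z), a monotone log-linear link (defaults: elevation −0.5,
forest-landscape-integrity −0.4, forest loss +0.5; the rest null), so older
forest accumulates where integrity and elevation are high and loss is low.
The true-effect record is returned for parameter-recovery tests. Countries
are a Voronoi partition of seeded random points; the id raster assigns each
pixel to its nearest seed, which is by definition the Voronoi cell containing
the pixel centre, so raster and polygons agree exactly. Carbon accumulation
rates are a positive smoothed field with mean 4.6 MgC ha⁻¹ yr⁻¹ (the
magnitude implied by ~3 GtC over 25 years on ~26 Mha of young regrowth) and
25% relative spread.

What the generator does *not* emulate: realistic biogeography, classifier
confusion between regrowth and plantations (synthetic plantations carry their
own class, so the oil-palm mask never intersects mapped regrowth — the
masking rule is exercised with constructed masks in the tests), calibration
to real transition frequencies, and sub-annual phenology. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not the accuracy of any real-data product.

All randomness flows from one seed through named `SeedSequence` spawn keys
(transitions, predictors, countries, carbon, hazard fields), so each
component is individually and jointly reproducible.

## Grid summaries and hotspots

Age maps aggregate to square cells (default 30 km; synthetic tests use
smaller multiples of the 30 m pixel) anchored at the raster's top-left
corner in the raster's own CRS, since the projection used for the published
30-km cells is not stated. Cell mean age is the unweighted mean over
regenerating pixels (equal pixel areas); conservation of total regenerating
area across cells is exact and asserted. Hotspot thresholds are
linear-interpolation percentiles (default 75th and 90th) of per-cell
old-forest area computed **over cells with nonzero old area** — the
published hotspot maps plot only forested cells — with a config flag to
include zeros; membership is at-or-above, so ties at the threshold are in,
and the 90th-percentile set nests inside the 75th by construction.

## National statistics

The long country × age-year area table is the hub. Derived quantities:
old (≥ 20 yr) and young (≤ 5 yr) areas, area-weighted mean age with its
standard deviation (the published "±" is interpreted as SD), and the
pixel-wise lower median. Shares are reported to the nearest integer percent,
ratios to one decimal, matching the published precision. The share ratio
ρ_c = old-share / all-share satisfies Σ_c all_share_c ρ_c = 1 to machine
precision and is scale-invariant; both are asserted. Countries with zero
all-age area are omitted.

The deforestation-timing companion curve counts transition events into
NONFOREST from any non-NONFOREST land-cover class (NODATA origins excluded —
an appearance from an observation gap is not an observed clearance; repeat
clearances of the same pixel count separately), buckets them by lookback
(target year − event year) into the same age bins (default 3–5, 6–10, 11–15,
16–20, 21–25, 26–30, 31–34, chosen to match the published "6–10 years"
example and partition [3, 34]), and normalises to sum to 1 over those bins.

The carbon projection sums rate × pixel area × horizon over pixels with
3 ≤ age ≤ 5 (defaults: horizon 25 years, rates in MgC ha⁻¹ yr⁻¹), reported
in GtC (10⁹ MgC); it is exactly linear in rates and is checked against a
per-pixel loop.

## Random-forest protocol

Sampling is stratified by age year: up to `n_per_age` pixels per age 3–34,
uniform without replacement (the full-scale figure is 10,000 per age;
synthetic runs default to a few hundred — the contract, not the count, is
what the tests pin down). Predictors are nearest-cell lookups; rows hitting
nodata are dropped and logged. The correlation filter removes predictors
greedily: while any pair exceeds |r| = 0.9, drop the member of the worst
pair with the larger mean absolute correlation to the remaining predictors —
the published rule does not state a tie-break, so this one is adopted and
logged.

Training uses a 75/25 split stratified by age decile, then a grid search
over ntree (100–1500) and mtry (3–29) under 7-fold cross-validation on the
training split by RMSE (folds stratified by age decile); `search=False`
skips the grid and uses the configured final values (500 trees, mtry 18 at
full scale). R² and RMSE are computed only on the held-back test split.
One model per region is the default, with a pooled model available.

Variable importance is the corrected impurity measure realised through
shadow variables: the model is refit on the data augmented with a permuted
copy of every predictor (candidate-per-split count doubled to keep the
selection pressure comparable), and the reported score is the raw impurity
importance minus the shadow's — an implementation-independent way to remove
the cardinality/frequency bias of impurity importances. Permutation
importance is always co-reported as a cross-check. Partial dependence
clamps one predictor to each of 50 grid values spanning its observed range
and averages predictions over all rows, returning the data quantiles for
the rug.

The recovery experiment that validates the whole chain plants a single
negative elevation → re-clearance link (effect −1.0, no other causal
predictors, hazard σ = 0.3, 80 × 80 grid, 150 samples per age) and requires
elevation to rank first in corrected-impurity importance with an increasing
partial-dependence curve in ≥ 9 of 10 seeded replicates.

## Pipeline

Stages run in dependency order; each writes a sidecar manifest keyed on a
hash of its config section plus the checksums of its input files. A stage
whose key and outputs are intact is skipped on re-run, so editing one config
section re-runs exactly the stages downstream of it. Two fresh runs with the
same config produce byte-identical artifacts; the tests assert this for the
age GeoTIFF and the CSV tables.

## Numerical choices and limitations

* Percentile definition: NumPy's linear interpolation between order
  statistics; membership is ≥ threshold.
* Median: lower order statistic on ties (ages are small integers, so
  interpolation would manufacture non-attainable half-years).
* Degenerate inputs: empty age maps yield zero-cell grids with a warning;
  all-equal hotspot pools put every nonzero cell in the top tier; zero
  pan-tropical old area makes the share ratio undefined and raises.
* Desk-scale defaults (96 × 96 to 128 × 128 grids, 100–200 samples per age,
  ≤ 150 trees) were chosen so the full synthetic pipeline and its validation
  run in seconds to minutes; the full-scale settings remain reachable
  through configuration.
* The synthetic landscape cannot validate classification accuracy,
  plantation confusion, or any real-world area estimate; it validates the
  algorithms and their invariants only.
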