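# Methods

This note documents the statistical procedures, the parameters that
matter, the numerical choices made where the design was genuinely open,
what the synthetic generator does and does not emulate, and known
limitations.

## Data model

The atomic observation is one (geographic unit, product, season,
production system, harvest year) record with area (ha), production (mt)
and yield (mt/ha). Missing is a first-class state carried as NaN and
serialized as an empty CSV field: in subnational reporting "not
collected" is distinct from "zero harvest" (surveyors are often not sent
to failed areas at all), and conflating the two would bias any analysis
of bad years. Where area > 0 and production are both present, yield must
equal production/area within a relative 1e−6; readers enforce this in
strict mode and report violations in lenient mode.

Units join to boundary polygons through the `fnid` geocode; an fnid is
specific to a boundary vintage, so a redrawn district gets a new fnid and
the calibration step is what connects the two eras.

## Quality control

Two screening rules, applied per series, writing a single integer flag
per record (0 none, 1 outlier, 2 low variance; 1 wins on collision since
a spike is the more actionable signal):

**Outlier rule.** A year flags when all three hold: Z-score above 3
(mean and sd over the observed yields of that series), value at least
250% of the nearest observed preceding *or* following yield, and series
maximum above 0.5 t/ha. Numerical conventions, each switchable in
`QCParams`:

- *sd is population (ddof 0)*. The rule is a screening heuristic, not an
  inference; the worked examples in the test-suite are stated under this
  convention (a 20-year series of nineteen 1.0s and one 6.0 gives
  z = 4.359).
- *Neighbour test is inclusive* (≥ 250%), reading "at least" literally.
- *Neighbours skip missing years* to the nearest observed value;
  endpoint years use their single neighbour.
- *Z-scores are computed once on the raw series*, not iteratively
  re-estimated after masking flagged values: a single screening pass.
- sd = 0 (constant series) produces no flags.

**Low-variance rule.** Second differences d(t) = y(t+1) − 2y(t) + y(t−1)
are computed on maximal runs of consecutively observed years (a reporting
gap breaks the run — curvature across a gap is not comparable). Wherever
`run_length` = 3 consecutive |d| fall below 1.5% of the series median
(all observed yields), every year spanned by the window (5 years) is
flagged; overlapping windows merge. The strict `<` reading makes exact
zeros (repeated values, perfect lines) always qualify. The informal
equivalence "at least four values on a trend" is not implemented as a
separate rule; the formal three-consecutive-second-differences criterion
is the rule.

Both rules are invariant under positive rescaling of a series (provided
the 0.5 t/ha guard holds on both sides), which is what lets flags carry
through Case A calibration unchanged.

## Standardization

**Sub-crop folding** sums production and area within each (unit, season,
system, canonical product, year) cell; missing contributes nothing, an
all-missing cell stays missing, and yield is recomputed. QC flags reset
to 0 because they described the pre-merge series.

**Expected production** per member unit is a normalized Gaussian
convolution over observed years (kernel sd 3 years, truncated at 4 sd;
beyond truncation reach the nearest observation is used so the estimate
exists on the whole span). Evaluating the climatology at unobserved years
— including in the coverage denominator — is a deliberate choice: a
unit's expected contribution does not vanish just because it failed to
report, and that is precisely what the gate must measure. Normalized
convolution preserves constants and interpolates a symmetric gap to the
midpoint (the [10, missing, 30] series gives 20 at the gap).

**Coverage gate**: a coarse-unit year is emitted iff
Σ climatology(reporting members) / Σ climatology(all members) ≥ 0.5.
Members that never report the product at all appear in neither sum. The
emitted value is the *raw sum of reported values* — never inflated by
1/coverage — keeping the minimal-adjustment ethos; inflation would
manufacture data. Lowering the gate can only add years (monotonicity),
which the tests assert.

Season heterogeneity ("annual" vs "short rains") is never merged
implicitly. Planted-vs-harvested area is metadata (`area_basis` in
configs); no conversion is attempted.

## Boundary calibration

**Detection.** Both vintages must share a coordinate reference
(geographic inputs are projected by the built-in sinusoidal equal-area
transform before any area arithmetic; planar inputs are assumed already
equal-area). Old/new units that are mutual best matches by intersection
area, with |A_new − A_old|/A_old < 10% and intersection ≥ 90% of the old
area, pass through untouched (the 10% trigger is measured against the
old geometry). The rest form connected components of the intersection
graph. A component is Case A when the outer boundary is conserved
(symmetric difference ≤ 1% of the union area, configurable) *and* the
component is a pure split (each new unit ≥ 99% inside one old unit) or
pure merge (dual condition); otherwise Case B. A 3-into-4 re-tiling with
conserved outer boundary is therefore Case B: its new units straddle old
ones, so post-change production shares cannot stand in for the old
footprint.

**Case A.** Shares s_i = P_i / Σ_j P_j per crop, with P_i the mean annual
production of new unit i after the change. The averaging window is the
intersection of the new units' reporting years when non-empty (means over
different windows are not comparable), else per-unit means with a logged
warning. Crops that some new unit never reports fall back to
cropland-area shares (polygon-area shares without a raster), logged in
the plan's provenance. Both production and area scale by s_i, so the
implied yield of every new unit equals the old yield and per-year totals
are conserved exactly (tolerance 1e−9 in the report, machine epsilon in
practice). A merge (n old → 1 new with conserved outer boundary)
needs no ratios: the new series is the sum, with any missing contributor
making the output year missing.

**Case B.** Weights w = cropland(new ∩ old_j) / cropland(old_j) from the
raster, crop-independent, clamped to [0, 1]; zero-cropland old units fall
back to polygon-area ratios with a warning. Missing propagation is
strict: if any contributing old unit is missing in year t, the output is
missing at t — a partial weighted sum would silently underestimate,
mirroring the coverage philosophy. Totals are conserved iff the new units
tile each old unit's cropland (Σ_new w = 1); the conservation report
carries the per-old-unit tiling sums, and the defect under a dropped
sliver equals the untiled weight times the old production (closed form,
asserted in tests).

Calibration direction is always old → current vintage. Multi-vintage
histories are handled by pairwise application in sequence; no automatic
chaining.

**Zonal extraction** uses exact polygon–cell intersection areas (shapely,
vectorized over the cell grid), not cell-centre sampling: Case B weights
on small units would otherwise be quantized by the raster resolution.

## Cross-validation

National annual production = sum over units, seasons and systems by
harvest year (the closest analogue to calendar-year national reference
tables; switchable). Years with no observed subnational production are
absent, not zero. Pearson r per (country, product) over exactly matching
years, defined only with ≥ 5 overlap years and non-constant series;
undefined cells carry their reason. Raw production is correlated by
default; log-correlation is a flag. Summary medians are taken over
defined cells. Because Case A calibration conserves national totals,
validation results are invariant to it (asserted as a cross-module
property test).

## Synthetic generator

The generator emulates: lognormal interannual yield variability around a
linear trend (yields are positive and right-skewed; CV-parameterized),
production = yield × area with per-unit base areas, intermittent
reporting (unit-years dropped with configurable probability), injected
high-yield spikes and repeated-value runs with truth labels,
split/merge/reorganization boundary events realized on integer-grid
rectangles (intersection areas exact by construction), a cropland
surface, and a national reference series (optionally noised). It does
*not* emulate: spatially correlated weather shocks across districts,
reporting biases correlated with bad years, heaping/rounding of reported
values, season splits within a country, or realistic country geography.
Passing recovery tests therefore demonstrate the rules' correctness and
the pipeline's bookkeeping, not detector performance on real data.

Default scenario: 2 regions × 5 districts, 2 crops, 20 years, mean yield
1.5 t/ha, trend 0.01 t/ha·yr, yield CV 0.12, area 5000 ha ± 5%, two
spikes (×6) and two 5-year repeated runs. The recovery ensemble uses 25
districts × 2 crops (50 series) over 20 seeds — sizes at which the whole
suite runs in seconds while every code path (gaps, endpoints, fallbacks)
is exercised.

**Clean backgrounds.** Recovery fixtures promise that injected anomalies
are the only rule triggers, and unconstrained noise cannot promise that:
at low CV random near-linear stretches trip the low-variance band, at
high CV random spikes trip the neighbour-ratio test, and no CV makes both
probabilities vanish over a thousand series. Clean background is
therefore an explicit fixture property: background noise is
rejection-sampled until every Z-score is below 2.5, every adjacent-year
ratio below 2.0, and every second difference at least 1.3× outside the
1.5%-of-median band — margins chosen so that, by the rules' own
arithmetic, injection side-effects (shifted medians, inflated sd, run
edges) cannot create or destroy a flag. After injection the generator
re-verifies the implied flag set against the truth labels with an
independent closed-form evaluation and redraws on mismatch. Perfect
precision/recall is thus a designed property of the fixture; the test
verifies the *implementation* against an independently coded oracle.

All randomness flows from one `numpy.random.default_rng(seed)` (PCG64) in
a fixed iteration order; fixed seed means byte-identical outputs.

## Geospatial I/O without a GIS stack

Boundary I/O supports GeoJSON and a minimal GeoPackage profile
implemented directly on stdlib sqlite3 plus shapely's WKB codec (a
GeoPackage geometry blob is a short "GP" header followed by ISO WKB);
only simple 2-D (multi)polygon feature tables are supported, which is
all a boundary vintage needs. Invalid geometries are repaired by the
zero-buffer convention when that yields a valid non-empty polygon, else
rejected by identifier. Rasters are single-band GeoTIFFs georeferenced by
ModelPixelScale/ModelTiepoint tags via tifffile. The coordinate reference
of inputs is auto-detected from file metadata; geographic (lon/lat)
geometries are projected with a world sinusoidal transform — equal-area
by construction, x = R·λ·cos φ, y = R·φ with the authalic radius — before
any area computation.

## Pipeline

Stages always run in the order QC → standardize → calibrate → validate;
each is independently toggleable. The manifest records the config
snapshot, SHA-256 of every input file, per-stage in/out/flagged/
missing-created counts and the package version; stage k's output count
equals stage k+1's input count by construction, and identical inputs and
config reproduce identical outputs and manifest (timestamp aside). A
stage failure aborts with the stage name, writing the partial manifest.

## Limitations

- A static cropland surface stands in for year- and crop-specific
  harvested-area maps in Case B weights; the transfer inherits that
  uncertainty.
- Case A shares assume post-change production shares reflect the
  pre-change spatial distribution; a split coinciding with a structural
  production shift will misallocate history.
- The coverage gate depends on the climatology being estimable per
  member; units with a single observed year get a flat climatology.
- The GeoPackage profile does not implement the full specification
  (spatial indexes, non-polygon geometries, projected CRS registries).
- No gap-filling or imputation anywhere, by design: absent values stay
  absent.
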