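# Methods

This note documents the models and conventions the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Indicator definitions

**Priority subsets.** Let *C* be the validated checklist (taxon ×
region listings with an `is_invasive` impact-evidence flag) and *E* the
global EICAT table (taxon × mechanism with magnitude in
MC < MN < MO < MR < MV). For a scope and mode, the subset is:

| scope/mode | species selected |
|---|---|
| realized/total | listed with `is_invasive` true (in the filter region, or anywhere) |
| potential/total | listed and carrying ≥ 1 EICAT assessment |
| potential/mechanism:*m* | listed and assessed for mechanism *m* |
| potential/worst | listed with max magnitude ∈ {MR, MV} |

Realized mechanism/worst modes run the identical magnitude/mechanism
logic over a *regional* assessment table; because no such table is yet
systematically published, requesting them without one is a typed
`MissingDataError` (CLI exit code 3), not a silent empty result. Species
assessed under EICAT but listed nowhere are excluded: the indicators
describe the regional IAS assemblage, not the assessment catalogue.

**Trends.** The trend value at year *t* is the number of subset species
whose first introduction record is ≤ *t*. Global series use each
species' earliest record across regions (a species counts once, at its
first arrival anywhere); region-filtered series use the region's own
record. The series runs flat from the most recent first record to the
evaluation year — the current indicator value is *assumed to sit at the
level of the latest recorded introduction*, since impact evidence is not
re-assessed on a schedule. Species without any usable first record
cannot enter the series; they are returned in `TrendSeries.uncounted`
and logged, because dropping them silently would understate current
values. An event-counting variant (counting species–region introductions
rather than species) was considered and rejected for the default: the
per-species convention keeps the trend's plateau equal to the subset's
"current value" and matches how cumulative-IAS curves are read.

**Spatial index of potential impact.** For each subset species, its
suitability surface (relative likelihood of occurrence in [0, 1]) is
masked to the regions where the species is listed — suitability projects
impact only within the current invaded range — and the masked surfaces
are summed per cell. The index is exactly additive over species, and
bounded by the subset size. Because each surface is max-rescaled per
species (a *relative* likelihood), sums are in "suitability units", not
calibrated expected species richness; no richness calibration is
applied or claimed.

**Information status.** For each region, over the set of *all* alien
species listed there (not only invasive-flagged ones):

- In = 100 × (species with a first-record year for that region) / listed;
- Im = 100 × (species with the impact flag populated) / listed;
- Rd = 100 × (species × time-slice pairs with ≥ `min_records` unique
  records in the region) / (listed × number of slices), over consecutive
  `slice_years`-year slices of [`window_start`, `window_end`];
- composite = (In + Im + Rd) / 3, undefined if any component is
  undefined;
- burden = number of listed alien species (reported alongside, never
  averaged in).

A region with no listed species has **undefined** indicators, kept
distinct from 0% so that "nothing reported" and "reported and absent"
render differently on maps. Values are stored at full precision;
delimited-text reports round half-up to integers for display only.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `rd.window_start`/`window_end` | 1970 / 2019 | 50-year assessment window |
| `rd.slice_years` | 5 | slice length; window must divide evenly |
| `rd.min_records` | 10 | inclusive adequacy threshold per species × slice |
| `rd.since_introduction` | false | count a species' slices from its regional first record |
| `envelope.quantile_clip` | 0.025 | tail fraction trimmed per climate layer |
| `envelope.min_presences` | 10 | refuse envelope fits below this |
| `year_window` | 1500–2030 | plausibility window for all parsed years |
| `date_granularity` | year | duplicate key uses year (or verbatim date) |

The Rd threshold is deliberately low — it asks whether *range dynamics
could be modelled at all*, not whether sampling is dense — and is
inclusive ("at least 10"). The `since_introduction` variant exists
because the fixed-window denominator penalizes recent arrivals; both
interpretations are defensible, the fixed window is the primary
definition, and no claim is made that either reproduces any particular
published country score.

## Harmonization conventions

- **Names** are canonicalized through a two-column synonym table whose
  canonical names are fixed points (no chains/cycles, so the operation
  is idempotent). Full backbone-taxonomy matching is out of scope;
  unmatched names pass through and are logged, because GRIIS/GBIF
  mismatches are routine and silent failure would corrupt joins.
- **Dates** reduce to single years: ISO 8601 dates/datetimes, bare
  years, and `/`-joined ranges (earliest year) are accepted; everything
  else is flagged unusable. The parser is total — arbitrary text never
  raises.
- **Duplicates**: exactly one record kept per (taxon, lat, lon, year),
  comparing parsed coordinates by exact float equality (no rounding).
  Year-level dating is the default key because first records are
  year-resolution; verbatim-date granularity is a config option.
- **Region assignment** is boundary-inclusive point-in-polygon; a point
  on a shared boundary goes to the lexicographically smallest region id.
  The tie-break is arbitrary but deterministic, which reproducibility
  requires; boundary points are measure-zero in real data.
- Readers collect row-level violations into error reports rather than
  aborting: indicator runs over aggregated, messy data must degrade
  gracefully, and a dropped-but-unreported row would bias percentages
  invisibly. Structural problems (missing mapped columns, unknown EICAT
  magnitudes, unparseable files) raise typed errors instead.
- Only `occurrenceStatus = present` listings are counted; other statuses
  (absent, doubtful) are reported and excluded.
- Everything is WGS84 longitude/latitude; inputs in other CRSs are an
  error, not auto-reprojected, keeping spatial semantics bit-stable.

## The envelope model

The built-in suitability model is a rectangular climate envelope in the
BIOCLIM tradition: per climate layer, presence values are clipped to the
[q, 1−q] quantiles; a cell scores the fraction of layers whose value
falls inside its envelope; scores are rescaled so the grid maximum is 1.
It is deterministic, has an exact geometric oracle under coordinate-
gradient layers, and exists so the pipeline runs offline end-to-end. It
is **not** a calibrated ecological niche model: no background selection,
no evaluation statistics, no regularization. Production use should
supply externally modelled surfaces as georeferenced single-band TIFFs
(values in [0, 1], shared grid, nodata −1); the indicator algebra is
agnostic to where surfaces come from. Region masking uses cell-center
containment (not area-weighted overlap): deterministic, exactly
oracle-checkable, and standard at indicator grain; the default synthetic
grid is 0.5°, configurable.

## The synthetic world

The generator emulates the statistical structure of the real inputs:
regions tile a lon/lat grid as rectangles (so containment oracles are
exact); each species has a rectangular geographic niche and invades a
random set of intersecting regions; introduction years follow a
two-phase history (slow before 1950, accelerating after — cosmetic, so
trends take their characteristic shape); occurrence sampling intensity
varies by region and 5-year slice; exact duplicate records are planted
at a configured rate; and reporting gaps censor first records and
impact flags. Ground truth (niches, gap sets, duplicate counts, subset
membership) is carried alongside, so every indicator can be checked
closed-loop against brute-force recomputation.

Default scale mirrors a global amphibian-style demonstration: **82
regions, 75 alien species, 11 invasive**, seven EICAT mechanisms with
geometrically decaying prevalence (predation-type mechanisms dominate),
magnitude distribution (0.15, 0.25, 0.30, 0.20, 0.10) over MC–MV.
Unstated-by-any-source rates were fixed once at values realistic for
GRIIS-style data: 30% of first records censored, 40% of regional impact
flags unpopulated, mean sampling effort 0.6 with Poisson mean 6 records
per species × region × slice at full effort, 5% planted duplicates. At
these rates the Rd sub-indicator is near zero at default scale — an
intentional reflection of occurrence-adequacy being the weakest evidence
dimension; the `no_gaps` scenario (all species flagged and dated,
sampling guaranteed to meet the Rd threshold in every slice) provides
the complementary closure check in which every defined composite must be
exactly 100.

What passing these tests shows: the indicator algebra, boundary
semantics, bookkeeping and determinism are correct. What they do not
show: behaviour under real-data pathologies absent from the generator —
coordinate imprecision and rounding-induced duplicates, taxonomic
drift beyond a static synonym table, non-rectangular ranges, spatially
autocorrelated sampling bias within regions, and checklist errors.

## Numerical and degenerate-input conventions

- Percentages and the composite are exact rational arithmetic in
  float64; the composite is asserted to equal the mean to 1e-9 in tests.
- Trend counts are integers via sorted-array bisection; no smoothing or
  uncertainty estimation is applied (deliberately out of scope).
- Empty subsets yield empty series with a warning, not an error; an
  evaluation year earlier than the latest first record is a parameter
  error.
- Surfaces validate to [0, 1] within 1e-6 on write *and* read; values
  outside are errors, never clamped. Raster round-trips are float64 and
  preserve the geotransform exactly.
- Suitability sums treat a species' nodata cells as zero contribution;
  cells with no data from any species are nodata in the index.
- Scenario generation uses per-stage seeded `numpy` generators
  (`default_rng([seed, stage])`), so world, history and occurrences are
  independently reproducible and insensitive to call order.

## Known limitations

- Realized mechanism/worst sub-indicators are exercised only on
  synthetic regional-assessment tables, pending real published data.
- The spatial index is not richness-calibrated (see above); values are
  comparable across subsets on one grid, not across studies.
- No fuzzy name matching, no coordinate-uncertainty filtering, no
  modelled trend uncertainty — all noted as future hooks, not silently
  approximated.
- GeoJSON regions crossing the antimeridian are not re-split; supply
  pre-split geometries.
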