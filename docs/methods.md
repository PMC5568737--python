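# Methods

## Model and assumptions

The package implements fixed-start thermal-time models: a phenophase begins
when accumulated growing degree days (AGDD) from January 1, above a 0 °C
base, reach a species × phenophase specific threshold.  Daily GDD uses the
simple-average convention — `max(0, (tmin + tmax)/2 − base)`, extremes
averaged *before* truncation — matching operational GDD map products.  The
source texts for this model family specify only "accumulated heat units
(0 °C base)"; truncation order is our choice and is the only place the GDD
arithmetic is ambiguous.

The universal threshold is the arithmetic mean of the AGDD observed at
onset across all calibration site × years.  This deliberately ignores
site effects, local adaptation, chilling, and photoperiod; the model's value
is that it can be inverted cheaply on any daily temperature grid.
Alternative base temperatures, variable start dates and chilling/photoperiod
terms are out of scope by design.

Assumptions worth keeping in mind:

* onset is driven by forcing heat alone, identically at every site;
* the first "yes" report approximates the true onset from above (an
  observer can only be late, never early), so thresholds fitted from sparse
  visit schedules carry a positive bias of up to one visit interval's worth
  of heat — which largely cancels when predictions are compared with
  observations collected under the same schedule;
* accumulation restarts every January 1, so no cross-year prior-"no"
  lookback is performed when pairing a first "yes" with its preceding "no".

## From status records to site phenometrics

Per individual and year we take the first "yes" on/after Jan 1 (later yeses
are ignored) and the latest "no" strictly before it in the same year.
Site-level values are means across individuals; the prior-"no" mean is taken
over the individuals that have one (the first-yes definition is a mean, the
prior-no side is defined symmetrically).  Conflicting same-day yes/no
reports for an individual resolve to "yes" and are counted in the log.

Filtering retains a phenometric iff (a) it has a prior "no" and the
first-yes − prior-no gap is **strictly** less than 15 days, (b) the first
yes is at or before DOY 172 (breaking leaf buds, leaves) or DOY 213 (open
flowers, ripe fruits) — both cutoffs inclusive, and (c) its site's region
tag is not excluded (default excluded tag: `AK`; a string-tag filter, not a
geometry test).  Removals are attributed to the first failing rule in the
order gap → cutoff → region, so audit counts reconcile exactly with
input − output.  Fractional day-of-year values survive filtering unchanged;
rounding to a calendar day (half-up) happens only when a phenometric is
looked up in the daily AGDD step function.

The calibration/validation split is by year: the holdout year (default
2016) validates, all earlier years calibrate, later years are dropped with
a warning.  Models require ≥ 30 distinct calibration site × years
(inclusive).

## Evaluation

The null model predicts every onset with the calibration-period mean of the
site-level mean first-yes DOY.  NSME is computed against that constant on
both pools — on the validation year the null constant remains the
calibration fit.  On calibration data this makes NSME coincide with the
classic Nash-Sutcliffe efficiency about the observed mean (asserted
numerically in the tests).  R² is the squared Pearson correlation of
predicted vs observed DOY; it is direction-blind, which is why candidate
selection also requires NSME ≥ 0.4 and MAE ≤ 10 days (all thresholds
inclusive, calibration metrics only).  Residuals are `predicted − observed`:
negative means the model called the phenophase early.

Site × years whose AGDD never reaches the threshold are flagged, excluded
from the metrics and counted (`n_not_met`) rather than imputed or silently
dropped — silent dropping would bias MAE.  Zero-variance degenerate inputs
raise an undefined-metric error which the pipeline converts to a
non-candidate reason code.  Human-readable summaries print days to one
decimal and R²/NSME to two; JSON carries full precision.

## Geographic extensibility

Long-term spring temperature — the mean of the four January–April monthly
means of daily `(tmin+tmax)/2`, averaged over climatology years — proxies
the forcing axis.  The climate envelope is the closed `[min, max]` interval
of spring values at the calibration sites (the most literal reading of a
one-variable envelope; no percentiles, hulls or kernels).  The species
range, supplied as GeoJSON polygons, is rasterized onto the spring grid
with center-in-polygon membership, and coverage is the percent of range
cells whose spring value falls inside the envelope, weighted by
cos(latitude) as an area proxy on a regular geographic grid (a flag
switches to raw cell counts for brute-force cross-checks).  Sites falling
outside the grid or on missing cells are listed as rejects, not fatal.

## Maps

Running a model over a gridded daily stack yields, per cell, the first DOY
whose AGDD reaches the threshold.  Two sentinels are kept distinct in the
integer raster: `NOT_MET` (−1, the year's heat never suffices) and `NODATA`
(−9999, missing input or clipped).  The production workflow clips twice —
species range, then the envelope-retained part of the range — and each clip
can only shrink the map's DOY spread.  A stack shorter than the calendar
year is treated as a partial/forecast window from Jan 1; crossings beyond
its horizon report as not met within the window.

Rasters are read and written as plain-text ESRI ASCII grids and stacks as
NPZ archives; range polygons as GeoJSON (WGS84).  PNG quicklooks are
rendered with matplotlib.

## Synthetic world

The generator emulates the features of a continental status-data network
that matter to this method, with defaults chosen once as plausible for
temperate eastern North America:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 50 | observation sites, uniform over the lat/lon box |
| `lat_min..lat_max` | 30–48° N | latitudinal climate gradient |
| `intercept`, `lat_slope` | 28 °C, −0.5 °C/° | annual-mean temperature vs latitude (~13 °C at 30° N, ~4 °C at 48° N) |
| `seasonal_amplitude` | 12 °C | sinusoidal cycle, coldest Jan 1 |
| `noise_sd`, `ar1_coef` | 2 °C, 0.7 | stationary AR(1) day-to-day noise |
| `diurnal_half_range` | 5 °C | tmin/tmax = mean ∓ range |
| species | 450 / 700 / 1300 GDD | true thresholds spanning the range reported for temperate shrubs and trees |
| `individuals_per_site` | 3 | plants per species per site |
| `onset_jitter_sd` | 2 d | individual onset spread around the site onset |
| `visit_interval` | 7 d | observer visits, per-individual-year random phase |
| `years` | 2011–2016 | 5 calibration years + holdout 2016 |

AR(1) noise (rather than white) makes the interaction between visit-schedule
imprecision and AGDD variance realistic.  All randomness flows from one
`numpy` generator seeded per run, so the same config and seed reproduce the
dataset, the reports and the output files byte-for-byte.

What the generator does **not** emulate: spatial clustering of observers
(urban bias), observer error (false yes/no reports), multi-year individual
dropout, elevation and coastal effects, and real interannual climate
anomalies.  Passing parameter-recovery tests therefore demonstrates the
correctness of the pipeline's arithmetic and plumbing under the stated
observation process — not that real networks satisfy the thermal-time
assumptions.

## Numerical conventions and degenerate inputs

* Fractional onset DOYs round half-up to a calendar day before AGDD lookup.
* Leap years use the year's own calendar day index (no normalization);
  accumulation is physical, not calendrical.
* `doy_threshold_met` returns the smallest day with AGDD ≥ threshold;
  thresholds ≤ 0 cross on day 1; a never-reached threshold returns a
  not-met marker.
* Because AGDD is a daily step function, a threshold estimated as the mean
  of per-record AGDD-at-onset exceeds roughly half of those records'
  values, so their predicted crossing lands one day late even in a
  noiseless world: expect a ~0.4–0.5 day calibration MAE floor from
  discretization alone.  Only a model carrying the exact generating
  threshold reproduces every onset day-for-day.
* Ties in the gap rule are strict (< 15), cutoffs and the n ≥ 30 rule
  inclusive — matching the conventions stated above exactly.

## Verification study sizes

The shipped tests and the acceptance script use: 50 sites × 5 calibration
years for threshold recovery (exact regime: daily visits, zero jitter,
noiseless sinusoid); a 20-seed ensemble × visit intervals {1, 3, 7, 14}
with one species (700 GDD) for the observation-degradation study; 1,000
randomized series plus a 20 × 20 random stack for crossing-search oracle
equivalence; and a 30 × 8 monotone-gradient grid for the envelope
brute-force check.  These sizes give stable ensemble means while keeping a
full verification run around a minute on one CPU.

## Known limitations

* One variable, one envelope: extensibility considers spring temperature
  only; precipitation, chilling and photoperiod constraints are not
  represented.
* The envelope is sensitive to single extreme calibration sites (min/max,
  not percentiles) — by construction.
* Thresholds fitted from sparse visit schedules are biased high by late
  detection; comparisons across networks with different visit cadences
  should account for this.
* Region exclusion is tag-based; records without a region tag are never
  excluded by rule (c).
* The cos(latitude) area weighting is exact for a spherical Earth and
  regular geographic grids; no projection support is included.
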