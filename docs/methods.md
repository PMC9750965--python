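# Methods

This note documents the statistical procedures implemented in `stratdust`,
the conventions and defaults behind them, what the synthetic-data
generator does and does not emulate, and the design choices made where
more than one reasonable convention exists.

## Calendar

All analysis happens on extended winters (NDJFM): Nov 1 through Mar 31,
labelled by the starting year ("1980/81"). Climatological arithmetic uses
a fixed 365-day year: generated calendars contain no Feb 29, and when leap
days occur in external data they are mapped onto Feb 28's calendar day
(both for the climatology and for anomalies). Each winter has exactly 151
days. Dates are calendar-day resolution throughout; there is no sub-daily
support.

## SSW detection

An SSW central date is the first day on which the daily-mean zonal-mean
zonal wind at 60°N/10 hPa is easterly (u < 0 strictly; u = 0 counts as
westerly). Two auxiliary rules complete the operational definition and
are exposed as parameters rather than hard-coded:

- `min_separation_days` (default 20): an easterly excursion starting
  within this distance of a previous central date is part of the same
  event. Without it, one long warming with brief westerly interruptions
  would count as several events.
- `recovery_days` (default 10): an excursion after which the wind never
  returns westerly for at least this many consecutive days before the
  winter ends is a final (springtime) warming and is excluded, since the
  vortex never re-forms.

These defaults are the conventional auxiliary rules of the wind-reversal
definition, not quantities estimated here; both are configuration.

## Episodes and the resampling null

An SSW episode is days +1…+30 after the onset; the onset day itself is
excluded, consistent with the "days [1, 30]" convention used for the
mortality windows. Windows are 30 consecutive 365-day-calendar days and
may extend past Mar 31 into April; days that extend beyond the available
record are treated as missing (and the pooled statistics skip them).

Each non-SSW replicate re-dates every observed event to the same month and
day in an extended winter drawn uniformly — with replacement,
independently per event and per replicate — from the winters containing no
SSW. With-replacement sampling keeps all replicates exchangeable even when
the no-SSW pool is small. A single seeded generator is consumed
replicate-major (all events of replicate 0, then replicate 1, …), making
every replicate reproducible from one integer seed. The default replicate
count is 1000.

## Seasonal cycle and anomalies

Per grid cell, the raw daily climatology (mean over years for each
calendar day in the record) is projected by least squares onto the mean
and the first three annual Fourier harmonics; higher harmonics are
discarded. Anomalies subtract the evaluated cycle on each day's calendar
day. The fit is calendar-agnostic: on a full-year record the harmonics
are mutually orthogonal and the projection is the classical Fourier
truncation; on an NDJFM-only record the least-squares fit remains exact
for any field inside the fitted span but partial-year sampling breaks
orthogonality with higher harmonics. Cells with gaps on some calendar
days are refitted on their valid days; all-missing cells get masked
coefficients and masked anomalies.

## Composites and Monte Carlo significance

The episode composite is the unweighted mean over all window days pooled
across events (not a mean of per-event means); the two conventions differ
only when windows have unequal valid-day counts, and pooling treats the
observed and null sets symmetrically. Box means over the two analysis
boxes — Eastern Mediterranean 30°–33.75°N, 10°–30°E and West Africa
16.25°–23.75°N, 12.5°–23.75°E, membership by cell centre with closed
bounds — are unweighted by default (the boxes span ≤ 7.5° of latitude);
cos-latitude weighting is available as an option.

Significance is a two-tailed Monte Carlo test at p < 0.10: the observed
composite is compared per cell against the [5th, 95th] percentile band
(linear interpolation) of replicate null composites, strict exterior;
boundary ties are not significant. Two null constructions are supported:

- **anomaly mode** (seasonal cycle removed): each replicate draws N random
  central dates, with replacement, from the pool of NDJFM days whose full
  post-onset window is covered by the record, and composites those
  windows. On a year-round record the coverage condition is vacuous and
  the pool is every NDJFM day; on an NDJFM-only record it excludes
  late-March dates whose windows would be truncated — otherwise the
  truncated windows inflate the null spread and the test becomes
  conservative.
- **full mode** (raw fields): the matched non-SSW episode sets are
  composited, so the null carries the same seasonal sampling as the
  observed episodes.

Fewer than 20 replicates are refused, since the 5th/95th percentiles are
then meaningless. Calibration under a true null (no planted response) is
part of the test suite: the flagged fraction averages ≈ 0.10 across
replicate fields.

## NAO index, regression maps, histograms

The station-based NAO index is the normalized SLP anomaly at Lisbon minus
that at Stykkisholmur, each normalized by its own NDJFM standard deviation
over the normalization period (default: the full record, since the classic
station definition does not fix one). Regression maps are per-cell OLS
slopes of a daily field on a daily index; display maps may be multiplied
by a caller-supplied scale (e.g. the mean NAO value during episodes),
which never touches the underlying slopes. Significance uses a two-sided
t-test with the effective sample size `N_eff = N(1 − r₁r₂)/(1 + r₁r₂)`
(r₁, r₂ the lag-1 autocorrelations of index and cell series), floored at
2 — the standard deflation of degrees of freedom for red-noise series.

Wind direction follows the meteorological direction-from convention,
`dir = mod(atan2(−u, −v), 360°)`, so the climatological northeasterly
trades fall in (0°, 90°) and the post-SSW southwesterlies in (180°, 270°);
calm (0, 0) is undefined and excluded. Histograms use the fixed bin
specifications of the analysis — dust: 500 × 20 μg m⁻³ in [0, 10000];
direction: 720 × 0.5° in [0, 360]; speed: 700 × 0.02 m s⁻¹ in [0, 14] —
with half-open bins (last bin closed), out-of-range values dropped with a
logged count, and probabilities normalized over the retained sample.

## Air-quality indicators

Both indicators pool days across all episode windows (mirroring the
270-day pooling of a 9-event set) and use only days with data. The
expected number of poor-air-quality days per 30-day period is
`exceedances / available days × 30`, which corrects for gaps and need not
be an integer; exceedance is strict (value > threshold), so boundary
values do not count — a measure-zero choice for continuous concentrations,
logged here as the adopted convention. Default thresholds are the EU
daily PM10 standard, 50 μg m⁻³, and the higher 260 μg m⁻³ regional
standard; a configurable sweep supports robustness checks. Null
replicates with zero available days are dropped with a warning; the
non-SSW mean is the mean over retained replicates. Random thinning of a
complete record leaves the indicator unbiased (verified over 1000 seeds in
the tests).

## Mortality

β is calibrated as `β = ln(1 + p/100) / 10` from the stated p = 0.98% per
10 μg m⁻³ of 2-day averaged PM2.5, so `exp(10β) − 1` reproduces the
statement exactly. Each event contributes 15 two-day periods (days
[1, 2] … [29, 30] after onset); a missing day within a pair leaves the
pair mean to the available day, and fully missing pairs are masked and
contribute nothing. Baseline mortality is supplied as an annual
per-person rate and converted to the 2-day basis as `M_b · 2/365`; the
temporal basis of the published rates is not fixed by the exposure-response
statement, so the conversion is isolated in one function
(`annual_to_2day`) and configurable. Population and baseline-mortality
rasters are used at the field grid (nearest-neighbour regridding when they
differ). Per-event totals sum region cells and periods (the order is
immaterial); the across-event spread is the sample standard deviation
(N − 1), appropriate for the small event counts involved.

## The synthetic world

The generator produces every input the pipeline consumes, with ground
truth recorded:

- **Stratospheric wind**: a westerly base state (35 m s⁻¹ mean, 8 m s⁻¹
  annual harmonic) plus AR(1) noise (lag-1 0.85, innovation s.d. 3 m s⁻¹),
  floored at +1 m s⁻¹ so non-event winters are strictly westerly; planted
  events force an easterly excursion that starts exactly on the planted
  day, lasts 10 days, and recovers well before winter's end.
- **Surface fields** (SLP, 10 m winds, dust, PM2.5, PM10): seasonal cycle
  (mean + up to three harmonics) + per-cell AR(1) noise (lag-1 0.6–0.85)
  + an additive response on days +1…+30 after each planted onset, uniform
  inside each analysis box (no edge tapering — this keeps closed-form
  recovery oracles exact). Defaults plant +50/−30 μg m⁻³ of dust
  (≈ 25%/15% of the 200 μg m⁻³ winter mean, matching the 20–30% and
  10–20% relative changes the composites should detect), a −4 hPa
  cyclonic SLP offset over the Eastern Mediterranean, and PM2.5/PM10
  dipoles of +15/−10 and +12/−25 μg m⁻³.
- **Study conditions**: 40 extended winters from 1980 with 24 planted
  SSWs (the observed NDJFM event rate), on a 1.25° grid covering
  10°–40°N, 20°W–35°E; smaller worlds are used in tests for speed and the
  event plan is always explicit configuration.
- **Stations**: nearest-cell series with independent Bernoulli gaps
  (default missing rate 0.15, typical of long station records), floored at
  zero. The pipeline's default stations sit inside the two response boxes
  as idealized counterparts of the Greek (worsening) and Senegalese
  (improving) sites.
- **Population/mortality**: uniform rasters (10⁵ persons per cell, 0.008
  per person-year) — magnitudes, not realism.

AR(1) noise was chosen deliberately so that the effective-sample-size
correction and the Monte Carlo machinery face serially correlated input,
as they do in reanalysis data. What the generator does *not* emulate:
spatially correlated noise, physically consistent dynamics between SLP,
wind and dust, dust advection or emission physics, spatially varying
climatologies, or heavy-tailed dust extremes. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under known ground truth — not the meteorological realism of any field.

A note on oracles: exact planted-offset recovery is checked against the
generator's own climatology (the same configuration with noise and
response amplitudes zeroed), because fitting the seasonal cycle on the
planted record itself folds part of the response into the climatology.
With the realistic event density (24 events in 40 winters) this shrinks
recovered box anomalies by roughly 15–25%, a record-length effect the
noisy-recovery check avoids by comparing against the matched non-SSW
composite mean instead.

## Numerical choices and degenerate inputs

- Percentiles by linear interpolation; ties at the band edge are not
  significant.
- `effective_n` floors at 2; zero-variance series are rejected rather
  than silently given r = 0.
- Missing station days propagate as NaN and every pooled statistic skips
  them; zero-available-day situations raise rather than return 0.
- Latitude is normalized ascending and longitude to [−180°, 180°) on
  read; time axes must be daily (the NDJFM season gap is allowed).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration gives bit-identical
  output, including across the CLI.

## Known limitations

- The published headline numbers (e.g. per-event excess deaths from
  CESM2/MERRA2 dust fields with GBD and CIESIN rasters, or the observed
  24-event inventory) require those external archives and are out of
  scope here; the package reproduces the *methods* and verifies them on
  synthetic ground truth plus the published arithmetic anchors.
- The choice of whether post-March window days are truncated or filled
  from April data depends on the record's coverage; windows simply treat
  absent days as missing, and the day counts are reported so the
  truncation fraction is visible.
- Box membership is by cell centre; cells straddling a box edge are all
  in or all out.
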