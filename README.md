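# stratdust

Sudden stratospheric warmings (SSWs) — midwinter breakdowns of the
stratospheric polar vortex in which the zonal-mean zonal wind at 60°N and
10 hPa reverses from westerly to easterly — project onto the surface as a
negative North Atlantic Oscillation (NAO)-like pattern that persists for
weeks. Over North Africa this weakens the subtropical ridge and the
northeasterly trade winds while driving southwesterly flow toward the
Eastern Mediterranean, producing a dipolar dust response: enhanced surface
dust and PM over the Eastern Mediterranean, reduced dust over West Africa,
with consequences for air quality and short-term mortality in both regions.

`stratdust` implements the complete inference chain behind this kind of
analysis as a tested, reusable Python library, for researchers in
subseasonal prediction, air quality and environmental epidemiology:

- **SSW detection** from the daily 60°N/10 hPa wind: the first easterly
  day of a qualifying reversal is the *central date*; close excursions are
  merged and final (springtime) warmings excluded.
- **Episodes and a matched resampling null**: *SSW episodes* are the
  30-day windows on days +1…+30 after each onset; 1000 replicate *non-SSW
  episode sets* keep the observed calendar dates but relocate each event
  into randomly drawn winters without an SSW.
- **Seasonal-cycle removal**: per-cell daily climatology projected onto
  the mean plus the first three annual Fourier harmonics.
- **Composites with Monte Carlo significance**: a cell is significant at
  p < 0.10 (two-tailed) when the observed episode composite falls outside
  the 5th–95th percentile band of the null composites.
- **Air-quality indicators** for gappy station PM10 records: the episode
  PM10 level, and the expected number of poor-air-quality days per 30-day
  period, `exceedances / available days × 30`, at the 50 and 260 μg m⁻³
  standards.
- **Excess mortality** from dust-source PM2.5 anomalies via the
  log-linear exposure-response model
  `ΔMort = M_b · N_pop · [exp(β·ΔX) − 1]`, with β calibrated so a
  10 μg m⁻³ rise in 2-day averaged PM2.5 raises total mortality by 0.98%,
  applied to the 15 two-day periods of each episode and summed over
  region, periods and cells to one excess-death total per event.
- **A synthetic-data generator** that plants SSWs, box-confined surface
  responses and station gaps with known ground truth, so the entire chain
  is testable end to end without external archives.

Supporting tools include the station-based NAO index (normalized SLP,
Lisbon minus Stykkisholmur), per-cell regression maps with an
effective-sample-size t-test for autocorrelated series
(`N_eff = N(1 − r₁r₂)/(1 + r₁r₂)`), the meteorological wind-direction
convention, and the fixed-bin dust/wind histograms.

## Worked example

Run the whole chain on a 12-winter synthetic world with 200 null sets:

```python
from stratdust import PipelineConfig, run_all

res = run_all(PipelineConfig(seed=42, n_years=12, n_sets=200))
```

which logs each stage and returns (abridged):

```
events: 7
central dates: ['1981-02-10', '1983-02-15', '1984-01-27'] ...
composites: {'em_dust_anom': 38.29, 'wa_dust_anom': -21.43, 'flagged_fraction': 0.19}
finokalia level: 94.9  null 83.7  pct +13.4
mbour     level: 58.0  null 91.5  pct -36.6
mortality em: +50.0 +/- 4.5   deaths/event
mortality wa: -32.3 +/- 3.3   deaths/event
```

Reading: all 7 planted SSWs were recovered exactly from the synthetic
stratospheric wind. The dust composite shows the planted dipole — a
+38 μg m⁻³ anomaly in the Eastern Mediterranean box (30°–33.75°N,
10°–30°E) and −21 μg m⁻³ in the West Africa box (16.25°–23.75°N,
12.5°–23.75°E); the box means sit below the planted ±50/−30 amplitudes
because the climatology is estimated from the same short record. The
Eastern Mediterranean station's PM10 level rises 13% above the non-SSW
mean while the West African station's falls 37%, and the exposure-response
model converts the PM2.5 dipole into ~50 excess deaths per event in the
Eastern Mediterranean box versus ~32 avoided deaths per event in West
Africa (magnitudes are set by the synthetic population and baseline
rates).

The same stages are available from the shell:

```sh
stratdust simulate --seed 42 -o sim/
stratdust detect-ssw --wind sim/wind.csv -o events.json
stratdust composite --field sim/dust.nc --wind sim/wind.csv -o composite.nc
stratdust run-all --seed 42 -o out/
```

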