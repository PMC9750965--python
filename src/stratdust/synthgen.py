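"""Synthetic inputs with known ground truth for the SSW–dust–health pipeline.

Emulates, at desk scale, the statistical structure of the data the pipeline
consumes: a daily stratospheric wind series with planted vortex breakdowns,
daily gridded surface fields (SLP, 10 m winds, dust, dust-source PM2.5,
PM10) built as seasonal cycle + AR(1) noise + an additive post-event
response confined to the two analysis boxes, gappy station PM10 series, and
static population / baseline-mortality rasters.

Everything is driven by one :class:`SynthConfig`; identical configs
(including seed) produce bit-identical output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from . import calendar as cal
from .regions import EASTERN_MEDITERRANEAN, WEST_AFRICA, Box, box_mask

_TWO_PI = 2.0 * math.pi

# Stable per-stream offsets for seeding independent generators from one seed.
_STREAM = {
    "wind": 0,
    "slp": 1,
    "u10": 2,
    "v10": 3,
    "dust": 4,
    "pm25": 5,
    "pm10": 6,
    "station": 7,
    "plan": 8,
}


@dataclass(frozen=True)
class FieldSpec:
    """Statistical recipe for one synthetic daily gridded field.

    mean plus up to three annual Fourier harmonics (amplitude, phase in
    days) form the seasonal cycle; AR(1) noise with lag-1 coefficient
    ``ar1`` and innovation s.d. ``noise_sd`` is added per cell; after each
    planted event, ``em_response`` / ``wa_response`` are added uniformly
    inside the Eastern Mediterranean / West Africa boxes for the response
    window.
    """

    mean: float
    harmonics: tuple[tuple[float, float], ...] = ()
    ar1: float = 0.6
    noise_sd: float = 1.0
    em_response: float = 0.0
    wa_response: float = 0.0
    units: str = ""

    def __post_init__(self):
        if len(self.harmonics) > 3:
            raise ValueError("at most 3 seasonal harmonics are supported")
        vals = [self.mean, self.ar1, self.noise_sd, self.em_response, self.wa_response]
        vals += [v for h in self.harmonics for v in h]
        if not all(np.isfinite(vals)):
            raise ValueError("all field-spec parameters must be finite")
        if abs(self.ar1) >= 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def seasonal(self, doy: np.ndarray) -> np.ndarray:
        out = np.full(doy.shape, self.mean, dtype=float)
        for k, (amp, phase) in enumerate(self.harmonics, start=1):
            out += amp * np.cos(_TWO_PI * k * (doy - phase) / 365.0)
        return out


def _default_fields() -> dict[str, FieldSpec]:
    # Winter-mean magnitudes loosely follow reanalysis / transport-model
    # climatologies of the study region: high dust loads over the Sahara
    # belt, NE trades (negative u and v), subtropical-ridge SLP.  The dust
    # dipole (+50 EM / -30 WA on a ~200 ug/m3 mean) sits in the 20-30% /
    # 10-20% relative-change range the composites should recover.
    return {
        "slp": FieldSpec(101500.0, ((400.0, 10.0),), 0.75, 250.0, -400.0, 0.0, "Pa"),
        "u10": FieldSpec(-2.0, ((1.0, 30.0),), 0.6, 1.5, 2.0, 1.5, "m s-1"),
        "v10": FieldSpec(-1.5, ((1.0, 60.0),), 0.6, 1.5, 2.0, 1.0, "m s-1"),
        "dust": FieldSpec(200.0, ((80.0, -30.0),), 0.7, 25.0, 50.0, -30.0, "ug m-3"),
        "pm25": FieldSpec(40.0, ((15.0, -30.0),), 0.7, 6.0, 15.0, -10.0, "ug m-3"),
        "pm10": FieldSpec(80.0, ((25.0, -30.0),), 0.7, 12.0, 12.0, -25.0, "ug m-3"),
    }


def default_ssw_plan(
    n_years: int, n_events: int | None = None, seed: int = 0
) -> dict[int, int]:
    """Plant one SSW in each of ``n_events`` distinct winters.

    The default event count is 0.6 per winter (24 events in 40 winters, the
    observed NDJFM rate), with central days drawn uniformly from day 40 to
    day 120 of the winter (mid-December to the start of March).
    """
    if n_events is None:
        n_events = int(round(0.6 * n_years))
    if n_events > n_years:
        raise ValueError("cannot plant more than one SSW per winter")
    rng = np.random.default_rng([seed, _STREAM["plan"]])
    winters = np.sort(rng.choice(n_years, size=n_events, replace=False))
    days = rng.integers(40, 121, size=n_events)
    return {int(w): int(d) for w, d in zip(winters, days)}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic world.

    ``ssw_events`` maps winter index (0-based) to the planted central day
    within the winter (0 = Nov 1, on the 151-day NDJFM grid); ``None``
    requests the default plan (24 events in 40 winters).
    """

    n_years: int = 40
    start_year: int = 1980
    ssw_events: Mapping[int, int] | None = None
    easterly_run: int = 10
    response_window: tuple[int, int] = (1, 30)
    fields: Mapping[str, FieldSpec] = field(default_factory=_default_fields)
    lat: tuple[float, float, float] = (10.0, 40.0, 1.25)
    lon: tuple[float, float, float] = (-20.0, 35.0, 1.25)
    missing_rate: float = 0.15
    wind_mean: float = 35.0
    wind_seasonal_amp: float = 8.0
    wind_ar1: float = 0.85
    wind_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if abs(self.wind_ar1) >= 1:
            raise ValueError("wind AR(1) coefficient must satisfy |phi| < 1")
        if self.ssw_events is None:
            object.__setattr__(
                self, "ssw_events", default_ssw_plan(self.n_years, seed=self.seed)
            )
        for w, d in self.ssw_events.items():
            if not 0 <= w < self.n_years:
                raise ValueError(f"planted winter index {w} outside 0..{self.n_years - 1}")
            if not 1 <= d < cal.DAYS_PER_WINTER:
                raise ValueError(
                    f"planted central day {d} outside the NDJFM winter (1..150)"
                )
            if d + self.easterly_run + 10 > cal.DAYS_PER_WINTER:
                raise ValueError(
                    f"planted event at winter day {d} leaves no room for vortex "
                    "recovery before the end of March (would be a final warming)"
                )

    # -- derived geometry ---------------------------------------------------

    def time_index(self) -> pd.DatetimeIndex:
        return cal.winter_calendar(self.start_year, self.n_years)

    def lat_values(self) -> np.ndarray:
        lo, hi, step = self.lat
        return np.arange(lo, hi + step / 2, step)

    def lon_values(self) -> np.ndarray:
        lo, hi, step = self.lon
        return np.arange(lo, hi + step / 2, step)

    def planted_dates(self) -> list[pd.Timestamp]:
        times = self.time_index()
        return [
            pd.Timestamp(times[w * cal.DAYS_PER_WINTER + d])
            for w, d in sorted(self.ssw_events.items())
        ]


@dataclass(frozen=True)
class GroundTruth:
    """What was actually planted, for oracle comparisons downstream."""

    central_dates: tuple[pd.Timestamp, ...]
    box_response: Mapping[str, tuple[float, float]]  # field -> (EM, WA) offsets
    response_window: tuple[int, int]


def _ground_truth(cfg: SynthConfig) -> GroundTruth:
    return GroundTruth(
        central_dates=tuple(cfg.planted_dates()),
        box_response={
            name: (spec.em_response, spec.wa_response)
            for name, spec in cfg.fields.items()
        },
        response_window=cfg.response_window,
    )


def _ar1(rng: np.random.Generator, phi: float, sd: float, shape: tuple[int, ...]) -> np.ndarray:
    """AR(1) noise along axis 0, started from the stationary distribution."""
    if sd == 0:
        return np.zeros(shape)
    eps = rng.standard_normal(shape) * sd
    out = np.empty(shape)
    out[0] = eps[0] / math.sqrt(1.0 - phi * phi)
    for t in range(1, shape[0]):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def make_strat_wind(cfg: SynthConfig) -> tuple[pd.Series, GroundTruth]:
    """Daily zonal-mean zonal wind at 60N / 10 hPa with planted reversals.

    Winters without a planted event stay strictly westerly (>= 1 m/s).
    Winters with an event cross to easterly exactly on the planted day,
    stay easterly for ``easterly_run`` days, then recover to westerly for
    the rest of the winter.
    """
    times = cfg.time_index()
    doy = cal.noleap_doy(times)
    rng = np.random.default_rng([cfg.seed, _STREAM["wind"]])
    u = cfg.wind_mean + cfg.wind_seasonal_amp * np.cos(_TWO_PI * (doy - 15) / 365.0)
    u = u + _ar1(rng, cfg.wind_ar1, cfg.wind_noise_sd, (len(times),))
    u = np.maximum(u, 1.0)  # guarantee strictly westerly background
    for w, d in sorted(cfg.ssw_events.items()):
        s = w * cal.DAYS_PER_WINTER + d
        run = cfg.easterly_run
        t = np.arange(run)
        u[s : s + run] = -(2.0 + 8.0 * np.sin(math.pi * (t + 0.5) / run))
    series = pd.Series(u, index=times, name="u60_10hPa")
    return series, _ground_truth(cfg)


def _response_time_mask(cfg: SynthConfig, events: list[pd.Timestamp], times: pd.DatetimeIndex) -> np.ndarray:
    w0, w1 = cfg.response_window
    mask = np.zeros(len(times), dtype=bool)
    for ev in events:
        days = cal.next_days(ev, w1)[w0 - 1 :]
        idx = times.get_indexer(days)
        mask[idx[idx >= 0]] = True
    return mask


def make_surface_fields(
    cfg: SynthConfig, events: list[pd.Timestamp] | None = None
) -> dict[str, xr.DataArray]:
    """Daily (time, lat, lon) fields: seasonal cycle + AR(1) noise + response.

    The post-event response is additive and spatially uniform inside each
    analysis box (positive dust/PM in the Eastern Mediterranean, negative in
    West Africa, cyclonic SLP over the EM region), applied on the configured
    day range after each planted central date.
    """
    if events is None:
        events = cfg.planted_dates()
    times = cfg.time_index()
    lats = cfg.lat_values()
    lons = cfg.lon_values()
    coords = {"time": times, "lat": lats, "lon": lons}
    template = xr.DataArray(
        np.empty((len(lats), len(lons))), coords={"lat": lats, "lon": lons}
    )
    em = box_mask(template, EASTERN_MEDITERRANEAN).to_numpy()
    wa = box_mask(template, WEST_AFRICA).to_numpy()
    if not em.any() or not wa.any():
        raise ValueError("grid too small: it must contain both analysis boxes")
    doy = cal.noleap_doy(times)
    resp_t = _response_time_mask(cfg, events, times)

    out: dict[str, xr.DataArray] = {}
    for name in sorted(cfg.fields):
        spec = cfg.fields[name]
        stream = _STREAM.get(name, 100 + zlib.crc32(name.encode()) % 1000)
        rng = np.random.default_rng([cfg.seed, stream])
        vals = spec.seasonal(doy)[:, None, None] + _ar1(
            rng, spec.ar1, spec.noise_sd, (len(times), len(lats), len(lons))
        )
        offset = spec.em_response * em + spec.wa_response * wa
        vals = vals + resp_t[:, None, None] * offset[None, :, :]
        out[name] = xr.DataArray(
            vals, coords=coords, dims=("time", "lat", "lon"), name=name,
            attrs={"units": spec.units},
        )
    return out


def make_station_series(
    cfg: SynthConfig,
    grid: xr.DataArray,
    station_lat: float,
    station_lon: float,
    seed_salt: int = 0,
) -> pd.Series:
    """Nearest-cell daily series with Bernoulli gaps, floored at zero.

    Missing days are NaN; independent per day with probability
    ``cfg.missing_rate``.
    """
    lat = float(grid["lat"].min()), float(grid["lat"].max())
    lon = float(grid["lon"].min()), float(grid["lon"].max())
    if not (lat[0] <= station_lat <= lat[1] and lon[0] <= station_lon <= lon[1]):
        raise ValueError("station location outside the grid domain")
    cell = grid.sel(lat=station_lat, lon=station_lon, method="nearest")
    values = np.maximum(cell.to_numpy().astype(float), 0.0)
    rng = np.random.default_rng([cfg.seed, _STREAM["station"], seed_salt])
    gaps = rng.random(values.shape) < cfg.missing_rate
    values[gaps] = np.nan
    return pd.Series(values, index=pd.DatetimeIndex(grid["time"].values), name="pm10")


def make_population_mortality(
    cfg: SynthConfig, pop_per_cell: float = 1.0e5, annual_rate: float = 0.008
) -> tuple[xr.DataArray, xr.DataArray]:
    """Static population-count and annual baseline-mortality-rate rasters."""
    if pop_per_cell < 0:
        raise ValueError("population must be >= 0")
    if not 0 <= annual_rate <= 1:
        raise ValueError("annual mortality rate must lie in [0, 1]")
    lats = cfg.lat_values()
    lons = cfg.lon_values()
    coords = {"lat": lats, "lon": lons}
    pop = xr.DataArray(
        np.full((len(lats), len(lons)), float(pop_per_cell)),
        coords=coords, dims=("lat", "lon"), name="population",
        attrs={"units": "persons"},
    )
    mb = xr.DataArray(
        np.full((len(lats), len(lons)), float(annual_rate)),
        coords=coords, dims=("lat", "lon"), name="baseline_mortality",
        attrs={"units": "deaths person-1 year-1"},
    )
    return pop, mb


def null_config(cfg: SynthConfig) -> SynthConfig:
    """Same world with every planted response amplitude set to zero."""
    fields = {
        name: replace(spec, em_response=0.0, wa_response=0.0)
        for name, spec in cfg.fields.items()
    }
    return replace(cfg, fields=fields)


def noise_free_config(cfg: SynthConfig) -> SynthConfig:
    """Same world with all AR(1) innovation s.d. set to zero (pure signal)."""
    fields = {name: replace(spec, noise_sd=0.0) for name, spec in cfg.fields.items()}
    return replace(cfg, fields=fields, wind_noise_sd=0.0)
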