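"""Excess mortality from dust-source PM2.5 anomalies following SSWs.

Short-term mortality impacts use the log-linear exposure-response model

    dMort = Mb * Npop * [exp(beta * dX) - 1]

per grid cell and 2-day period, where Mb is the baseline mortality rate on
a 2-day basis, Npop the exposed population, dX the 2-day averaged PM2.5
anomaly, and beta the concentration-response factor calibrated so that a
10 ug/m3 increase in 2-day averaged PM2.5 raises total mortality by 0.98%.
The 30 post-onset days of each event give 15 two-day periods (days [1,2],
[3,4], ..., [29,30]); summing cells in a region and periods gives one
excess-death total per event, summarized by the mean and the sample
standard deviation across events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import calendar as cal
from .regions import Box, box_mask
from .ssw import SSWEvent

#: Days in the post-onset window and the implied number of 2-day periods.
WINDOW_DAYS = 30
N_PERIODS = 15


@dataclass(frozen=True)
class ExposureResponse:
    """Calibrated concentration-response factor for short-term PM2.5."""

    beta: float            # per ug/m3 of 2-day averaged PM2.5
    source_pct_per_10: float  # the calibration statement, % per 10 ug/m3

    def relative_risk_pct(self, dx: float) -> float:
        """Percent change in mortality for a 2-day anomaly of ``dx`` ug/m3."""
        return 100.0 * (math.exp(self.beta * dx) - 1.0)


def calibrate_beta(pct_per_10: float = 0.98, window_ug: float = 10.0) -> ExposureResponse:
    """Invert the stated percent-per-10-ug/m3 relationship for beta.

    beta = ln(1 + pct/100) / window_ug, so that exp(window_ug * beta) - 1
    reproduces the stated relative risk exactly.
    """
    if pct_per_10 <= -100.0:
        raise ValueError("percent change must exceed -100")
    if window_ug <= 0:
        raise ValueError("window_ug must be positive")
    beta = math.log1p(pct_per_10 / 100.0) / window_ug
    return ExposureResponse(beta=beta, source_pct_per_10=pct_per_10)


def two_day_anomalies(pm25_anom: xr.DataArray, central_date) -> xr.DataArray:
    """The 15 two-day averaged PM2.5 anomalies after one event.

    Period k (1..15) averages post-onset days 2k-1 and 2k; a missing day
    within a pair leaves the pair's mean to the available day, and a fully
    missing pair is NaN.  Days absent from the record (e.g. April days in
    an NDJFM-only field) count as missing.
    """
    times = pd.DatetimeIndex(pm25_anom["time"].values)
    days = cal.next_days(central_date, WINDOW_DAYS)
    idx = times.get_indexer(days)
    spatial = tuple(d for d in pm25_anom.dims if d != "time")
    vals = pm25_anom.transpose("time", *spatial).to_numpy().astype(float)
    shape = vals.shape[1:]
    day_vals = np.full((WINDOW_DAYS, *shape), np.nan)
    ok = idx >= 0
    day_vals[ok] = vals[idx[ok]]
    pairs = day_vals.reshape(N_PERIODS, 2, *shape)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dx = np.nanmean(pairs, axis=1)
    coords = {d: pm25_anom.coords[d] for d in spatial if d in pm25_anom.coords}
    return xr.DataArray(dx, coords={"period": np.arange(1, N_PERIODS + 1), **coords},
                        dims=("period", *spatial))


def mortality_change(
    mb_2day: xr.DataArray | float,
    npop: xr.DataArray | float,
    er: ExposureResponse,
    dx: xr.DataArray | np.ndarray | float,
):
    """dMort = Mb * Npop * [exp(beta * dX) - 1], per cell and 2-day period.

    ``mb_2day`` is the baseline mortality per person per 2-day period.
    Negative anomalies give negative changes (avoided deaths).
    """
    if isinstance(mb_2day, (int, float)) and mb_2day < 0:
        raise ValueError("baseline mortality must be >= 0")
    if isinstance(npop, (int, float)) and npop < 0:
        raise ValueError("population must be >= 0")
    return mb_2day * npop * (np.exp(er.beta * dx) - 1.0)


def annual_to_2day(mb_annual):
    """Convert an annual per-person mortality rate to a 2-day basis."""
    return mb_annual * (2.0 / 365.0)


@dataclass
class MortalityResult:
    """Per-event regional excess deaths with their across-event summary."""

    per_event: np.ndarray
    region: Box
    beta: float

    @property
    def mean(self) -> float:
        return float(self.per_event.mean())

    @property
    def std(self) -> float:
        """Sample standard deviation across events (N-1 denominator)."""
        if len(self.per_event) < 2:
            return float("nan")
        return float(self.per_event.std(ddof=1))


def event_totals(
    mort_maps: Sequence[xr.DataArray],
    region: Box,
    events: Sequence[SSWEvent] | None = None,
) -> MortalityResult:
    """Sum per-event mortality maps over a region's cells and all periods.

    ``mort_maps[i]`` is event i's (period, lat, lon) mortality-change
    field.  NaN periods (fully missing data) contribute zero.
    """
    if events is not None and len(events) != len(mort_maps):
        raise ValueError("one mortality map per event required")
    totals = []
    for m in mort_maps:
        mask = box_mask(m, region)
        if int(mask.sum()) == 0:
            raise ValueError(f"region {region} contains no grid cells")
        totals.append(float(m.where(mask).sum(skipna=True)))
    return MortalityResult(per_event=np.asarray(totals), region=region, beta=float("nan"))


def excess_mortality(
    pm25_anom: xr.DataArray,
    events: Sequence[SSWEvent],
    population: xr.DataArray,
    mb_annual: xr.DataArray,
    region: Box,
    er: ExposureResponse | None = None,
) -> MortalityResult:
    """End-to-end regional excess deaths per SSW event.

    For each event: 15 two-day PM2.5 anomaly maps -> per-cell, per-period
    mortality changes -> sum over the region's cells and periods.  Returns
    the per-event totals with mean and across-event standard deviation.
    """
    if er is None:
        er = calibrate_beta()
    mb2 = annual_to_2day(mb_annual)
    maps = []
    for ev in events:
        dx = two_day_anomalies(pm25_anom, ev.central_date)
        maps.append(mortality_change(mb2, population, er, dx))
    result = event_totals(maps, region, events)
    result.beta = er.beta
    return result
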