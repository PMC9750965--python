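"""Episode windows, the resampled non-SSW null, and seasonal-cycle removal.

An *SSW episode* is the 30-day period after an event's onset: days +1..+30
relative to the central date (day 0, the central date itself, excluded).
The null distribution is built from replicate *non-SSW episode sets*: each
replicate keeps the observed events' calendar dates (month and day) but
relocates every event, independently and with replacement, into a randomly
chosen extended winter that contains no SSW.

Daily anomalies are formed by subtracting a smooth seasonal cycle — the
mean plus the first three Fourier harmonics of the raw daily climatology —
from each calendar day, which removes the annual march while keeping
day-to-day and interannual variability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import calendar as cal
from .ssw import SSWEvent

logger = logging.getLogger(__name__)

#: Default post-onset window (first day, last day) relative to the onset.
DEFAULT_WINDOW = (1, 30)


@dataclass(frozen=True)
class EpisodeSet:
    """A labelled collection of post-onset windows, one per event.

    ``windows[i]`` holds the explicit calendar days of event ``i``'s
    window (Feb 29 never appears; windows may run past Mar 31 into April).
    """

    label: str  # "ssw" | "non-ssw"
    replicate_id: int
    central_dates: tuple[pd.Timestamp, ...]
    windows: tuple[pd.DatetimeIndex, ...]

    def __post_init__(self):
        if len(self.windows) != len(self.central_dates):
            raise ValueError("one window per event required")

    @property
    def n_events(self) -> int:
        return len(self.windows)

    def all_days(self) -> pd.DatetimeIndex:
        """All window days pooled, duplicates kept if windows overlap."""
        if len(self.windows) == 1:
            return self.windows[0]
        return self.windows[0].append(list(self.windows[1:]))


def build_window(central_date, window: tuple[int, int] = DEFAULT_WINDOW) -> pd.DatetimeIndex:
    lo, hi = window
    if not 1 <= lo <= hi:
        raise ValueError("window must satisfy 1 <= first <= last")
    return cal.next_days(central_date, hi)[lo - 1 :]


def build_ssw_episodes(
    events: Sequence[SSWEvent], window: tuple[int, int] = DEFAULT_WINDOW
) -> EpisodeSet:
    """The observed SSW episode set: days +1..+30 after each central date."""
    if len(events) == 0:
        raise ValueError("no events to build episodes from")
    centrals = tuple(e.central_date for e in events)
    return EpisodeSet(
        label="ssw",
        replicate_id=0,
        central_dates=centrals,
        windows=tuple(build_window(c, window) for c in centrals),
    )


def sample_non_ssw_episodes(
    events: Sequence[SSWEvent],
    no_ssw_winters: Iterable[int],
    n_sets: int = 1000,
    seed: int = 0,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[EpisodeSet]:
    """Replicate non-SSW episode sets matched to the observed calendar.

    Each of the ``n_sets`` replicates re-dates every observed event to the
    same month-day in a winter drawn uniformly, with replacement and
    independently per event, from ``no_ssw_winters`` (winter starting
    years).  One generator seeded with ``seed`` is consumed replicate-major
    (all events of replicate 0, then replicate 1, ...).
    """
    pool = np.array(sorted({int(w) for w in no_ssw_winters}))
    if pool.size == 0:
        raise ValueError("no null pool: every winter contains an SSW")
    if len(events) == 0:
        raise ValueError("no events to match")
    rng = np.random.default_rng(seed)
    month_day = [(c.central_date.month, c.central_date.day) for c in events]
    out = []
    for rep in range(n_sets):
        winters = rng.choice(pool, size=len(events), replace=True)
        centrals = []
        for (m, d), wy in zip(month_day, winters):
            year = int(wy) if m >= 11 else int(wy) + 1
            centrals.append(pd.Timestamp(year=year, month=m, day=d))
        centrals = tuple(centrals)
        out.append(
            EpisodeSet(
                label="non-ssw",
                replicate_id=rep + 1,
                central_dates=centrals,
                windows=tuple(build_window(c, window) for c in centrals),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Seasonal cycle
# ---------------------------------------------------------------------------


def _design(doy: np.ndarray, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(doy, dtype=float)]
    for k in range(1, n_harmonics + 1):
        ang = 2.0 * np.pi * k * doy / 365.0
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class SeasonalCycle:
    """Per-cell smooth climatology: mean + first ``n_harmonics`` harmonics.

    ``coef`` has a leading ``coef`` dimension of length 1 + 2*n_harmonics
    (mean, then cos/sin pairs for harmonics 1, 2, 3) over the input's
    spatial dimensions.  The cycle is 365-periodic by construction.
    """

    coef: xr.DataArray
    n_harmonics: int = 3

    def evaluate(self, dates) -> xr.DataArray:
        """Climatological value at each date (Feb 29 uses Feb 28)."""
        dates = pd.DatetimeIndex(dates)
        X = _design(cal.noleap_doy(dates).astype(float), self.n_harmonics)
        spatial = [d for d in self.coef.dims if d != "coef"]
        c = self.coef.transpose("coef", *spatial).to_numpy()
        vals = np.tensordot(X, c, axes=(1, 0))
        coords = {"time": dates}
        coords.update({d: self.coef.coords[d] for d in spatial if d in self.coef.coords})
        return xr.DataArray(vals, coords=coords, dims=("time", *spatial))


def fit_seasonal_cycle(grid: xr.DataArray, n_harmonics: int = 3) -> SeasonalCycle:
    """Fit the smooth seasonal cycle of a daily field, cell by cell.

    The raw daily climatology (mean over years for each 365-day calendar
    day present in the record) is projected by least squares onto the mean
    and the first ``n_harmonics`` annual Fourier harmonics; higher
    harmonics are discarded.  Works for any calendar coverage (full year or
    NDJFM-only); note the harmonics are mutually orthogonal only under
    full-year sampling.

    Cells whose climatology is undefined (all-missing) get NaN
    coefficients, so their anomalies stay masked.
    """
    dates = pd.DatetimeIndex(grid["time"].values)
    doy = cal.noleap_doy(dates)
    uniq = np.unique(doy)
    counts = np.array([(doy == u).sum() for u in uniq])
    if (counts < 2).any():
        warnings.warn(
            "fewer than 2 years of data for some calendar days; "
            "the daily climatology is noisy there",
            stacklevel=2,
        )
    spatial_dims = tuple(d for d in grid.dims if d != "time")
    vals = grid.transpose("time", *spatial_dims).to_numpy().astype(float)
    ncell = int(np.prod(vals.shape[1:], dtype=int)) if spatial_dims else 1
    flat = vals.reshape(len(dates), ncell)

    # Raw climatology: mean over years per calendar day, ignoring gaps.
    clim = np.empty((uniq.size, ncell))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for i, u in enumerate(uniq):
            clim[i] = np.nanmean(flat[doy == u], axis=0)

    X = _design(uniq.astype(float), n_harmonics)
    ncoef = X.shape[1]
    coef = np.full((ncoef, ncell), np.nan)
    good = ~np.isnan(clim).any(axis=0)
    if good.any():
        coef[:, good] = np.linalg.lstsq(X, clim[:, good], rcond=None)[0]
    # Cells with gaps on some calendar days: refit on their valid days.
    partial = ~good & ~np.isnan(clim).all(axis=0)
    for j in np.flatnonzero(partial):
        ok = ~np.isnan(clim[:, j])
        if ok.sum() >= ncoef:
            coef[:, j] = np.linalg.lstsq(X[ok], clim[ok, j], rcond=None)[0]

    shape = tuple(vals.shape[1:]) if spatial_dims else ()
    da = xr.DataArray(
        coef.reshape((ncoef, *shape)),
        dims=("coef", *spatial_dims),
        coords={d: grid.coords[d] for d in spatial_dims if d in grid.coords},
    )
    return SeasonalCycle(coef=da, n_harmonics=n_harmonics)


def anomalize(grid: xr.DataArray, cycle: SeasonalCycle) -> xr.DataArray:
    """Daily anomalies: field minus the seasonal cycle on that calendar day."""
    spatial = tuple(d for d in cycle.coef.dims if d != "coef")
    for d in spatial:
        if d not in grid.dims:
            raise ValueError(f"grid lacks dimension {d!r} required by the cycle")
        if d in grid.coords and d in cycle.coef.coords and not np.array_equal(
            grid.coords[d].values, cycle.coef.coords[d].values
        ):
            raise ValueError(f"coordinate mismatch on {d!r} between grid and cycle")
    clim = cycle.evaluate(grid["time"].values)
    anom = grid - clim.transpose(*grid.dims)
    anom.attrs = dict(grid.attrs)
    anom.name = (grid.name or "field") + "_anom"
    return anom
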