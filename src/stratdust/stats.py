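"""Composites, Monte Carlo significance, NAO index, regressions, histograms.

The central statistic is the episode composite: the unweighted mean of a
daily field over all days of all post-onset windows, pooled across events.
Its significance is assessed with a two-tailed Monte Carlo test at
p < 0.10: the observed composite is compared against the 5th–95th
percentile band of composites over replicate null episode sets, built
either from random central dates (anomaly fields) or from the matched
non-SSW resampling (full fields, where the seasonal cycle must be
controlled for).

Also here: the station-based NAO index, per-cell regression maps with an
effective-sample-size t-test for autocorrelated series, the meteorological
wind-direction convention, and fixed-bin (bivariate) histograms of dust,
wind direction and wind speed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import xarray as xr

from . import calendar as cal
from .episodes import DEFAULT_WINDOW, EpisodeSet, build_window

logger = logging.getLogger(__name__)

MIN_REPLICATES = 20

#: Reference station coordinates for the station-based NAO index.
LISBON = (38.72, -9.14)
STYKKISHOLMUR = (65.08, -22.73)


# ---------------------------------------------------------------------------
# Composites and Monte Carlo significance
# ---------------------------------------------------------------------------


def _flatten(field: xr.DataArray) -> tuple[np.ndarray, pd.DatetimeIndex, tuple]:
    spatial = tuple(d for d in field.dims if d != "time")
    vals = field.transpose("time", *spatial).to_numpy().astype(float)
    times = pd.DatetimeIndex(field["time"].values)
    shape = vals.shape[1:]
    return vals.reshape(len(times), -1), times, shape


def _window_rows(times: pd.DatetimeIndex, ep: EpisodeSet) -> np.ndarray:
    """Row indices of all pooled window days present in the record."""
    idx = times.get_indexer(ep.all_days())
    return idx[idx >= 0]


def _pooled_mean(flat: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(flat[rows], axis=0)
    count = np.sum(~np.isnan(flat[rows]), axis=0)
    return mean, count


def composite(field: xr.DataArray, ep: EpisodeSet) -> xr.Dataset:
    """Episode composite: per-cell mean over all pooled window days.

    Masked days are skipped per cell; the number of days actually averaged
    is returned alongside.  Window days outside the field's time axis
    (e.g. April days of a late event in an NDJFM-only record) are dropped.
    """
    flat, times, shape = _flatten(field)
    rows = _window_rows(times, ep)
    if rows.size == 0:
        raise ValueError("episode windows do not overlap the field's time axis")
    mean, count = _pooled_mean(flat, rows)
    spatial = tuple(d for d in field.dims if d != "time")
    coords = {d: field.coords[d] for d in spatial if d in field.coords}
    return xr.Dataset(
        {
            "mean": xr.DataArray(mean.reshape(shape), coords=coords, dims=spatial),
            "n_days": xr.DataArray(count.reshape(shape), coords=coords, dims=spatial),
        }
    )


@dataclass
class CompositeResult:
    """Observed composite with its Monte Carlo null band and significance."""

    mean: xr.DataArray
    p5: xr.DataArray
    p95: xr.DataArray
    sig: xr.DataArray          # True iff mean strictly outside [p5, p95]
    n_days: xr.DataArray
    null_composites: np.ndarray = field(repr=False)  # (n_sets, *spatial)
    p_level: float = 0.10

    @property
    def flagged_fraction(self) -> float:
        m = self.sig.to_numpy()
        valid = ~np.isnan(self.mean.to_numpy())
        return float(m[valid].mean())


def monte_carlo_test(
    field: xr.DataArray,
    ssw_ep: EpisodeSet,
    null_eps: Sequence[EpisodeSet] | None = None,
    p: float = 0.10,
    mode: str = "anomaly",
    n_sets: int = 1000,
    seed: int = 0,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> CompositeResult:
    """Two-tailed Monte Carlo test of an episode composite.

    ``mode="anomaly"`` (seasonal cycle already removed): the null is built
    by drawing, for each of ``n_sets`` replicates, N random central dates
    (with replacement) from the pool of NDJFM days whose post-onset window
    is fully covered by the record, and compositing those windows, N being
    the observed event count.  (For a year-round record the pool is simply
    every NDJFM day; for an NDJFM-only record the coverage condition drops
    late-March dates whose windows would be truncated, keeping the null
    composites exchangeable with the observed one.)

    ``mode="full"`` (raw fields): the provided matched non-SSW episode
    sets are composited instead, so the null carries the same seasonal
    sampling as the observed episodes.

    A cell is significant when the observed composite lies strictly
    outside the null's [p/2, 1-p/2] percentile band (linear-interpolated
    percentiles); boundary ties are not significant.
    """
    flat, times, shape = _flatten(field)
    rows_obs = _window_rows(times, ssw_ep)
    if rows_obs.size == 0:
        raise ValueError("episode windows do not overlap the field's time axis")
    mean_obs, count_obs = _pooled_mean(flat, rows_obs)

    if mode == "anomaly":
        rng = np.random.default_rng(seed)
        ndjfm = times[cal.in_ndjfm(times)]
        covered = np.array(
            [(times.get_indexer(build_window(c, window)) >= 0).all() for c in ndjfm]
        )
        pool = ndjfm[covered]
        if len(pool) == 0:
            raise ValueError("no candidate central dates with full window coverage")
        replicate_rows = []
        for _ in range(n_sets):
            centrals = pool[rng.integers(0, len(pool), size=ssw_ep.n_events)]
            days = [build_window(c, window) for c in centrals]
            idx = times.get_indexer(days[0].append(days[1:]) if len(days) > 1 else days[0])
            replicate_rows.append(idx[idx >= 0])
    elif mode == "full":
        if null_eps is None:
            raise ValueError("full mode requires the matched non-SSW episode sets")
        replicate_rows = [_window_rows(times, ep) for ep in null_eps]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if len(replicate_rows) < MIN_REPLICATES:
        raise ValueError(
            f"need at least {MIN_REPLICATES} null replicates for meaningful "
            f"percentiles, got {len(replicate_rows)}"
        )

    null = np.empty((len(replicate_rows), flat.shape[1]))
    for i, rows in enumerate(replicate_rows):
        null[i] = _pooled_mean(flat, rows)[0] if rows.size else np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo, hi = np.nanpercentile(
            null, [100 * p / 2, 100 * (1 - p / 2)], axis=0, method="linear"
        )
    sig = (mean_obs < lo) | (mean_obs > hi)

    spatial = tuple(d for d in field.dims if d != "time")
    coords = {d: field.coords[d] for d in spatial if d in field.coords}

    def wrap(a, dtype=None):
        return xr.DataArray(a.reshape(shape).astype(dtype) if dtype else a.reshape(shape),
                            coords=coords, dims=spatial)

    return CompositeResult(
        mean=wrap(mean_obs),
        p5=wrap(lo),
        p95=wrap(hi),
        sig=wrap(sig, bool),
        n_days=wrap(count_obs),
        null_composites=null.reshape((len(replicate_rows), *shape)),
        p_level=p,
    )


# ---------------------------------------------------------------------------
# NAO index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NAOIndex:
    """Station-based NAO: normalized SLP at Lisbon minus Stykkisholmur."""

    series: pd.Series
    std_lisbon: float
    std_stykkisholmur: float


def nao_index(
    slp_anom: xr.DataArray,
    pt_lisbon: tuple[float, float] = LISBON,
    pt_stykkisholmur: tuple[float, float] = STYKKISHOLMUR,
    clim_dates: pd.DatetimeIndex | None = None,
) -> NAOIndex:
    """Daily station-based NAO index from an SLP anomaly field.

    At each reference point the nearest-cell SLP anomaly is normalized by
    its NDJFM standard deviation over ``clim_dates`` (default: the full
    record); the index is the Lisbon value minus the Stykkisholmur value.
    A negative index marks the low-pressure-south pattern that follows
    SSWs.
    """
    def point_series(pt):
        lat, lon = pt
        if not (
            float(slp_anom["lat"].min()) <= lat <= float(slp_anom["lat"].max())
            and float(slp_anom["lon"].min()) <= lon <= float(slp_anom["lon"].max())
        ):
            raise ValueError(f"point {pt} outside the SLP grid")
        cell = slp_anom.sel(lat=lat, lon=lon, method="nearest")
        return pd.Series(cell.to_numpy().astype(float),
                         index=pd.DatetimeIndex(slp_anom["time"].values))

    lis = point_series(pt_lisbon)
    sty = point_series(pt_stykkisholmur)
    ref = lis.index if clim_dates is None else pd.DatetimeIndex(clim_dates)
    ref = ref[cal.in_ndjfm(ref)]
    s_lis = float(lis.reindex(ref).std(ddof=1))
    s_sty = float(sty.reindex(ref).std(ddof=1))
    if not (s_lis > 0 and s_sty > 0):
        raise ValueError("zero SLP variance at a reference point")
    return NAOIndex(series=lis / s_lis - sty / s_sty,
                    std_lisbon=s_lis, std_stykkisholmur=s_sty)


# ---------------------------------------------------------------------------
# Effective sample size and regression maps
# ---------------------------------------------------------------------------


def lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0:
        raise ValueError("zero-variance series: lag-1 autocorrelation undefined")
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def effective_n(
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    r1: float | None = None,
    r2: float | None = None,
    n: int | None = None,
) -> float:
    """Effective sample size of two autocorrelated series.

    N_eff = N * (1 - r1*r2) / (1 + r1*r2), with r1, r2 the lag-1
    autocorrelations of the two series — the standard correction that
    deflates the degrees of freedom of a regression between red-noise
    series.  Autocorrelations are estimated from ``x`` and ``y`` unless
    supplied directly.  The result is floored at 2.
    """
    if r1 is None:
        if x is None:
            raise ValueError("supply x or r1")
        r1 = lag1_autocorr(x)
    if r2 is None:
        if y is None:
            raise ValueError("supply y or r2")
        r2 = lag1_autocorr(y)
    if n is None:
        if x is not None:
            n = len(x)
        elif y is not None:
            n = len(y)
        else:
            raise ValueError("supply n when both series are omitted")
    if x is not None and y is not None and len(x) != len(y):
        raise ValueError("series must have equal length")
    if n < 3:
        raise ValueError("need N >= 3")
    neff = n * (1.0 - r1 * r2) / (1.0 + r1 * r2)
    return float(max(neff, 2.0))


@dataclass
class RegressionMap:
    """Per-cell OLS of a field on an index, with autocorrelation-aware test."""

    slope: xr.DataArray        # field units per index unit
    scaled: xr.DataArray       # slope * display scale
    t: xr.DataArray
    n_eff: xr.DataArray
    pvalue: xr.DataArray
    sig: xr.DataArray          # p < p_level (two-sided)
    p_level: float = 0.10


def regress_map(
    field: xr.DataArray,
    index: pd.Series,
    scale: float = 1.0,
    p_level: float = 0.10,
) -> RegressionMap:
    """Least-squares slope of a daily field on a daily index, per cell.

    The t-test for each cell uses the effective sample size computed from
    the lag-1 autocorrelations of the index and of that cell's series
    (t with N_eff - 2 degrees of freedom, two-sided).  ``scale`` only
    multiplies the display map; slopes are returned unscaled.
    """
    flat, times, shape = _flatten(field)
    idx = index.reindex(times)
    x = idx.to_numpy().astype(float)
    ok = ~np.isnan(x)
    x = x[ok]
    flat = flat[ok]
    if np.std(x) == 0:
        raise ValueError("constant index: regression undefined")
    n = len(x)
    xm = x - x.mean()
    ym = flat - np.nanmean(flat, axis=0)
    ym = np.where(np.isnan(ym), 0.0, ym)  # missing days contribute nothing
    sxx = float(np.sum(xm**2))
    slope = (xm @ ym) / sxx
    sy = np.sqrt(np.sum(ym**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ ym) / (np.sqrt(sxx) * sy)
    r1 = lag1_autocorr(x)
    ncell = flat.shape[1]
    neff = np.empty(ncell)
    for j in range(ncell):
        col = flat[:, j]
        s = np.nanstd(col)
        if not s > 0:
            neff[j] = np.nan
            continue
        c = col.copy()
        c[np.isnan(c)] = np.nanmean(c)
        neff[j] = effective_n(r1=r1, r2=float(np.corrcoef(c[:-1], c[1:])[0, 1]), n=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((neff - 2.0) / (1.0 - r**2))
        pval = 2.0 * scipy.stats.t.sf(np.abs(t), np.maximum(neff - 2.0, 1e-9))
    sig = pval < p_level

    spatial = tuple(d for d in field.dims if d != "time")
    coords = {d: field.coords[d] for d in spatial if d in field.coords}

    def wrap(a, dtype=None):
        arr = a.reshape(shape)
        return xr.DataArray(arr.astype(dtype) if dtype else arr, coords=coords, dims=spatial)

    return RegressionMap(
        slope=wrap(slope), scaled=wrap(slope * scale), t=wrap(t),
        n_eff=wrap(neff), pvalue=wrap(pval), sig=wrap(sig, bool), p_level=p_level,
    )


# ---------------------------------------------------------------------------
# Wind direction and histograms
# ---------------------------------------------------------------------------


def wind_direction(u, v):
    """Meteorological direction-from in degrees clockwise from north.

    dir = mod(atan2(-u, -v), 360): a northerly (wind from the north) has
    (u, v) = (0, -|v|) and direction 0; an easterly has direction 90.
    Quadrants: NE (0, 90), SE (90, 180), SW (180, 270), NW (270, 360).
    Calm (0, 0) is undefined and returned as NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d = np.degrees(np.arctan2(-u, -v)) % 360.0
    d = np.where((u == 0) & (v == 0), np.nan, d)
    if d.ndim == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class HistAxis:
    lo: float
    hi: float
    nbins: int

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.nbins + 1)

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.nbins


#: Surface dust concentration margin: 500 bins of width 20 ug/m3 in [0, 10000].
DUST_AXIS = HistAxis(0.0, 10000.0, 500)
#: Wind direction margin: 720 bins of width 0.5 deg in [0, 360].
DIRECTION_AXIS = HistAxis(0.0, 360.0, 720)
#: Wind speed margin: 700 bins of width 0.02 m/s in [0, 14].
SPEED_AXIS = HistAxis(0.0, 14.0, 700)


@dataclass
class Histogram:
    """Probability histogram on fixed edges; bins [lo, hi), last bin closed."""

    x_edges: np.ndarray
    prob: np.ndarray              # 1-D (nx,) or 2-D (nx, ny)
    y_edges: np.ndarray | None = None
    n_total: int = 0
    n_dropped: int = 0

    def marginal_x(self) -> np.ndarray:
        return self.prob if self.prob.ndim == 1 else self.prob.sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        if self.prob.ndim != 2:
            raise ValueError("univariate histogram has no y marginal")
        return self.prob.sum(axis=0)


def bivariate_hist(
    x,
    y=None,
    x_axis: HistAxis = DUST_AXIS,
    y_axis: HistAxis | None = None,
) -> Histogram:
    """Fixed-bin probability histogram of one or two pooled samples.

    NaN entries and out-of-range values are dropped (count reported and
    logged); probabilities are normalized over the retained values.
    """
    x = np.asarray(x, dtype=float).ravel()
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y_axis is None:
            raise ValueError("y_axis required for a bivariate histogram")
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
    else:
        x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty input")
    n_total = int(x.size)
    if y is None:
        counts, edges = np.histogram(x, bins=x_axis.edges)
        kept = int(counts.sum())
        prob = counts / kept if kept else counts.astype(float)
        hist = Histogram(x_edges=edges, prob=prob,
                         n_total=n_total, n_dropped=n_total - kept)
    else:
        counts, xe, ye = np.histogram2d(x, y, bins=[x_axis.edges, y_axis.edges])
        kept = int(counts.sum())
        prob = counts / kept if kept else counts
        hist = Histogram(x_edges=xe, prob=prob, y_edges=ye,
                         n_total=n_total, n_dropped=n_total - kept)
    if hist.n_dropped:
        logger.info("histogram dropped %d of %d out-of-range values",
                    hist.n_dropped, n_total)
    return hist


@dataclass
class HistogramMC:
    """Per-bin SSW histogram vs the non-SSW null band.

    ``label`` is +1 where the SSW probability lies above the null's 95th
    percentile (significant increase), -1 below the 5th (decrease), 0
    otherwise.
    """

    edges: np.ndarray
    ssw_prob: np.ndarray
    null_mean: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    label: np.ndarray


def direction_hist_mc(
    values: xr.DataArray,
    ssw_ep: EpisodeSet,
    null_eps: Sequence[EpisodeSet],
    axis: HistAxis = DIRECTION_AXIS,
    p: float = 0.10,
) -> HistogramMC:
    """Monte Carlo comparison of a pooled per-bin histogram across episodes.

    ``values`` is a daily field (e.g. wind direction, already restricted to
    the analysis box); all cells and window days are pooled into one
    histogram per episode set.
    """
    if len(null_eps) < MIN_REPLICATES:
        raise ValueError(f"need at least {MIN_REPLICATES} null replicates")
    flat, times, _ = _flatten(values)

    def ep_hist(ep: EpisodeSet) -> np.ndarray:
        rows = _window_rows(times, ep)
        sample = flat[rows].ravel()
        sample = sample[~np.isnan(sample)]
        if sample.size == 0:
            return np.full(axis.nbins, np.nan)
        return bivariate_hist(sample, x_axis=axis).prob

    ssw_prob = ep_hist(ssw_ep)
    null = np.stack([ep_hist(ep) for ep in null_eps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo, hi = np.nanpercentile(null, [100 * p / 2, 100 * (1 - p / 2)], axis=0)
        null_mean = np.nanmean(null, axis=0)
    label = np.zeros(axis.nbins, dtype=np.int8)
    label[ssw_prob > hi] = 1
    label[ssw_prob < lo] = -1
    return HistogramMC(edges=axis.edges, ssw_prob=ssw_prob,
                       null_mean=null_mean, p5=lo, p95=hi, label=label)
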