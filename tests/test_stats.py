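"""Composites, Monte Carlo significance, NAO, regressions, histograms."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, strategies as st

import stratdust as sd
from stratdust import calendar as cal
from stratdust.ssw import SSWEvent
from stratdust.stats import (
    DIRECTION_AXIS,
    DUST_AXIS,
    HistAxis,
    SPEED_AXIS,
    direction_hist_mc,
)


def ev(date):
    d = pd.Timestamp(date)
    return SSWEvent(d, int(cal.winter_start_year([d])[0]))


def grid_from(values, dates, ncell=1):
    arr = np.broadcast_to(
        np.asarray(values, dtype=float)[:, None], (len(dates), ncell)
    ).copy()
    return xr.DataArray(arr, coords={"time": dates, "cell": np.arange(ncell)},
                        dims=("time", "cell"))


# ---------------------------------------------------------------------------
# Composites
# ---------------------------------------------------------------------------


def test_composite_of_constant_is_constant(world):
    const = xr.ones_like(world.grids["dust"]) * 3.5
    comp = sd.composite(const, world.ssw_ep)
    assert np.allclose(comp["mean"].values, 3.5)
    assert (comp["n_days"].values > 0).all()


def test_composite_two_disjoint_windows_averages_pooled_days():
    dates = cal.winter_calendar(2000, 2)
    vals = np.zeros(len(dates))
    e1, e2 = ev("2000-12-10"), ev("2002-01-10")
    ep = sd.build_ssw_episodes([e1, e2])
    idx = pd.DatetimeIndex(dates)
    vals[idx.get_indexer(ep.windows[0])] = 1.0
    vals[idx.get_indexer(ep.windows[1])] = 3.0
    comp = sd.composite(grid_from(vals, dates), ep)
    assert np.allclose(comp["mean"].values, 2.0)
    assert (comp["n_days"].values == 60).all()


def test_composite_skips_masked_days(world):
    dust = world.grids["dust"].copy(deep=True)
    day = world.ssw_ep.windows[0][0]
    t = pd.DatetimeIndex(dust["time"].values).get_loc(day)
    dust.values[t, 0, 0] = np.nan
    comp = sd.composite(dust, world.ssw_ep)
    full = sd.composite(world.grids["dust"], world.ssw_ep)
    assert comp["n_days"].values[0, 0] == full["n_days"].values[0, 0] - 1
    assert np.isfinite(comp["mean"].values[0, 0])


def test_composite_without_overlap_is_an_error(world):
    ep = sd.build_ssw_episodes([ev("1950-01-10")])
    with pytest.raises(ValueError, match="overlap"):
        sd.composite(world.grids["dust"], ep)


@given(st.floats(-5, 5), st.floats(-5, 5))
def test_composite_linearity(a, b):
    dates = cal.winter_days(2000)
    rng = np.random.default_rng(1)
    base = grid_from(rng.normal(size=len(dates)), dates)
    ep = sd.build_ssw_episodes([ev("2000-12-10")])
    c0 = sd.composite(base, ep)["mean"].values
    c1 = sd.composite(a * base + b, ep)["mean"].values
    assert np.allclose(c1, a * c0 + b, atol=1e-10)


# ---------------------------------------------------------------------------
# Monte Carlo test
# ---------------------------------------------------------------------------


def test_constant_field_nothing_flagged(world):
    const = xr.ones_like(world.grids["dust"])
    res = sd.monte_carlo_test(const, world.ssw_ep, n_sets=50, seed=1)
    assert not res.sig.values.any()  # boundary ties are not significant


def test_too_few_replicates_refused(world, dust_anom):
    with pytest.raises(ValueError, match="replicates"):
        sd.monte_carlo_test(dust_anom, world.ssw_ep, n_sets=5, seed=1)
    with pytest.raises(ValueError, match="replicates"):
        sd.monte_carlo_test(dust_anom, world.ssw_ep, world.null_eps[:5], mode="full")


def test_planted_offset_flagged_in_box(world, dust_anom):
    res = sd.monte_carlo_test(dust_anom, world.ssw_ep, n_sets=200, seed=3)
    em = sd.box_mask(res.sig, sd.EASTERN_MEDITERRANEAN).values
    wa = sd.box_mask(res.sig, sd.WEST_AFRICA).values
    # +50/-30 ug/m3 on ~25 ug/m3 innovation noise: essentially every box
    # cell must be flagged, and the box means must carry the right signs
    assert res.sig.values[em].mean() > 0.9
    assert res.sig.values[wa].mean() > 0.9
    assert float(sd.box_mean(res.mean, sd.EASTERN_MEDITERRANEAN)) > 0
    assert float(sd.box_mean(res.mean, sd.WEST_AFRICA)) < 0


def test_full_mode_uses_matched_non_ssw_sets(world):
    res = sd.monte_carlo_test(
        world.grids["dust"], world.ssw_ep, world.null_eps, mode="full"
    )
    assert res.null_composites.shape[0] == len(world.null_eps)
    em = sd.box_mask(res.sig, sd.EASTERN_MEDITERRANEAN).values
    assert res.sig.values[em].mean() > 0.9
    assert (res.mean < res.p5).values.sum() + (res.mean > res.p95).values.sum() == res.sig.values.sum()


# ---------------------------------------------------------------------------
# NAO index
# ---------------------------------------------------------------------------


def nao_grid(lis_vals, sty_vals, dates):
    lats = np.array([38.0, 66.0])
    lons = np.array([-23.0, -9.0])
    arr = np.zeros((len(dates), 2, 2))
    arr[:, 0, 1] = lis_vals  # Lisbon-nearest cell
    arr[:, 1, 0] = sty_vals  # Stykkisholmur-nearest cell
    return xr.DataArray(arr, coords={"time": dates, "lat": lats, "lon": lons},
                        dims=("time", "lat", "lon"))


def test_identical_normalized_series_gives_zero_index():
    dates = cal.winter_days(2000)
    vals = np.sin(np.arange(len(dates)))
    idx = sd.nao_index(nao_grid(vals, vals, dates))
    assert np.allclose(idx.series.values, 0.0, atol=1e-12)


def test_opposite_one_sigma_anomalies_give_two():
    dates = cal.winter_days(2000)
    rng = np.random.default_rng(0)
    vals = rng.normal(size=len(dates))
    idx = sd.nao_index(nao_grid(vals, -vals, dates))
    expected = 2.0 * vals / vals.std(ddof=1)
    assert np.allclose(idx.series.values, expected)


def test_planted_cyclone_south_gives_negative_index():
    dates = cal.winter_days(2000)
    rng = np.random.default_rng(1)
    lis = rng.normal(size=len(dates))
    sty = rng.normal(size=len(dates))
    planted = slice(40, 70)
    lis[planted] -= 5.0  # cyclonic (low SLP) anomaly south
    sty[planted] += 5.0  # anticyclonic north
    idx = sd.nao_index(nao_grid(lis, sty, dates))
    assert (idx.series.values[planted] < 0).all()


def test_point_outside_grid_rejected():
    dates = cal.winter_days(2000)
    grid = nao_grid(np.ones(len(dates)), np.zeros(len(dates)), dates)
    with pytest.raises(ValueError, match="outside"):
        sd.nao_index(grid, pt_lisbon=(10.0, 100.0))


# ---------------------------------------------------------------------------
# Effective sample size
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r1,r2,expected_ratio",
    [(0.0, 0.0, 1.0), (0.5, 0.5, 0.6), (0.9, -0.9, 1.81 / 0.19)],
)
def test_effective_n_closed_form(r1, r2, expected_ratio):
    assert sd.effective_n(r1=r1, r2=r2, n=100) == pytest.approx(100 * expected_ratio)


def test_effective_n_estimated_from_white_noise():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=5000), rng.normal(size=5000)
    assert sd.effective_n(x, y) == pytest.approx(5000, rel=0.05)


def test_effective_n_floor_and_errors():
    assert sd.effective_n(r1=0.999, r2=0.999, n=10) == 2.0
    with pytest.raises(ValueError, match="zero-variance"):
        sd.effective_n(np.ones(10), np.arange(10.0))
    with pytest.raises(ValueError):
        sd.effective_n(np.arange(5.0), np.arange(4.0))


# ---------------------------------------------------------------------------
# Regression maps
# ---------------------------------------------------------------------------


def test_noise_free_slope_recovered():
    dates = cal.winter_days(2000)
    rng = np.random.default_rng(2)
    index = pd.Series(rng.normal(size=len(dates)), index=dates)
    field = grid_from(2.0 * index.values, dates, ncell=4)
    res = sd.regress_map(field, index)
    assert np.allclose(res.slope.values, 2.0)
    assert res.sig.values.all()


def test_scale_only_affects_display_map():
    dates = cal.winter_days(2000)
    rng = np.random.default_rng(3)
    index = pd.Series(rng.normal(size=len(dates)), index=dates)
    field = grid_from(2.0 * index.values + rng.normal(size=len(dates)), dates)
    res = sd.regress_map(field, index, scale=0.0)
    assert np.allclose(res.scaled.values, 0.0)
    assert not np.allclose(res.slope.values, 0.0)


def test_independent_field_flag_rate_near_p():
    dates = cal.winter_calendar(2000, 4)
    rng = np.random.default_rng(4)
    index = pd.Series(rng.normal(size=len(dates)), index=dates)
    ncell = 600
    field = xr.DataArray(rng.normal(size=(len(dates), ncell)),
                         coords={"time": dates, "cell": np.arange(ncell)},
                         dims=("time", "cell"))
    res = sd.regress_map(field, index, p_level=0.10)
    assert 0.06 < res.sig.values.mean() < 0.14


def test_constant_index_rejected():
    dates = cal.winter_days(2000)
    index = pd.Series(np.ones(len(dates)), index=dates)
    field = grid_from(np.arange(len(dates), dtype=float), dates)
    with pytest.raises(ValueError, match="constant index"):
        sd.regress_map(field, index)


# ---------------------------------------------------------------------------
# Wind direction and histograms
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "u,v,expected",
    [(0, -5, 0.0), (-5, 0, 90.0), (0, 5, 180.0), (5, 0, 270.0), (5, 5, 225.0)],
)
def test_wind_direction_convention(u, v, expected):
    assert sd.wind_direction(u, v) == pytest.approx(expected)


def test_calm_is_nan_and_excluded():
    assert np.isnan(sd.wind_direction(0.0, 0.0))
    h = sd.bivariate_hist([30.0, np.nan], x_axis=DUST_AXIS)
    assert h.prob.sum() == pytest.approx(1.0)


def test_dust_value_30_lands_in_second_bin():
    h = sd.bivariate_hist([30.0], x_axis=DUST_AXIS)
    assert h.prob[1] == 1.0
    assert h.x_edges[1] == 20.0


def test_hand_placed_points_match_brute_force_tally():
    rng = np.random.default_rng(5)
    dust = rng.uniform(0, 10000, 10)
    speed = rng.uniform(0, 14, 10)
    h = sd.bivariate_hist(dust, speed, x_axis=DUST_AXIS, y_axis=SPEED_AXIS)
    brute = np.zeros((DUST_AXIS.nbins, SPEED_AXIS.nbins))
    for d, s in zip(dust, speed):
        i = min(int(d // DUST_AXIS.width), DUST_AXIS.nbins - 1)
        j = min(int(s // SPEED_AXIS.width), SPEED_AXIS.nbins - 1)
        brute[i, j] += 1
    assert np.array_equal(h.prob * 10, brute)


def test_marginals_match_univariate_histograms():
    rng = np.random.default_rng(6)
    dust = rng.uniform(0, 9000, 500)
    dirs = rng.uniform(0, 360, 500)
    h2 = sd.bivariate_hist(dust, dirs, x_axis=DUST_AXIS, y_axis=DIRECTION_AXIS)
    hx = sd.bivariate_hist(dust, x_axis=DUST_AXIS)
    hy = sd.bivariate_hist(dirs, x_axis=DIRECTION_AXIS)
    assert np.allclose(h2.marginal_x(), hx.prob)
    assert np.allclose(h2.marginal_y(), hy.prob)


def test_out_of_range_dropped_with_count():
    h = sd.bivariate_hist([10.0, 20000.0, -5.0], x_axis=DUST_AXIS)
    assert h.n_dropped == 2
    assert h.prob.sum() == pytest.approx(1.0)


def test_empty_input_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        sd.bivariate_hist([np.nan], x_axis=DUST_AXIS)


def test_direction_hist_identical_distributions_not_significant(world):
    dirs = sd.wind_direction(world.grids["u10"].values, world.grids["v10"].values)
    da = xr.DataArray(dirs, coords=world.grids["u10"].coords,
                      dims=world.grids["u10"].dims)
    # the same episode set everywhere: the SSW histogram equals every null
    same = [world.ssw_ep] * 25
    res = direction_hist_mc(da, world.ssw_ep, same)
    assert (res.label == 0).all()


def test_planted_southwesterly_rotation_labelled_increase(world):
    u10 = world.grids["u10"].copy(deep=True)
    v10 = world.grids["v10"].copy(deep=True)
    rows = pd.DatetimeIndex(u10["time"].values).isin(world.ssw_ep.all_days().values)
    u10.values[rows] = 3.0 + 0.2 * np.abs(u10.values[rows])  # from the SW:
    v10.values[rows] = 3.0 + 0.2 * np.abs(v10.values[rows])  # u>0 and v>0
    dirs = xr.DataArray(sd.wind_direction(u10.values, v10.values),
                        coords=u10.coords, dims=u10.dims)
    res = direction_hist_mc(dirs, world.ssw_ep, world.null_eps)
    centers = (res.edges[:-1] + res.edges[1:]) / 2
    inc = np.flatnonzero(res.label == 1)
    # significant increases appear, and only at south-westerly directions;
    # the climatological north-easterlies lose probability instead
    assert inc.size > 0
    assert ((centers[inc] > 180) & (centers[inc] < 270)).all()
    ne = (centers > 0) & (centers < 90)
    assert (res.label[ne] <= 0).all()
    assert (res.label[ne] == -1).any()
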