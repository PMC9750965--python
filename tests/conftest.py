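"""Shared fixtures: a small synthetic world used across the test modules."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest
import xarray as xr
from hypothesis import settings

import stratdust as sd

settings.register_profile("default", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("default")


@dataclass
class World:
    cfg: sd.SynthConfig
    wind: pd.Series
    truth: sd.GroundTruth
    grids: dict[str, xr.DataArray]
    events: list[sd.SSWEvent]
    pool: set[int]
    ssw_ep: sd.EpisodeSet
    null_eps: list[sd.EpisodeSet]


@pytest.fixture(scope="session")
def small_cfg() -> sd.SynthConfig:
    # 8 winters, 4 planted SSWs: small enough for fast tests, large enough
    # for a non-degenerate null pool.
    return sd.SynthConfig(
        n_years=8, seed=7, ssw_events={1: 50, 3: 70, 5: 90, 6: 45}
    )


@pytest.fixture(scope="session")
def world(small_cfg) -> World:
    wind, truth = sd.make_strat_wind(small_cfg)
    grids = sd.make_surface_fields(small_cfg)
    events = sd.detect_ssw(wind)
    winters = range(small_cfg.start_year, small_cfg.start_year + small_cfg.n_years)
    pool = sd.winters_without_ssw(events, winters)
    ssw_ep = sd.build_ssw_episodes(events)
    null_eps = sd.sample_non_ssw_episodes(events, pool, n_sets=60, seed=11)
    return World(small_cfg, wind, truth, grids, events, pool, ssw_ep, null_eps)


@pytest.fixture(scope="session")
def dust_anom(world) -> xr.DataArray:
    cycle = sd.fit_seasonal_cycle(world.grids["dust"])
    return sd.anomalize(world.grids["dust"], cycle)
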