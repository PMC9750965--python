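"""Reading and writing the pipeline's file formats.

Grids are CF-style NetCDF (classic format, via xarray's scipy backend)
with dimensions time/lat/lon and a ``units`` attribute per variable.
Station series are two-column CSV (``date,value``) with ISO dates; an
empty value cell or a negative sentinel marks a missing day.
"""

from __future__ import annotations

import csv
import datetime
import math
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

_ENGINE = "scipy"  # NetCDF3 classic


def write_grid(da: xr.DataArray, path, name: str | None = None, **extra_attrs) -> None:
    """Write a daily (time, lat, lon) field or static raster to NetCDF."""
    name = name or da.name or "field"
    ds = da.to_dataset(name=name)
    ds.attrs.update(extra_attrs)
    ds.to_netcdf(path, engine=_ENGINE)


def read_grid(path, var: str | None = None) -> xr.DataArray:
    """Read and validate a gridded field.

    Requires time/lat/lon coordinates (time optional for static rasters)
    and a ``units`` attribute; normalizes latitude to ascending order and
    longitude to [-180, 180); rejects non-daily time steps.
    """
    ds = xr.open_dataset(path, engine=_ENGINE)
    if var is None:
        cands = [v for v in ds.data_vars if "lat" in ds[v].dims and "lon" in ds[v].dims]
        if len(cands) != 1:
            raise ValueError(f"cannot identify the data variable among {list(ds.data_vars)}")
        var = cands[0]
    da = ds[var].load()
    ds.close()
    for coord in ("lat", "lon"):
        if coord not in da.coords:
            raise ValueError(f"missing coordinate: {coord}")
    if "units" not in da.attrs:
        raise ValueError(f"missing units attribute on variable {var!r}")
    lon = ((da["lon"].to_numpy() + 180.0) % 360.0) - 180.0
    da = da.assign_coords(lon=lon).sortby("lon").sortby("lat")
    if "time" in da.dims:
        times = pd.DatetimeIndex(da["time"].values)
        step = np.unique(np.diff(times.values).astype("timedelta64[h]"))
        # NDJFM records legitimately jump Mar 31 -> Nov 1 (and over Feb 29);
        # any sub-daily or multi-day step that is not a season gap is rejected.
        ok = (step == np.timedelta64(24, "h")) | (step >= np.timedelta64(48, "h"))
        if len(times) > 1 and not ok.all():
            raise ValueError("time axis is not daily")
        da = da.assign_coords(time=times)
    return da


def write_station(series: pd.Series, path) -> None:
    """Write a daily station series as ``date,value`` CSV (blank = missing)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "value"])
        for date, value in series.items():
            w.writerow([pd.Timestamp(date).date().isoformat(),
                        "" if (value is None or (isinstance(value, float) and math.isnan(value))) else repr(float(value))])


def read_station(path, negative_missing: bool = True) -> pd.Series:
    """Read a ``date,value`` station CSV.

    Empty cells and (by default) negative sentinel values become NaN
    (missing days); pass ``negative_missing=False`` for signed series such
    as the stratospheric wind.  Unparseable dates are rejected with the
    offending line number; duplicate dates are rejected with the date.
    """
    dates: list[datetime.date] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["date", "value"]:
            raise ValueError(f"{path}: expected header 'date,value'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                d = datetime.date.fromisoformat(row[0].strip())
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable date on line {lineno}: {row[0]!r}") from exc
            cell = row[1].strip() if len(row) > 1 else ""
            if cell == "":
                v = math.nan
            else:
                v = float(cell)
                if negative_missing and v < 0:
                    v = math.nan  # negative sentinel
            dates.append(d)
            values.append(v)
    idx = pd.DatetimeIndex(dates)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0].date()
        raise ValueError(f"{path}: duplicated date {dup}")
    return pd.Series(values, index=idx, name=Path(path).stem)
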