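"""Analysis region boxes and box reductions on (lat, lon) grids."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr


@dataclass(frozen=True)
class Box:
    """A latitude/longitude box; membership is by cell centre, closed bounds."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if not (self.lat_min <= self.lat_max and self.lon_min <= self.lon_max):
            raise ValueError(f"degenerate box bounds: {self}")


#: Eastern Mediterranean dust-response box (enhanced dust after SSWs).
EASTERN_MEDITERRANEAN = Box(30.0, 33.75, 10.0, 30.0)

#: West Africa dust-response box (reduced dust after SSWs).
WEST_AFRICA = Box(16.25, 23.75, 12.5, 23.75)


def box_mask(obj: xr.DataArray, box: Box) -> xr.DataArray:
    """Boolean (lat, lon) mask of cell centres inside ``box`` (closed)."""
    lat = obj["lat"]
    lon = obj["lon"]
    mask = ((lat >= box.lat_min) & (lat <= box.lat_max)) & (
        (lon >= box.lon_min) & (lon <= box.lon_max)
    )
    return mask


def box_mean(field: xr.DataArray, box: Box, weighted: bool = False) -> xr.DataArray:
    """Mean of ``field`` over cells inside ``box``.

    Unweighted by default: the analysis boxes span at most 7.5 degrees of
    latitude, where cos-lat weights change the mean negligibly.  Pass
    ``weighted=True`` for cos(lat) area weighting.
    """
    mask = box_mask(field, box)
    if int(mask.sum()) == 0:
        raise ValueError(f"grid contains no cell centres inside {box}")
    sub = field.where(mask)
    if weighted:
        w = np.cos(np.deg2rad(field["lat"])) * xr.ones_like(field["lon"], dtype=float)
        w = w.where(mask)
        return (sub * w).sum(("lat", "lon"), skipna=True) / w.sum(skipna=True)
    return sub.mean(("lat", "lon"), skipna=True)
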