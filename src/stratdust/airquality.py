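"""Station PM10 air-quality indicators during SSW vs non-SSW episodes.

Two indicators, both computed on the days pooled across all episode
windows and corrected for observation gaps:

* ``level`` — the mean daily PM10 concentration over window days with data;
* ``expected_poor_days`` — exceedance days divided by available data days,
  times 30: the expected number of poor-air-quality days per 30-day period
  (not necessarily an integer).

Default thresholds are the EU daily PM10 standard (50 ug/m3) and the
higher Senegalese/Tunisian standard (260 ug/m3).  Exceedance is strict
(value > threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .episodes import EpisodeSet

#: EU daily-mean PM10 limit and the higher regional standard, ug/m3.
DEFAULT_THRESHOLDS = (50.0, 260.0)


def _window_values(series: pd.Series, ep: EpisodeSet) -> np.ndarray:
    """Values on all pooled window days; days absent from the record are NaN."""
    vals = series.reindex(ep.all_days()).to_numpy(dtype=float)
    return vals


def level(series: pd.Series, ep: EpisodeSet) -> float:
    """Mean PM10 over all non-missing window days, pooled across events."""
    vals = _window_values(series, ep)
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("no available data days in the episode windows")
    return float(vals[ok].mean())


def expected_poor_days(series: pd.Series, ep: EpisodeSet, threshold: float) -> float:
    """Gap-corrected exceedance days per 30-day period.

    (days with value > threshold) / (available days) * 30.
    """
    vals = _window_values(series, ep)
    ok = ~np.isnan(vals)
    n_avail = int(ok.sum())
    if n_avail == 0:
        raise ValueError("no available data days in the episode windows")
    n_poor = int((vals[ok] > threshold).sum())
    return 30.0 * n_poor / n_avail


@dataclass
class IndicatorNull:
    """Distribution of an indicator over the non-SSW replicates."""

    values: np.ndarray
    mean: float
    p5: float
    p95: float
    n_dropped: int  # replicates with zero available days


def indicator_null(
    series: pd.Series,
    null_eps: Sequence[EpisodeSet],
    threshold: float | None = None,
) -> IndicatorNull:
    """The indicator evaluated on every non-SSW replicate.

    Computes ``level`` when ``threshold`` is None, else
    ``expected_poor_days`` at that threshold.  Replicates with zero
    available days are dropped with a warning.
    """
    vals = []
    dropped = 0
    for ep in null_eps:
        try:
            if threshold is None:
                vals.append(level(series, ep))
            else:
                vals.append(expected_poor_days(series, ep, threshold))
        except ValueError:
            dropped += 1
    if not vals:
        raise ValueError("all null replicates have zero available days")
    if dropped:
        warnings.warn(f"dropped {dropped} null replicates with no data", stacklevel=2)
    arr = np.asarray(vals, dtype=float)
    lo, hi = np.percentile(arr, [5.0, 95.0])
    return IndicatorNull(values=arr, mean=float(arr.mean()),
                         p5=float(lo), p95=float(hi), n_dropped=dropped)


def percent_change(ssw_value: float, null_mean: float) -> float:
    """SSW-caused change relative to the non-SSW mean, in percent."""
    if not null_mean > 0:
        raise ValueError("non-SSW mean must be positive")
    return 100.0 * (ssw_value - null_mean) / null_mean
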