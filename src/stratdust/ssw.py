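"""Sudden-stratospheric-warming detection from the 60N / 10 hPa wind.

An SSW is a breakdown of the winter stratospheric polar vortex, detected as
a reversal of the zonal-mean zonal wind at 60N and 10 hPa from westerly to
easterly during the extended winter (NDJFM).  The first easterly day of a
qualifying reversal is the event's central date.

Two auxiliary rules of the standard definition are applied, both exposed as
parameters: easterly excursions beginning within ``min_separation_days`` of
a previous central date are merged into that event, and an excursion after
which the wind never returns westerly for at least ``recovery_days``
consecutive days before the winter ends is a final (springtime) warming and
is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import calendar as cal


@dataclass(frozen=True, order=True)
class SSWEvent:
    central_date: pd.Timestamp
    winter_start_year: int

    @property
    def winter_label(self) -> str:
        return cal.winter_label(self.winter_start_year)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as (start, stop) half-open pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_ssw(
    series: pd.Series,
    min_separation_days: int = 20,
    recovery_days: int = 10,
) -> list[SSWEvent]:
    """Detect SSW central dates in a daily NDJFM wind series.

    ``series`` is the daily-mean zonal-mean zonal wind at 60N / 10 hPa in
    m/s, westerly positive, indexed by calendar date and covering whole
    extended winters.  Easterly means u < 0 strictly; u = 0 counts as
    westerly.

    Returns one :class:`SSWEvent` per qualifying wind reversal, in time
    order.  An empty series yields an empty list; NaNs are rejected.
    """
    if len(series) == 0:
        return []
    if series.isna().any():
        raise ValueError("wind series contains NaN")
    dates = pd.DatetimeIndex(series.index)
    if not dates.is_monotonic_increasing or dates.has_duplicates:
        raise ValueError("dates must be strictly increasing")

    events: list[SSWEvent] = []
    winters = cal.winter_start_year(dates)
    for wy in np.unique(winters):
        sel = winters == wy
        u = series.to_numpy()[sel]
        wdates = dates[sel]
        easterly_runs = _runs(u < 0)
        if not easterly_runs:
            continue
        # Merge excursions starting within min_separation_days of the
        # previous group's central day.
        groups: list[list[tuple[int, int]]] = []
        for run in easterly_runs:
            if groups and run[0] - groups[-1][0][0] < min_separation_days:
                groups[-1].append(run)
            else:
                groups.append([run])
        westerly = u >= 0
        for group in groups:
            tail = westerly[group[-1][1] :]
            recovered = any(stop - start >= recovery_days for start, stop in _runs(tail))
            if not recovered:
                continue  # final warming: vortex never re-forms this winter
            central = group[0][0]
            events.append(SSWEvent(pd.Timestamp(wdates[central]), int(wy)))
    return sorted(events)


def winters_without_ssw(
    events: Iterable[SSWEvent], winter_start_years: Sequence[int]
) -> set[int]:
    """Winters (by starting year) of the inventory containing no event."""
    with_event = {e.winter_start_year for e in events}
    return {int(w) for w in winter_start_years} - with_event
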