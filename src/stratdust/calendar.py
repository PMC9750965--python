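"""Extended-winter (NDJFM) calendar utilities on a fixed 365-day year.

The analysis season is the extended boreal winter, November through March
(NDJFM).  An extended winter starting in year ``y`` runs Nov 1 of ``y``
through Mar 31 of ``y+1`` and is labelled "y/(y+1)" (e.g. "1980/81").
All climatological arithmetic uses a 365-day year: Feb 29 is dropped from
generated calendars, and where leap days occur in external data they are
mapped onto Feb 28's calendar day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Days in one extended winter: Nov(30) + Dec(31) + Jan(31) + Feb(28) + Mar(31).
DAYS_PER_WINTER = 151

#: Months belonging to the extended winter season.
NDJFM_MONTHS = (11, 12, 1, 2, 3)

_MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_CUM_DAYS = np.concatenate([[0], np.cumsum(_MONTH_DAYS[:-1])])


def noleap_doy(dates) -> np.ndarray:
    """Day of year on the 365-day calendar; Feb 29 maps to Feb 28 (doy 59)."""
    dates = pd.DatetimeIndex(dates)
    m = dates.month.to_numpy()
    d = dates.day.to_numpy()
    d = np.where((m == 2) & (d == 29), 28, d)
    return _CUM_DAYS[m - 1] + d


def drop_feb29(dates: pd.DatetimeIndex) -> pd.DatetimeIndex:
    return dates[~((dates.month == 2) & (dates.day == 29))]


def winter_days(start_year: int) -> pd.DatetimeIndex:
    """All 151 days of the extended winter starting Nov 1 of ``start_year``."""
    days = pd.date_range(f"{start_year}-11-01", f"{start_year + 1}-03-31", freq="D")
    return drop_feb29(days)


def winter_calendar(start_year: int, n_years: int) -> pd.DatetimeIndex:
    """Concatenated NDJFM calendar for ``n_years`` consecutive winters."""
    parts = [winter_days(start_year + k) for k in range(n_years)]
    return parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]


def in_ndjfm(dates) -> np.ndarray:
    dates = pd.DatetimeIndex(dates)
    return np.isin(dates.month, NDJFM_MONTHS)


def winter_start_year(dates) -> np.ndarray:
    """Starting year of the extended winter containing each date.

    Nov/Dec dates belong to the winter of their own year; Jan–Mar dates to
    the winter that started the previous year.  Dates outside NDJFM are
    assigned by the same rule (months 4–10 map to the preceding winter) but
    are not meaningful.
    """
    dates = pd.DatetimeIndex(dates)
    y = dates.year.to_numpy()
    return np.where(dates.month.to_numpy() >= 11, y, y - 1)


def winter_label(start_year: int) -> str:
    return f"{start_year}/{str(start_year + 1)[-2:]}"


def next_days(date, n: int) -> pd.DatetimeIndex:
    """The ``n`` calendar days strictly after ``date``, Feb 29 skipped.

    Used to build the 30-day post-onset episode windows: day +1 is the day
    after the central date.
    """
    date = pd.Timestamp(date)
    span = pd.date_range(date + pd.Timedelta(days=1), periods=n + 2, freq="D")
    return drop_feb29(span)[:n]
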