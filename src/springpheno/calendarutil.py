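"""Fixed 365-day (no-leap) calendar helpers.

All date arithmetic in this package runs on a no-leap calendar: every year
has 365 days and February always has 28.  Day-of-year (DOY) is 1-based, so
Jan 1 = 1 and Dec 31 = 365.  A daily meteorological series for year *y*
additionally carries the preceding November and December (61 days), so that
chilling sums that start on Nov 1 never need a second record.
"""

from __future__ import annotations

import numpy as np

#: days in each month on the no-leap calendar
MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

#: cumulative days before each month (Jan -> 0, Feb -> 31, ...)
_CUM = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])

DAYS_PER_YEAR = 365
#: length of the Nov 1 .. Dec 31 prefix carried by every met series
N_PREFIX = 61
#: DOY of November 1 on the no-leap calendar
NOV1_DOY = 305
#: total length of a met series: prefix + full calendar year
SERIES_LEN = N_PREFIX + DAYS_PER_YEAR


def doy_to_date(year: int, doy: int) -> str:
    """ISO date string for a 1-based day-of-year on the no-leap calendar."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError(f"doy must be in [1, 365], got {doy}")
    month = int(np.searchsorted(_CUM, doy, side="left"))
    day = doy - _CUM[month - 1]
    return f"{year:04d}-{month:02d}-{day:02d}"


def date_to_year_doy(date: str) -> tuple[int, int]:
    """Parse an ISO date string; Feb 29 is rejected (no-leap calendar)."""
    try:
        y, m, d = (int(p) for p in date.split("-"))
    except ValueError as exc:
        raise ValueError(f"unparseable ISO date: {date!r}") from exc
    if not 1 <= m <= 12 or not 1 <= d <= MONTH_LENGTHS[m - 1]:
        raise ValueError(f"invalid no-leap calendar date: {date!r}")
    return y, int(_CUM[m - 1] + d)


def ordinal(year: int, doy: int) -> int:
    """Absolute day count on the no-leap calendar (monotone across years)."""
    return year * DAYS_PER_YEAR + (doy - 1)


def from_ordinal(o: int) -> tuple[int, int]:
    year, rem = divmod(int(o), DAYS_PER_YEAR)
    return year, rem + 1


def series_dates(year: int) -> list[str]:
    """ISO dates for a full met series: Nov 1 of ``year-1`` .. Dec 31 of ``year``."""
    out = [doy_to_date(year - 1, d) for d in range(NOV1_DOY, DAYS_PER_YEAR + 1)]
    out += [doy_to_date(year, d) for d in range(1, DAYS_PER_YEAR + 1)]
    return out


def series_ordinals(year: int) -> np.ndarray:
    """Absolute day ordinals for the 426-day series of ``year``."""
    start = ordinal(year - 1, NOV1_DOY)
    return np.arange(start, start + SERIES_LEN)
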