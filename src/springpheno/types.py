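"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calendarutil import SERIES_LEN, N_PREFIX, series_dates


@dataclass
class DailyMetSeries:
    """One pixel-year of daily weather on the no-leap calendar.

    The series covers Nov 1 of ``year - 1`` through Dec 31 of ``year``
    (426 consecutive days), so that chilling-day sums starting the previous
    November are computable from a single record.

    Attributes
    ----------
    pixel_id : str
        Opaque pixel identifier.
    year : int
        The calendar year the record belongs to.
    tmean : ndarray
        Daily mean air temperature, degC, length 426.
    precip : ndarray
        Daily precipitation, mm, length 426, non-negative.
    """

    pixel_id: str
    year: int
    tmean: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        self.tmean = np.asarray(self.tmean, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        if self.tmean.shape != (SERIES_LEN,) or self.precip.shape != (SERIES_LEN,):
            raise ValueError(
                f"met series must have {SERIES_LEN} days "
                f"(Nov 1 of year-1 .. Dec 31), got {self.tmean.shape}"
            )
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be non-negative")

    @property
    def dates(self) -> list[str]:
        """ISO dates of every day in the series."""
        return series_dates(self.year)

    @property
    def tmean_year(self) -> np.ndarray:
        """Temperatures of the Jan 1 .. Dec 31 window (length 365)."""
        return self.tmean[N_PREFIX:]

    @property
    def precip_year(self) -> np.ndarray:
        """Precipitation of the Jan 1 .. Dec 31 window (length 365)."""
        return self.precip[N_PREFIX:]

    @property
    def t_avg_annual(self) -> float:
        """Annual mean of daily temperature of the record's calendar year."""
        return float(self.tmean_year.mean())

    @property
    def annual_precip(self) -> float:
        """Total precipitation of the record's calendar year, mm."""
        return float(self.precip_year.sum())


@dataclass(frozen=True)
class BGSRecord:
    """Beginning-of-growing-season date for one pixel-year.

    ``bgs_doy`` is a 1-based day of year, or ``None`` when no onset
    occurred (the missing state).  DOY 366 is tolerated only so that
    externally supplied leap-calendar observations can be read; nothing in
    this package ever produces it.
    """

    pixel_id: str
    year: int
    bgs_doy: int | None

    def __post_init__(self) -> None:
        if self.bgs_doy is not None and not 1 <= self.bgs_doy <= 366:
            raise ValueError(f"bgs_doy must be in [1, 366] or None, got {self.bgs_doy}")

    @property
    def missing(self) -> bool:
        return self.bgs_doy is None


@dataclass(frozen=True)
class SiteContext:
    """Per-pixel quantities a predictor may need beyond the daily series.

    ``t_avg_annual`` (degC) and ``avg_ann_precip`` (mm) default to being
    computed from the driving record's own calendar year.
    """

    latitude: float = 45.0
    t_avg_annual: float | None = None
    avg_ann_precip: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must be in [0, 90] degrees north")
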