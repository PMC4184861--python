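import numpy as np
import pytest

from springpheno.calendarutil import DAYS_PER_YEAR, NOV1_DOY, SERIES_LEN
from springpheno.types import DailyMetSeries

N_PREFIX = 61


def sinusoid_series(
    mean: float = 5.0,
    amplitude: float = 15.0,
    peak_doy: int = 200,
    annual_precip: float = 500.0,
    wet_center: int = 200,
    concentration: float = 2.0,
    pixel_id: str = "fix",
    year: int = 2005,
) -> DailyMetSeries:
    """Deterministic fixture: sinusoidal temperature, raised-cosine precip.

    The precipitation is the expected seasonal profile (no sampling), so
    every derived quantity has a closed-form daily value.
    """
    doys = np.concatenate(
        [np.arange(NOV1_DOY, DAYS_PER_YEAR + 1), np.arange(1, DAYS_PER_YEAR + 1)]
    ).astype(float)
    tmean = mean - amplitude * np.cos(2 * np.pi * (doys - peak_doy + 182.5) / 365.0)
    w = ((1 + np.cos(2 * np.pi * (np.arange(1, 366) - wet_center) / 365.0)) / 2.0) ** concentration
    year_precip = annual_precip * w / w.sum()
    precip = np.concatenate([year_precip[NOV1_DOY - 1 :], year_precip])
    return DailyMetSeries(pixel_id, year, tmean, precip)


def constant_series(tmean_c: float, precip_mm: float = 0.0, year: int = 2005) -> DailyMetSeries:
    return DailyMetSeries(
        "const", year, np.full(SERIES_LEN, float(tmean_c)), np.full(SERIES_LEN, float(precip_mm))
    )


@pytest.fixture(scope="session")
def standard_series() -> DailyMetSeries:
    """The standard cool-site fixture (annual mean 5 degC, amplitude 15)."""
    return sinusoid_series()


@pytest.fixture(scope="session")
def warm_series() -> DailyMetSeries:
    """A mild-winter fixture (annual mean 12 degC, amplitude 12): no
    chilling days below 0 degC."""
    return sinusoid_series(mean=12.0, amplitude=12.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_series(rng: np.random.Generator, pixel_id: str = "rnd", year: int = 2005) -> DailyMetSeries:
    """A randomized but physically plausible pixel-year."""
    mean = rng.uniform(-5.0, 18.0)
    amp = rng.uniform(3.0, 20.0)
    noise = rng.uniform(0.0, 3.0)
    met = sinusoid_series(
        mean=mean,
        amplitude=amp,
        peak_doy=int(rng.integers(180, 220)),
        annual_precip=rng.uniform(100.0, 1200.0),
        wet_center=int(rng.integers(1, 366)),
        concentration=rng.uniform(0.0, 6.0),
        pixel_id=pixel_id,
        year=year,
    )
    tmean = met.tmean + rng.normal(0.0, noise, SERIES_LEN)
    precip = met.precip * rng.gamma(1.0, 1.0, SERIES_LEN)
    return DailyMetSeries(pixel_id, year, tmean, precip)
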