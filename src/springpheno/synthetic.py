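"""Synthetic pixel landscapes, daily climate, and onset observations.

The generator emulates the kind of inputs a hemispheric phenology study
draws from a gridded reanalysis and a satellite phenology product: per
pixel, a daily mean-temperature series that is a latitude/site-dependent
sinusoid plus iid Gaussian noise, gamma-distributed daily precipitation
with a raised-cosine seasonal concentration, and onset observations
produced by running a chosen onset model and adding integer-rounded
Gaussian observation error (satellite onset dates are reported in whole
days).

Noise is keyed to (seed, pixel, calendar year), so the Nov-Dec overlap
between the 426-day series of consecutive years is bitwise identical —
the synthetic climate is one continuous realization per pixel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .calendarutil import DAYS_PER_YEAR, NOV1_DOY
from .climate import Biome, Scheme
from .models import ModelKind, ParamSet, predict
from .types import BGSRecord, DailyMetSeries, SiteContext


@dataclass(frozen=True)
class ClimateGenConfig:
    """Parameters of the per-pixel climate generator.

    ``seasonal_amplitude`` is half the peak-to-trough range of the annual
    temperature cycle; ``precip_concentration`` >= 0 controls how strongly
    rainfall clusters around ``wet_season_center_doy`` (0 = uniform).
    """

    mean_annual_temp: float = 5.0
    seasonal_amplitude: float = 12.0
    temp_noise_sd: float = 1.0
    peak_doy: int = 200
    annual_precip: float = 500.0
    wet_season_center_doy: int = 200
    precip_concentration: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.temp_noise_sd < 0:
            raise ValueError("temp_noise_sd must be >= 0")
        if self.annual_precip < 0:
            raise ValueError("annual_precip must be >= 0")
        if self.precip_concentration < 0:
            raise ValueError("precip_concentration must be >= 0")


@dataclass(frozen=True)
class PixelSite:
    """One pixel of the synthetic landscape."""

    pixel_id: str
    latitude: float
    biome: Biome
    climate_config: ClimateGenConfig

    def __post_init__(self) -> None:
        if not 0.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must be in [0, 90] (Northern Hemisphere)")


def _pixel_rng(seed: int, pixel_id: str, year: int, stream: int) -> np.random.Generator:
    """Deterministic per-(pixel, year, stream) generator."""
    key = zlib.crc32(pixel_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, key, year, stream]))


def seasonal_temperature(config: ClimateGenConfig, doy: np.ndarray) -> np.ndarray:
    """Deterministic part of the temperature cycle at the given days of year."""
    phase = 2.0 * np.pi * (np.asarray(doy, dtype=float) - config.peak_doy + 182.5) / 365.0
    return config.mean_annual_temp - config.seasonal_amplitude * np.cos(phase)


def seasonal_precip_weights(config: ClimateGenConfig) -> np.ndarray:
    """Expected share of annual precipitation per DOY (sums to 1).

    A raised cosine centered on the wet season, raised to the
    ``precip_concentration`` power; concentration 0 gives a uniform year.
    """
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    base = 1.0 + np.cos(2.0 * np.pi * (doy - config.wet_season_center_doy) / 365.0)
    w = (base / 2.0) ** config.precip_concentration
    total = w.sum()
    if total == 0.0:  # infinite concentration collapse; keep a valid pmf
        w = np.zeros_like(w)
        w[int(config.wet_season_center_doy) - 1] = 1.0
        return w
    return w / total

#: shape of the daily gamma precipitation amounts (scale carries the season)
_PRECIP_GAMMA_SHAPE = 0.8


def _year_climate(site: PixelSite, year: int) -> tuple[np.ndarray, np.ndarray]:
    """Temperature and precipitation for one Jan-Dec calendar year."""
    cfg = site.climate_config
    doy = np.arange(1, DAYS_PER_YEAR + 1)
    tmean = seasonal_temperature(cfg, doy)
    if cfg.temp_noise_sd > 0:
        rng = _pixel_rng(cfg.seed, site.pixel_id, year, stream=0)
        tmean = tmean + rng.normal(0.0, cfg.temp_noise_sd, DAYS_PER_YEAR)
    weights = seasonal_precip_weights(cfg)
    if cfg.annual_precip > 0:
        rng = _pixel_rng(cfg.seed, site.pixel_id, year, stream=1)
        scale = cfg.annual_precip * weights / _PRECIP_GAMMA_SHAPE
        precip = rng.gamma(_PRECIP_GAMMA_SHAPE, 1.0, DAYS_PER_YEAR) * scale
    else:
        precip = np.zeros(DAYS_PER_YEAR)
    return tmean, precip


def generate_climate(site: PixelSite, year: int) -> DailyMetSeries:
    """Daily weather for one pixel-year (Nov 1 of ``year-1`` .. Dec 31).

    The expected daily temperature follows
    ``mean - amplitude * cos(2*pi*(d - peak_doy + 182.5)/365)`` with iid
    Normal(0, ``temp_noise_sd``^2) noise; daily precipitation is gamma with
    a seasonal scale whose annual sum is ``annual_precip`` in expectation.
    Identical (seed, pixel, year) always yields an identical series.
    """
    prev_t, prev_p = _year_climate(site, year - 1)
    cur_t, cur_p = _year_climate(site, year)
    tmean = np.concatenate([prev_t[NOV1_DOY - 1 :], cur_t])
    precip = np.concatenate([prev_p[NOV1_DOY - 1 :], cur_p])
    return DailyMetSeries(site.pixel_id, year, tmean, precip)


def generate_bgs_observations(
    model_kind: ModelKind | str,
    params: ParamSet,
    met: list[DailyMetSeries],
    obs_noise_sd: float,
    seed: int,
    sites: dict[str, PixelSite] | None = None,
    scheme: Scheme | str = Scheme.WOODY,
) -> list[BGSRecord]:
    """Observed onsets: model prediction plus integer-rounded Gaussian error.

    Pixel-years where the model never triggers are emitted as missing
    records.  ``sites`` supplies latitude (and biome scheme) when the model
    needs them; per-pixel annual statistics are taken from each record's
    own calendar year.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out: list[BGSRecord] = []
    for series in met:
        site = sites.get(series.pixel_id) if sites else None
        ctx = SiteContext(latitude=site.latitude if site else 45.0)
        use_scheme = site.biome.phenology_scheme if site else Scheme(scheme)
        pred = predict(model_kind, series, ctx, params, scheme=use_scheme)
        if pred.missing:
            out.append(pred)
            continue
        doy = pred.bgs_doy
        if obs_noise_sd > 0:
            doy = int(np.clip(doy + round(rng.normal(0.0, obs_noise_sd)), 1, DAYS_PER_YEAR))
        out.append(BGSRecord(series.pixel_id, series.year, doy))
    return out


@dataclass(frozen=True)
class GradientSpec:
    """Ranges the landscape spans, one value or an inclusive (lo, hi) range.

    Site mean annual temperatures are placed on an even grid over
    ``mean_annual_temp`` so the span is covered exactly; the other ranged
    fields are drawn uniformly (decorrelated from the temperature axis).
    """

    mean_annual_temp: tuple[float, float] = (-2.0, 10.0)
    seasonal_amplitude: float | tuple[float, float] = 12.0
    temp_noise_sd: float = 1.0
    peak_doy: int = 200
    annual_precip: float | tuple[float, float] = 500.0
    wet_season_center_doy: int | tuple[int, int] = 200
    precip_concentration: float = 2.0
    latitude: float | tuple[float, float] = 45.0


def _spread(value, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(value, tuple):
        lo, hi = value
        return rng.uniform(lo, hi, n)
    return np.full(n, float(value))


def generate_landscape(
    n_pixels: int,
    biome_mix: dict[Biome, float],
    gradient: GradientSpec | None = None,
    seed: int = 0,
) -> list[PixelSite]:
    """A reproducible set of pixel sites spanning a climate gradient.

    ``biome_mix`` maps biome -> proportion (must sum to 1); counts follow
    the largest-remainder rule and biome labels are shuffled across the
    temperature gradient so biome and climate are not confounded.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if not biome_mix:
        raise ValueError("biome_mix must not be empty")
    props = np.array(list(biome_mix.values()), dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("biome_mix proportions must sum to 1")
    gradient = gradient or GradientSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))

    lo, hi = gradient.mean_annual_temp
    means = np.linspace(lo, hi, n_pixels) if n_pixels > 1 else np.array([(lo + hi) / 2.0])
    amp = _spread(gradient.seasonal_amplitude, n_pixels, rng)
    precip = _spread(gradient.annual_precip, n_pixels, rng)
    wet = _spread(gradient.wet_season_center_doy, n_pixels, rng)
    lat = _spread(gradient.latitude, n_pixels, rng)

    # largest-remainder apportionment of biome counts
    raw = props * n_pixels
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for i in order[: n_pixels - counts.sum()]:
        counts[i] += 1
    labels: list[Biome] = []
    for biome, count in zip(biome_mix, counts):
        labels += [biome] * int(count)
    labels = [labels[i] for i in rng.permutation(n_pixels)]

    width = len(str(n_pixels - 1))
    sites = []
    for i in range(n_pixels):
        cfg = ClimateGenConfig(
            mean_annual_temp=float(means[i]),
            seasonal_amplitude=float(amp[i]),
            temp_noise_sd=gradient.temp_noise_sd,
            peak_doy=gradient.peak_doy,
            annual_precip=float(precip[i]),
            wet_season_center_doy=int(round(wet[i])),
            precip_concentration=gradient.precip_concentration,
            seed=seed,
        )
        sites.append(
            PixelSite(
                pixel_id=f"px{i:0{width}d}",
                latitude=float(lat[i]),
                biome=labels[i],
                climate_config=cfg,
            )
        )
    return sites
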