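"""Readers and writers for the package's file formats.

CSV is the canonical interchange; NetCDF (classic, via the SciPy backend)
is an optional dialect for gridded met data.  Daily met series are written
as one contiguous, deduplicated block of days per pixel (consecutive years
share their Nov-Dec overlap), and reconstructed per pixel-year on read.

Schemas
-------
met CSV:    pixel_id, date (ISO-8601, no-leap calendar), tmean_c, precip_mm
BGS CSV:    pixel_id, year, bgs_doy (empty field = missing)
sites CSV:  pixel_id, latitude, biome [+ climate generator columns]
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .calendarutil import (
    NOV1_DOY,
    SERIES_LEN,
    date_to_year_doy,
    from_ordinal,
    ordinal,
    series_dates,
)
from .climate import Biome
from .synthetic import ClimateGenConfig, PixelSite
from .types import BGSRecord, DailyMetSeries

MET_COLUMNS = ("pixel_id", "date", "tmean_c", "precip_mm")
BGS_COLUMNS = ("pixel_id", "year", "bgs_doy")


class MetGapError(ValueError):
    """A pixel's daily series has a hole."""


def _header_lines(seed: int | None, extra: dict | None = None) -> str:
    parts = []
    if seed is not None:
        parts.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        parts.append(f"# {k}: {v}")
    return "\n".join(parts) + ("\n" if parts else "")


# ---------------------------------------------------------------------------
# met series
# ---------------------------------------------------------------------------


def _met_frame(series: list[DailyMetSeries]) -> pd.DataFrame:
    """One row per (pixel, day), overlapping days deduplicated."""
    per_pixel: dict[str, dict[int, tuple[str, float, float]]] = {}
    for s in series:
        days = per_pixel.setdefault(s.pixel_id, {})
        start = ordinal(s.year - 1, NOV1_DOY)
        dates = series_dates(s.year)
        for i in range(SERIES_LEN):
            o = start + i
            row = (dates[i], float(s.tmean[i]), float(s.precip[i]))
            prev = days.get(o)
            if prev is not None and prev != row:
                raise ValueError(
                    f"inconsistent overlapping values for pixel {s.pixel_id} on {row[0]}"
                )
            days[o] = row
    rows = []
    for pid in sorted(per_pixel):
        for o in sorted(per_pixel[pid]):
            date, t, p = per_pixel[pid][o]
            rows.append((pid, date, t, p))
    return pd.DataFrame(rows, columns=list(MET_COLUMNS))


def write_met(series: list[DailyMetSeries], path: str | Path, seed: int | None = None) -> None:
    """Write met series to CSV (full float precision, one block per pixel)."""
    df = _met_frame(series)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_met(path: str | Path) -> list[DailyMetSeries]:
    """Read met CSV into per pixel-year series.

    A pixel-year is emitted for every calendar year whose full span
    (Nov 1 of the preceding year through Dec 31) is covered without gaps.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(MET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"met CSV missing columns: {sorted(missing)}")
    unknown = set(df.columns) - set(MET_COLUMNS)
    if unknown:
        warnings.warn(f"ignoring unknown met CSV columns: {sorted(unknown)}", stacklevel=2)
    out: list[DailyMetSeries] = []
    for pid, grp in df.groupby("pixel_id", sort=True):
        ydoy = [date_to_year_doy(d) for d in grp["date"]]
        ords = np.array([ordinal(y, d) for y, d in ydoy])
        order = np.argsort(ords)
        ords = ords[order]
        gaps = np.nonzero(np.diff(ords) != 1)[0]
        if gaps.size:
            y, d = from_ordinal(ords[gaps[0]] + 1)
            from .calendarutil import doy_to_date

            raise MetGapError(f"gap in daily series for pixel {pid} at {doy_to_date(y, d)}")
        tmean = grp["tmean_c"].to_numpy()[order]
        precip = grp["precip_mm"].to_numpy()[order]
        first_year, last_year = from_ordinal(ords[0])[0] + 1, from_ordinal(ords[-1])[0]
        for year in range(first_year, last_year + 1):
            start = ordinal(year - 1, NOV1_DOY)
            i0 = start - ords[0]
            if i0 < 0 or i0 + SERIES_LEN > len(ords):
                continue
            out.append(
                DailyMetSeries(str(pid), year, tmean[i0 : i0 + SERIES_LEN], precip[i0 : i0 + SERIES_LEN])
            )
    return out


def write_met_netcdf(series: list[DailyMetSeries], path: str | Path) -> None:
    """Write met series as classic NetCDF, dimensions (pixel, time).

    Time is the absolute no-leap day ordinal; every pixel must cover the
    same day range (pad by writing whole years).
    """
    df = _met_frame(series)
    ydoy = [date_to_year_doy(d) for d in df["date"]]
    df["ord"] = [ordinal(y, d) for y, d in ydoy]
    pivot_t = df.pivot(index="pixel_id", columns="ord", values="tmean_c")
    pivot_p = df.pivot(index="pixel_id", columns="ord", values="precip_mm")
    if pivot_t.isna().any().any():
        raise ValueError("NetCDF export requires all pixels to cover the same days")
    ds = xr.Dataset(
        {
            "tmean_c": (("pixel", "time"), pivot_t.to_numpy()),
            "precip_mm": (("pixel", "time"), pivot_p.to_numpy()),
        },
        coords={
            "pixel": np.array([p.encode() for p in pivot_t.index]),
            "time": pivot_t.columns.to_numpy().astype("int32"),
        },
        attrs={"time_units": "day ordinal on a 365-day no-leap calendar (year*365 + doy - 1)"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_met_netcdf(path: str | Path) -> list[DailyMetSeries]:
    """Read a NetCDF met file written by :func:`write_met_netcdf`."""
    ds = xr.open_dataset(path, engine="scipy")
    ords = ds["time"].to_numpy().astype(int)
    out: list[DailyMetSeries] = []
    for i, pid in enumerate(ds["pixel"].to_numpy()):
        pid = pid.decode() if isinstance(pid, bytes) else str(pid)
        tmean = ds["tmean_c"].values[i]
        precip = ds["precip_mm"].values[i]
        first_year, last_year = from_ordinal(ords[0])[0] + 1, from_ordinal(ords[-1])[0]
        for year in range(first_year, last_year + 1):
            i0 = ordinal(year - 1, NOV1_DOY) - ords[0]
            if i0 < 0 or i0 + SERIES_LEN > len(ords):
                continue
            out.append(DailyMetSeries(pid, year, tmean[i0 : i0 + SERIES_LEN], precip[i0 : i0 + SERIES_LEN]))
    ds.close()
    return out


# ---------------------------------------------------------------------------
# BGS records
# ---------------------------------------------------------------------------


def write_bgs(records: list[BGSRecord], path: str | Path, seed: int | None = None) -> None:
    """Write onset records to CSV; missing onsets become empty fields."""
    df = pd.DataFrame(
        {
            "pixel_id": [r.pixel_id for r in records],
            "year": [r.year for r in records],
            "bgs_doy": [r.bgs_doy if r.bgs_doy is not None else pd.NA for r in records],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(seed))
        df.to_csv(fh, index=False)


def read_bgs(path: str | Path) -> list[BGSRecord]:
    """Read onset records; empty ``bgs_doy`` fields map to the missing state."""
    df = pd.read_csv(path, comment="#")
    missing = set(BGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"BGS CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        doy = row["bgs_doy"]
        if pd.isna(doy):
            out.append(BGSRecord(str(row["pixel_id"]), int(row["year"]), None))
            continue
        doy = int(doy)
        if not 1 <= doy <= 366:
            raise ValueError(f"bgs_doy out of range [1, 366]: {doy}")
        out.append(BGSRecord(str(row["pixel_id"]), int(row["year"]), doy))
    return out


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------

_SITE_CFG_FIELDS = (
    "mean_annual_temp",
    "seasonal_amplitude",
    "temp_noise_sd",
    "peak_doy",
    "annual_precip",
    "wet_season_center_doy",
    "precip_concentration",
    "seed",
)


def write_sites(sites: list[PixelSite], path: str | Path, seed: int | None = None) -> None:
    rows = []
    for s in sites:
        row = {"pixel_id": s.pixel_id, "latitude": s.latitude, "biome": s.biome.value}
        row.update({f: getattr(s.climate_config, f) for f in _SITE_CFG_FIELDS})
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed))
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.17g")


def read_sites(path: str | Path) -> list[PixelSite]:
    df = pd.read_csv(path, comment="#")
    out = []
    for _, row in df.iterrows():
        cfg_kwargs = {
            f: row[f] for f in _SITE_CFG_FIELDS if f in df.columns and not pd.isna(row[f])
        }
        for int_field in ("peak_doy", "wet_season_center_doy", "seed"):
            if int_field in cfg_kwargs:
                cfg_kwargs[int_field] = int(cfg_kwargs[int_field])
        out.append(
            PixelSite(
                pixel_id=str(row["pixel_id"]),
                latitude=float(row["latitude"]),
                biome=Biome(row["biome"]),
                climate_config=ClimateGenConfig(**cfg_kwargs),
            )
        )
    return out
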