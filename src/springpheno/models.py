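"""The four spring-onset models as deterministic day-scan predictors.

Every model scans one pixel-year of daily mean air temperature (plus the
preceding Nov-Dec for the chilling model) and returns the first day of year
(DOY) on which its onset criterion is met, or the missing state if the
criterion is never met by Dec 31.

One-phase models
    * **GDD** — accumulate ``max(T_d - T_base, 0)`` from a start day
      (default Jan 1); onset when the sum reaches a critical value
      ``GDD_c``.
    * **NGD** — count days with ``T_d > T_base``; onset when the count
      reaches a critical number of growing days ``NGD_c``.
    * **Biome-BGC woody** — accumulate soil-temperature excess above a
      base, where soil temperature is proxied by an 11-day trailing mean of
      air temperature; the critical sum is site-adapted,
      ``exp(a + b * T_avg)`` with ``T_avg`` the annual mean temperature;
      onset additionally requires day length above 39300 s, and the
      reported onset is 15 days before the threshold-crossing day.
    * **Biome-BGC grass** — as woody but the critical thermal sum is
      ``c * max(T_avg, 0) + d`` and, in addition, cumulative precipitation
      from Jan 1 must reach a fraction ``k`` of the average annual
      precipitation.

Two-phase model
    * **NCD-GDD** — chilling days (daily mean below a chill base) are
      counted from Nov 1; forcing degree-days accumulate from Jan 1; onset
      on the first day ``t`` with
      ``GDD(t) >= g + h * exp(w * NCD(t))`` (``w <= 0``: more chilling
      lowers the forcing requirement).

All kernels accept a 1-D series or a 2-D batch ``(n_series, n_days)`` and
are pure NumPy; the public per-series predictors wrap them and return
:class:`~springpheno.types.BGSRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .calendarutil import DAYS_PER_YEAR, N_PREFIX, SERIES_LEN
from .climate import Scheme
from .types import BGSRecord, DailyMetSeries, SiteContext

#: photoperiod gate of the Biome-BGC woody rule, seconds of day length
DAYLENGTH_GATE_S = 39300.0
#: the reported onset precedes the threshold-crossing day by this many days
ONSET_OFFSET_DAYS = 15
#: window of the trailing-mean soil-temperature proxy, days
SOIL_WINDOW_DAYS = 11

MISSING = -1  # batch-kernel sentinel for "no onset"


class ModelKind(str, Enum):
    GDD = "gdd"
    BBGC = "bbgc"
    NGD = "ngd"
    NCD_GDD = "ncd_gdd"


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GDDParams:
    """Growing-degree-day model: base temperature, critical sum, start day."""

    t_base: float
    gdd_crit: float
    t0: int = 1

    def __post_init__(self) -> None:
        if self.gdd_crit < 0:
            raise ValueError("gdd_crit must be >= 0")
        if not 1 <= self.t0 <= DAYS_PER_YEAR:
            raise ValueError("t0 must be a day of year in [1, 365]")


@dataclass(frozen=True)
class BBGCWoodyParams:
    """Biome-BGC woody rule: critical sum ``exp(a + b * T_avg)``."""

    t_base: float
    a: float
    b: float
    daylength_gate_s: float = DAYLENGTH_GATE_S
    onset_offset_days: int = ONSET_OFFSET_DAYS
    soil_window_days: int = SOIL_WINDOW_DAYS

    def __post_init__(self) -> None:
        if self.soil_window_days < 1 or self.soil_window_days % 2 == 0:
            raise ValueError("soil_window_days must be odd and positive")
        if self.onset_offset_days < 0:
            raise ValueError("onset_offset_days must be >= 0")


@dataclass(frozen=True)
class BBGCGrassParams:
    """Biome-BGC grass rule: thermal sum ``c * max(T_avg, 0) + d`` plus a
    precipitation criterion ``k * AvgAnnPrcp``."""

    t_base: float
    c: float
    d: float
    k: float
    onset_offset_days: int = ONSET_OFFSET_DAYS
    soil_window_days: int = SOIL_WINDOW_DAYS

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must be a fraction in [0, 1]")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.soil_window_days < 1 or self.soil_window_days % 2 == 0:
            raise ValueError("soil_window_days must be odd and positive")


@dataclass(frozen=True)
class NGDParams:
    """Number-of-growing-days model."""

    t_base: float
    ngd_crit: int
    t0: int = 1

    def __post_init__(self) -> None:
        if int(self.ngd_crit) != self.ngd_crit or self.ngd_crit < 1:
            raise ValueError("ngd_crit must be a positive integer")


@dataclass(frozen=True)
class NCDGDDParams:
    """Chilling/forcing model: forcing requirement ``g + h * exp(w * NCD)``."""

    t_chill: float
    t_base: float
    g: float
    h: float
    w: float

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.w > 0:
            raise ValueError("w must be <= 0 (chilling cannot raise the requirement)")


ParamSet = GDDParams | BBGCWoodyParams | BBGCGrassParams | NGDParams | NCDGDDParams


# ---------------------------------------------------------------------------
# array kernels (1-D series or 2-D batches)
# ---------------------------------------------------------------------------


def gdd_accumulate(tmean_year: np.ndarray, t_base: float, t0: int = 1) -> np.ndarray:
    """Cumulative degree-days ``sum(max(T_d - t_base, 0))`` from day ``t0``.

    ``tmean_year`` covers Jan 1 .. Dec 31 (last axis length 365).  Days
    before ``t0`` contribute nothing and report 0.
    """
    t = np.asarray(tmean_year, dtype=float)
    excess = np.maximum(t - t_base, 0.0)
    if t0 > 1:
        excess = excess.copy()
        excess[..., : t0 - 1] = 0.0
    return np.cumsum(excess, axis=-1)


def soil_temperature(tmean: np.ndarray, window_days: int = SOIL_WINDOW_DAYS) -> np.ndarray:
    """Trailing running mean of daily temperature (the soil-temperature proxy).

    The mean is causal: day ``i`` averages days ``i-window+1 .. i``.  Days
    with fewer than ``window_days`` predecessors average all available days.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    t = np.asarray(tmean, dtype=float)
    s = np.cumsum(t, axis=-1)
    n = t.shape[-1]
    out = np.empty_like(t)
    w = min(window_days, n)
    head = s[..., : w - 1] / np.arange(1, w)
    out[..., : w - 1] = head
    out[..., w - 1 :] = (s[..., w - 1 :] - np.concatenate(
        [np.zeros(t.shape[:-1] + (1,)), s[..., : n - w]], axis=-1
    )) / w
    return out


def day_length(latitude: float, doy: int | np.ndarray) -> np.ndarray | float:
    """Astronomical day length in seconds.

    Solar declination ``delta = -23.44 deg * cos(2*pi*(doy + 10)/365)``;
    the half-day hour angle satisfies
    ``cos(omega) = -tan(lat) * tan(delta)``, clamped so that polar day and
    night return 86400 and 0 s.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must be within [-90, 90]")
    doy_arr = np.asarray(doy, dtype=float)
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (doy_arr + 10.0) / 365.0)
    cos_omega = -math.tan(math.radians(latitude)) * np.tan(decl)
    cos_omega = np.clip(cos_omega, -1.0, 1.0)
    omega = np.arccos(cos_omega)  # radians, half-day
    seconds = omega / np.pi * 86400.0
    if np.isscalar(doy):
        return float(seconds)
    return seconds


def _first_true_doy(ok: np.ndarray) -> np.ndarray:
    """First qualifying DOY along the last axis of a (batch of) 365-day mask."""
    ok2 = np.atleast_2d(ok)
    any_ok = ok2.any(axis=-1)
    idx = np.argmax(ok2, axis=-1)
    doy = np.where(any_ok, idx + 1, MISSING)
    return doy if ok.ndim > 1 else doy[0]


def gdd_onset(tmean_year: np.ndarray, params: GDDParams) -> np.ndarray:
    """Onset DOY(s) of the GDD model; ``MISSING`` where never triggered."""
    cum = gdd_accumulate(tmean_year, params.t_base, params.t0)
    ok = cum >= params.gdd_crit
    if params.t0 > 1:
        ok[..., : params.t0 - 1] = False
    return _first_true_doy(ok)


def ngd_onset(tmean_year: np.ndarray, params: NGDParams) -> np.ndarray:
    """Onset DOY(s) of the NGD model."""
    t = np.asarray(tmean_year, dtype=float)
    growing = (t > params.t_base).astype(np.int64)
    if params.t0 > 1:
        growing = growing.copy()
        growing[..., : params.t0 - 1] = 0
    count = np.cumsum(growing, axis=-1)
    return _first_true_doy(count >= params.ngd_crit)


def bbgc_woody_onset(
    tmean_full: np.ndarray,
    latitude: float | np.ndarray,
    params: BBGCWoodyParams,
    t_avg_annual: float | np.ndarray,
    soil: np.ndarray | None = None,
) -> np.ndarray:
    """Onset DOY(s) of the Biome-BGC woody rule.

    ``tmean_full`` is the 426-day series (Nov 1 prefix included) so the
    trailing soil-temperature mean has real predecessors on Jan 1.
    ``soil`` may carry a precomputed trailing mean of ``tmean_full``.
    """
    t = np.asarray(tmean_full, dtype=float)
    if soil is None:
        soil = soil_temperature(t, params.soil_window_days)
    soil = soil[..., N_PREFIX:]
    excess = np.maximum(soil - params.t_base, 0.0)
    cum = np.cumsum(excess, axis=-1)
    crit = np.exp(params.a + params.b * np.asarray(t_avg_annual, dtype=float))
    thermal_ok = cum >= (crit[..., None] if np.ndim(crit) else crit)
    doys = np.arange(1, DAYS_PER_YEAR + 1)
    lat = np.asarray(latitude, dtype=float)
    if lat.ndim == 0:
        gate = day_length(float(lat), doys) > params.daylength_gate_s
    else:
        uniq, inv = np.unique(lat, return_inverse=True)
        dl = np.stack([np.asarray(day_length(float(u), doys)) for u in uniq])
        gate = dl[inv] > params.daylength_gate_s
    crossing = _first_true_doy(thermal_ok & gate)
    return np.where(
        crossing == MISSING, MISSING, np.maximum(crossing - params.onset_offset_days, 1)
    )


def bbgc_grass_onset(
    tmean_full: np.ndarray,
    precip_full: np.ndarray,
    params: BBGCGrassParams,
    t_avg_annual: float | np.ndarray,
    avg_ann_precip: float | np.ndarray,
    soil: np.ndarray | None = None,
) -> np.ndarray:
    """Onset DOY(s) of the Biome-BGC grass rule (thermal AND precipitation)."""
    t = np.asarray(tmean_full, dtype=float)
    if soil is None:
        soil = soil_temperature(t, params.soil_window_days)
    soil = soil[..., N_PREFIX:]
    cum_t = np.cumsum(np.maximum(soil - params.t_base, 0.0), axis=-1)
    cum_p = np.cumsum(np.asarray(precip_full, dtype=float)[..., N_PREFIX:], axis=-1)
    t_avg = np.asarray(t_avg_annual, dtype=float)
    p_ann = np.asarray(avg_ann_precip, dtype=float)
    crit_t = params.c * np.maximum(t_avg, 0.0) + params.d
    crit_p = params.k * p_ann
    ok = (cum_t >= (crit_t[..., None] if crit_t.ndim else crit_t)) & (
        cum_p >= (crit_p[..., None] if crit_p.ndim else crit_p)
    )
    crossing = _first_true_doy(ok)
    return np.where(
        crossing == MISSING, MISSING, np.maximum(crossing - params.onset_offset_days, 1)
    )


def ncd_gdd_onset(tmean_full: np.ndarray, params: NCDGDDParams) -> np.ndarray:
    """Onset DOY(s) of the two-phase chilling/forcing model.

    Chilling days (daily mean strictly below the chill base) are counted
    from Nov 1 of the previous year; forcing degree-days accumulate from
    Jan 1; both counts include the current day.
    """
    t = np.asarray(tmean_full, dtype=float)
    if t.shape[-1] != SERIES_LEN:
        raise ValueError(
            "chilling model needs the Nov-Dec prefix: expected "
            f"{SERIES_LEN}-day series, got {t.shape[-1]}"
        )
    chill = np.cumsum(t < params.t_chill, axis=-1)[..., N_PREFIX:]
    gdd = gdd_accumulate(t[..., N_PREFIX:], params.t_base, t0=1)
    crit = params.g + params.h * np.exp(params.w * chill)
    return _first_true_doy(gdd >= crit)


# ---------------------------------------------------------------------------
# per-series predictors
# ---------------------------------------------------------------------------


def _record(met: DailyMetSeries, doy: int) -> BGSRecord:
    return BGSRecord(met.pixel_id, met.year, None if doy == MISSING else int(doy))


def predict_gdd(met: DailyMetSeries, params: GDDParams) -> BGSRecord:
    """First day the cumulative degree-day sum reaches ``gdd_crit``."""
    return _record(met, int(gdd_onset(met.tmean_year, params)))


def predict_ngd(met: DailyMetSeries, params: NGDParams) -> BGSRecord:
    """First day the growing-day count reaches ``ngd_crit``."""
    return _record(met, int(ngd_onset(met.tmean_year, params)))


def predict_bbgc_woody(
    met: DailyMetSeries,
    latitude: float,
    params: BBGCWoodyParams,
    t_avg_annual: float | None = None,
) -> BGSRecord:
    if t_avg_annual is None:
        t_avg_annual = met.t_avg_annual
    return _record(met, int(bbgc_woody_onset(met.tmean, latitude, params, t_avg_annual)))


def predict_bbgc_grass(
    met: DailyMetSeries,
    params: BBGCGrassParams,
    t_avg_annual: float | None = None,
    avg_ann_precip: float | None = None,
) -> BGSRecord:
    if t_avg_annual is None:
        t_avg_annual = met.t_avg_annual
    if avg_ann_precip is None:
        avg_ann_precip = met.annual_precip
    if avg_ann_precip <= 0:
        raise ValueError("avg_ann_precip must be > 0 for the grass rule")
    return _record(
        met, int(bbgc_grass_onset(met.tmean, met.precip, params, t_avg_annual, avg_ann_precip))
    )


def predict_ncd_gdd(met: DailyMetSeries, params: NCDGDDParams) -> BGSRecord:
    return _record(met, int(ncd_gdd_onset(met.tmean, params)))


def predict(
    model_kind: ModelKind | str,
    met: DailyMetSeries,
    site_context: SiteContext,
    params: ParamSet,
    scheme: Scheme | str = Scheme.WOODY,
) -> BGSRecord:
    """Dispatch to the predictor matching ``model_kind``.

    For the Biome-BGC family the variant is chosen by ``scheme`` (grass for
    grassland, savanna and woody-savanna classes; woody otherwise).
    """
    kind = ModelKind(model_kind)
    ctx = site_context
    if kind is ModelKind.GDD:
        _require(params, GDDParams, kind)
        return predict_gdd(met, params)
    if kind is ModelKind.NGD:
        _require(params, NGDParams, kind)
        return predict_ngd(met, params)
    if kind is ModelKind.NCD_GDD:
        _require(params, NCDGDDParams, kind)
        return predict_ncd_gdd(met, params)
    if Scheme(scheme) is Scheme.GRASS:
        _require(params, BBGCGrassParams, kind)
        return predict_bbgc_grass(met, params, ctx.t_avg_annual, ctx.avg_ann_precip)
    _require(params, BBGCWoodyParams, kind)
    return predict_bbgc_woody(met, ctx.latitude, params, ctx.t_avg_annual)


def _require(params: ParamSet, cls: type, kind: ModelKind) -> None:
    if not isinstance(params, cls):
        raise TypeError(
            f"model {kind.value!r} needs {cls.__name__}, got {type(params).__name__}"
        )


# ---------------------------------------------------------------------------
# batched prediction over many pixel-years (used by calibration)
# ---------------------------------------------------------------------------


@dataclass
class MetBatch:
    """Stacked pixel-year series for fast repeated prediction.

    ``tmean`` and ``precip`` are ``(n, 426)``; ``latitude``, ``t_avg`` and
    ``ann_precip`` are per-row site context.
    """

    pixel_ids: list[str]
    years: np.ndarray
    tmean: np.ndarray
    precip: np.ndarray
    latitude: np.ndarray
    t_avg: np.ndarray
    ann_precip: np.ndarray

    def __post_init__(self) -> None:
        self._cache: dict = {}

    def _cached(self, key, fn, max_entries: int = 24) -> np.ndarray:
        # small FIFO cache: repeated objective evaluations during
        # calibration sweep one threshold at a time, so consecutive calls
        # reuse the same cumulative arrays
        if key not in self._cache:
            if len(self._cache) >= max_entries:
                self._cache.pop(next(iter(self._cache)))
            self._cache[key] = fn()
        return self._cache[key]

    def soil(self, window_days: int) -> np.ndarray:
        """Cached trailing-mean soil-temperature proxy of the full series."""
        return self._cached(("soil", window_days), lambda: soil_temperature(self.tmean, window_days))

    def gdd_cum(self, t_base: float, t0: int = 1) -> np.ndarray:
        """Cached cumulative degree-days of the calendar year."""
        return self._cached(
            ("gdd", float(t_base), int(t0)),
            lambda: gdd_accumulate(self.tmean[:, N_PREFIX:], t_base, t0),
        )

    def growing_count(self, t_base: float, t0: int = 1) -> np.ndarray:
        """Cached cumulative count of days above ``t_base``."""

        def build() -> np.ndarray:
            growing = (self.tmean[:, N_PREFIX:] > t_base).astype(np.int64)
            if t0 > 1:
                growing[:, : t0 - 1] = 0
            return np.cumsum(growing, axis=1)

        return self._cached(("ngd", float(t_base), int(t0)), build)

    def chill_response(self, t_chill: float, w: float) -> np.ndarray:
        """Cached ``exp(w * NCD(t))`` with chilling counted from Nov 1."""

        def chill() -> np.ndarray:
            return np.cumsum(self.tmean < t_chill, axis=1)[:, N_PREFIX:]

        ncd = self._cached(("chill", float(t_chill)), chill)
        return self._cached(("chillresp", float(t_chill), float(w)), lambda: np.exp(w * ncd))

    def soil_cum(self, t_base: float, window_days: int) -> np.ndarray:
        """Cached cumulative soil-temperature excess from Jan 1."""
        soil = self.soil(window_days)
        return self._cached(
            ("soilcum", float(t_base), int(window_days)),
            lambda: np.cumsum(np.maximum(soil[:, N_PREFIX:] - t_base, 0.0), axis=1),
        )

    def precip_cum(self) -> np.ndarray:
        """Cached cumulative precipitation from Jan 1."""
        return self._cached(("pcum",), lambda: np.cumsum(self.precip[:, N_PREFIX:], axis=1))

    def daylength_gate(self, gate_s: float) -> np.ndarray:
        """Cached per-row day-length gate mask over the calendar year."""

        def build() -> np.ndarray:
            doys = np.arange(1, DAYS_PER_YEAR + 1)
            uniq, inv = np.unique(self.latitude, return_inverse=True)
            dl = np.stack([np.asarray(day_length(float(u), doys)) for u in uniq])
            return dl[inv] > gate_s

        return self._cached(("gate", float(gate_s)), build)

    @classmethod
    def from_series(
        cls, series: list[DailyMetSeries], latitudes: dict[str, float] | float = 45.0
    ) -> "MetBatch":
        tm = np.stack([s.tmean for s in series])
        pr = np.stack([s.precip for s in series])
        if isinstance(latitudes, dict):
            lat = np.array([latitudes[s.pixel_id] for s in series])
        else:
            lat = np.full(len(series), float(latitudes))
        return cls(
            pixel_ids=[s.pixel_id for s in series],
            years=np.array([s.year for s in series]),
            tmean=tm,
            precip=pr,
            latitude=lat,
            t_avg=tm[:, N_PREFIX:].mean(axis=1),
            ann_precip=pr[:, N_PREFIX:].sum(axis=1),
        )

    def __len__(self) -> int:
        return self.tmean.shape[0]


def predict_batch(
    model_kind: ModelKind | str,
    params: ParamSet,
    batch: MetBatch,
    scheme: Scheme | str = Scheme.WOODY,
) -> np.ndarray:
    """Onset DOY for every row of ``batch`` (``MISSING`` = no onset).

    Agrees exactly with the per-series predictors; intermediate cumulative
    arrays are cached on the batch so repeated calls during calibration
    only pay for the final threshold comparison.
    """
    kind = ModelKind(model_kind)
    if kind is ModelKind.GDD:
        ok = batch.gdd_cum(params.t_base, params.t0) >= params.gdd_crit
        if params.t0 > 1:
            ok[:, : params.t0 - 1] = False
        return _first_true_doy(ok)
    if kind is ModelKind.NGD:
        return _first_true_doy(batch.growing_count(params.t_base, params.t0) >= params.ngd_crit)
    if kind is ModelKind.NCD_GDD:
        crit = params.g + params.h * batch.chill_response(params.t_chill, params.w)
        return _first_true_doy(batch.gdd_cum(params.t_base) >= crit)
    cum_t = batch.soil_cum(params.t_base, params.soil_window_days)
    if Scheme(scheme) is Scheme.GRASS:
        ok = (cum_t >= (params.c * np.maximum(batch.t_avg, 0.0) + params.d)[:, None]) & (
            batch.precip_cum() >= (params.k * batch.ann_precip)[:, None]
        )
        crossing = _first_true_doy(ok)
    else:
        crit = np.exp(params.a + params.b * batch.t_avg)
        ok = (cum_t >= crit[:, None]) & batch.daylength_gate(params.daylength_gate_s)
        crossing = _first_true_doy(ok)
    return np.where(
        crossing == MISSING, MISSING, np.maximum(crossing - params.onset_offset_days, 1)
    )
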