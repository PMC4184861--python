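"""Parameter-recovery experiments on synthetic landscapes.

Each experiment generates a landscape spanning a climate gradient, drives
one onset model with the bundled calibrated parameters of a reference
biome to produce noise-free observations, splits the pixels in half,
calibrates the free parameters on the training half, and reports the
recovered values next to the generating truth.  They are the package's
standard self-checks that the calibration machinery can identify each
model family's parameters when the data actually come from that model.

Two further probes measure the Biome-BGC woody rule's behavioral
constants from the outside: the photoperiod gate (seconds of day length)
and the onset offset (days between the threshold-crossing day and the
reported onset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calendarutil import SERIES_LEN
from .calibrate import CalibrationResult, CalibrationSpec, calibrate, free_param, split_half
from .climate import Biome
from .models import (
    BBGCWoodyParams,
    ModelKind,
    day_length,
    predict_bbgc_woody,
)
from .params import default_params, dump_params
from .synthetic import GradientSpec, generate_bgs_observations, generate_climate, generate_landscape
from .types import DailyMetSeries


@dataclass
class RecoveryResult:
    """Outcome of one parameter-recovery experiment."""

    model_kind: ModelKind
    biome: Biome
    truth: dict[str, float]
    recovered: dict[str, float]
    sse: float
    n_train: int
    converged: bool

    def relative_error(self, name: str) -> float:
        t = self.truth[name]
        return abs(self.recovered[name] - t) / abs(t) if t != 0 else abs(self.recovered[name])


def _run_recovery(
    model: ModelKind,
    biome: Biome,
    gradient: GradientSpec,
    free: list,
    n_pixels: int,
    n_years: int,
    seed: int,
    fixed_overrides: dict | None = None,
) -> RecoveryResult:
    truth_params = default_params(biome, model)
    truth = dump_params(truth_params)
    for aux in ("daylength_gate_s", "onset_offset_days", "soil_window_days"):
        truth.pop(aux, None)
    scheme = biome.phenology_scheme

    mix = {biome: 1.0}
    sites = generate_landscape(n_pixels, mix, gradient, seed=seed)
    years = range(2001, 2001 + n_years)
    met = [generate_climate(s, y) for s in sites for y in years]
    site_by_id = {s.pixel_id: s for s in sites}
    obs = generate_bgs_observations(
        model, truth_params, met, obs_noise_sd=0.0, seed=seed, sites=site_by_id
    )

    train_sites, _ = split_half(sites, seed=seed)
    train_ids = {s.pixel_id for s in train_sites}
    train_obs = [r for r in obs if r.pixel_id in train_ids]
    met_lookup = {(m.pixel_id, m.year): m for m in met}
    latitudes = {s.pixel_id: s.latitude for s in sites}

    free_names = {p.name for p in free}
    fixed = {k: v for k, v in truth.items() if k not in free_names}
    fixed.update(fixed_overrides or {})
    spec = CalibrationSpec(
        model_kind=model,
        biome=biome,
        free_params=free,
        fixed_params=fixed,
        seed=seed,
        scheme=scheme,
    )
    result: CalibrationResult = calibrate(spec, train_obs, met_lookup, latitudes)
    return RecoveryResult(
        model_kind=model,
        biome=biome,
        truth=truth,
        recovered=dict(result.param_values),
        sse=result.sse,
        n_train=result.n_train,
        converged=result.converged,
    )


def gdd_recovery(seed: int = 42, n_pixels: int = 200, n_years: int = 10) -> RecoveryResult:
    """Recover (t_base, gdd_crit) of the evergreen-needleleaf GDD model."""
    gradient = GradientSpec(
        mean_annual_temp=(-2.0, 10.0), seasonal_amplitude=12.0, temp_noise_sd=1.0
    )
    free = [free_param("t_base"), free_param("gdd_crit")]
    return _run_recovery(
        ModelKind.GDD, Biome.EVERGREEN_NEEDLELEAF_FOREST, gradient, free, n_pixels, n_years, seed
    )


def ngd_recovery(seed: int = 43, n_pixels: int = 200, n_years: int = 10) -> RecoveryResult:
    """Recover (t_base, ngd_crit) of the deciduous-broadleaf NGD model."""
    gradient = GradientSpec(
        mean_annual_temp=(-2.0, 10.0), seasonal_amplitude=12.0, temp_noise_sd=1.0
    )
    free = [free_param("t_base"), free_param("ngd_crit")]
    return _run_recovery(
        ModelKind.NGD, Biome.DECIDUOUS_BROADLEAF_FOREST, gradient, free, n_pixels, n_years, seed
    )


def bbgc_woody_recovery(seed: int = 44, n_pixels: int = 300, n_years: int = 10) -> RecoveryResult:
    """Recover (t_base, a, b) of the deciduous-broadleaf woody rule.

    Sites span a wide mean-annual-temperature range so the dependence of
    the critical sum ``exp(a + b*T_avg)`` on site temperature is
    identifiable.
    """
    gradient = GradientSpec(
        mean_annual_temp=(0.0, 18.0), seasonal_amplitude=12.0, temp_noise_sd=0.5, latitude=45.0
    )
    free = [
        free_param("t_base", n_grid=11),
        free_param("a", n_grid=11),
        free_param("b", n_grid=11),
    ]
    return _run_recovery(
        ModelKind.BBGC, Biome.DECIDUOUS_BROADLEAF_FOREST, gradient, free, n_pixels, n_years, seed
    )


def ncd_gdd_recovery(seed: int = 45, n_pixels: int = 300, n_years: int = 10) -> RecoveryResult:
    """Recover (g, h, w) of the deciduous-broadleaf chilling/forcing law.

    Winter severity varies across the landscape so accumulated chilling
    days at onset range from none to deep-winter values, tracing out the
    negative-exponential forcing requirement.
    """
    gradient = GradientSpec(
        mean_annual_temp=(2.0, 16.0), seasonal_amplitude=12.0, temp_noise_sd=1.0
    )
    free = [free_param("g"), free_param("h"), free_param("w")]
    return _run_recovery(
        ModelKind.NCD_GDD, Biome.DECIDUOUS_BROADLEAF_FOREST, gradient, free, n_pixels, n_years, seed
    )


def bbgc_grass_recovery(seed: int = 46, n_pixels: int = 300, n_years: int = 10) -> RecoveryResult:
    """Recover (c, d, k) of the grassland grass rule.

    Springs are warm (the thermal criterion is met early) and wet seasons
    arrive late at pixel-dependent times, so the precipitation fraction
    ``k`` controls the onset for most pixel-years.
    """
    gradient = GradientSpec(
        mean_annual_temp=(8.0, 16.0),
        seasonal_amplitude=10.0,
        temp_noise_sd=1.0,
        annual_precip=(300.0, 600.0),
        wet_season_center_doy=(150, 260),
        precip_concentration=6.0,
    )
    free = [
        free_param("c", n_grid=11),
        free_param("d", n_grid=13),
        free_param("k", n_grid=21),
    ]
    return _run_recovery(
        ModelKind.BBGC, Biome.GRASSLAND, gradient, free, n_pixels, n_years, seed
    )


# ---------------------------------------------------------------------------
# behavioral constants of the woody rule
# ---------------------------------------------------------------------------


def _warm_series(year: int = 2001) -> DailyMetSeries:
    """Constant 20 degC, so the thermal criterion is met on day 1."""
    return DailyMetSeries("probe", year, np.full(SERIES_LEN, 20.0), np.zeros(SERIES_LEN))


def measure_onset_offset(latitude: float = 45.0) -> int:
    """Days between the threshold-crossing day and the reported onset.

    With a trivially satisfied thermal criterion (critical sum
    ``exp(0) = 1`` degree-day against constant warmth), the crossing day
    is the first day the photoperiod gate opens, located independently
    from the day-length curve; the offset is crossing minus reported
    onset.
    """
    params = BBGCWoodyParams(t_base=0.0, a=0.0, b=0.0)
    met = _warm_series()
    onset = predict_bbgc_woody(met, latitude, params).bgs_doy
    doys = np.arange(1, 366)
    gate_open = int(doys[np.asarray(day_length(latitude, doys)) > params.daylength_gate_s][0])
    return gate_open - onset


def measure_daylength_gate(lat_lo: float = 38.0, lat_hi: float = 55.0, n_lat: int = 600) -> float:
    """Behaviorally bracket the photoperiod gate, in seconds.

    At each latitude the gate lies between the day length of the last
    blocked day and that of the first permitted day; intersecting these
    brackets over many latitudes pins the constant down to a few seconds.
    The returned value is the bracket midpoint.
    """
    params = BBGCWoodyParams(t_base=0.0, a=0.0, b=0.0)
    offset = measure_onset_offset()
    lo, hi = 0.0, 86400.0
    doys = np.arange(1, 366)
    for lat in np.linspace(lat_lo, lat_hi, n_lat):
        met = _warm_series()
        onset = predict_bbgc_woody(met, float(lat), params).bgs_doy
        crossing = onset + offset
        dl = np.asarray(day_length(float(lat), doys))
        hi = min(hi, float(dl[crossing - 1]))  # gate < day length on the crossing day
        if crossing >= 2:
            lo = max(lo, float(dl[crossing - 2]))  # previous day stayed blocked
    return (lo + hi) / 2.0
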