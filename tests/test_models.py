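"""Unit and property tests for the four onset predictors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import constant_series, random_series, sinusoid_series
from springpheno.calendarutil import SERIES_LEN
from springpheno.climate import Scheme
from springpheno.models import (
    BBGCGrassParams,
    BBGCWoodyParams,
    GDDParams,
    MetBatch,
    ModelKind,
    NCDGDDParams,
    NGDParams,
    day_length,
    gdd_accumulate,
    predict,
    predict_batch,
    predict_bbgc_grass,
    predict_bbgc_woody,
    predict_gdd,
    predict_ncd_gdd,
    predict_ngd,
    soil_temperature,
)
from springpheno.types import SiteContext

ENF_GDD = GDDParams(t_base=6.0, gdd_crit=50.0)
DBF_WOODY = BBGCWoodyParams(t_base=-5.0, a=5.505, b=0.085)
GRASSLAND_GRASS = BBGCGrassParams(t_base=-5.0, c=15.0, d=369.0, k=0.05)
DNF_NGD = NGDParams(t_base=5.0, ngd_crit=6)
DBF_NCDGDD = NCDGDDParams(t_chill=0.0, t_base=-5.0, g=-100.0, h=700.0, w=-0.1)


class TestGDD:
    def test_constant_at_base_accumulates_nothing(self):
        met = constant_series(6.0)
        assert np.all(gdd_accumulate(met.tmean_year, 6.0) == 0.0)

    def test_constant_above_base_accumulates_linearly(self):
        met = constant_series(16.0)
        cum = gdd_accumulate(met.tmean_year, 6.0)
        assert np.allclose(cum, 10.0 * np.arange(1, 366))

    def test_accumulation_matches_loop_oracle_elementwise(self, standard_series):
        cum = gdd_accumulate(standard_series.tmean_year, 6.0)
        expected = oracles.naive_gdd_series(list(standard_series.tmean_year), 6.0)
        assert np.allclose(cum, expected)

    def test_constant_sixteen_onset_day_five(self):
        # 10 degree-days per day against a 50 degree-day requirement
        assert predict_gdd(constant_series(16.0), ENF_GDD).bgs_doy == 5

    def test_always_cold_yields_missing(self):
        assert predict_gdd(constant_series(-5.0), ENF_GDD).missing

    def test_standard_fixture_frozen_value(self, standard_series):
        # evergreen-needleleaf calibrated values on the standard sinusoid
        assert predict_gdd(standard_series, ENF_GDD).bgs_doy == 132

    def test_accumulation_start_day_is_respected(self):
        met = constant_series(16.0)
        rec = predict_gdd(met, GDDParams(t_base=6.0, gdd_crit=50.0, t0=100))
        assert rec.bgs_doy == 104  # five 10-degree days starting at DOY 100


class TestSoilTemperature:
    def test_constant_series_unchanged(self):
        x = np.full(50, 3.5)
        assert np.allclose(soil_temperature(x, 11), x)

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=40)
        assert np.allclose(soil_temperature(x, 1), x)

    def test_linear_ramp_lags_five_days(self):
        # trailing 11-day mean of a ramp equals the value 5 days earlier
        ramp = 0.1 * np.arange(100)
        out = soil_temperature(ramp, 11)
        assert np.allclose(out[10:], ramp[10:] - 0.5)

    def test_partial_windows_average_available_days(self, rng):
        x = rng.normal(size=30)
        out = soil_temperature(x, 11)
        expected = oracles.naive_soil(list(x), 11)
        assert np.allclose(out, expected)


class TestDayLength:
    def test_equator_half_day(self):
        for doy in (1, 100, 200, 300):
            assert day_length(0.0, doy) == pytest.approx(43200.0, abs=600)

    def test_polar_night_clamps_to_zero(self):
        assert day_length(80.0, 355) == 0.0

    def test_polar_day_clamps_to_full_day(self):
        assert day_length(80.0, 172) == 86400.0

    def test_matches_independent_solar_geometry(self):
        # frozen from a hand-rolled declination / hour-angle computation
        assert day_length(45.0, 172) == pytest.approx(55532.663, abs=1.0)
        assert day_length(45.0, 172) == pytest.approx(oracles.naive_day_length(45.0, 172))


class TestBBGCWoody:
    def test_zero_coefficients_give_unit_critical_sum(self):
        # exp(0) = 1 degree-day: onset as soon as the photoperiod allows
        params = BBGCWoodyParams(t_base=0.0, a=0.0, b=0.0)
        met = constant_series(20.0)
        rec = predict_bbgc_woody(met, 45.0, params)
        crossing = rec.bgs_doy + params.onset_offset_days
        assert day_length(45.0, crossing) > params.daylength_gate_s
        assert day_length(45.0, crossing - 1) <= params.daylength_gate_s

    def test_onset_is_fifteen_days_before_crossing(self, standard_series):
        # frozen: crossing day 128 on the standard fixture
        rec = predict_bbgc_woody(standard_series, 45.0, DBF_WOODY)
        assert rec.bgs_doy == 128 - 15 == 113

    def test_offset_never_yields_doy_below_one(self):
        params = BBGCWoodyParams(t_base=0.0, a=0.0, b=0.0)
        met = constant_series(25.0)
        rec = predict_bbgc_woody(met, 20.0, params)  # low latitude: gate opens early
        assert rec.bgs_doy >= 1

    def test_cold_year_missing(self):
        assert predict_bbgc_woody(constant_series(-20.0), 45.0, DBF_WOODY).missing


class TestBBGCGrass:
    def test_standard_fixture_frozen_value(self, standard_series):
        rec = predict_bbgc_grass(standard_series, GRASSLAND_GRASS)
        assert rec.bgs_doy == 118

    def test_zero_k_reduces_to_thermal_criterion(self, standard_series):
        no_precip = BBGCGrassParams(t_base=-5.0, c=15.0, d=369.0, k=0.0)
        rec = predict_bbgc_grass(standard_series, no_precip)
        met_dry = sinusoid_series(annual_precip=0.0)
        rec_dry = predict_bbgc_grass(met_dry, no_precip, avg_ann_precip=500.0)
        assert rec.bgs_doy == rec_dry.bgs_doy

    def test_dry_year_with_positive_k_missing(self):
        met = constant_series(20.0, precip_mm=0.0)
        rec = predict_bbgc_grass(met, GRASSLAND_GRASS, avg_ann_precip=400.0)
        assert rec.missing


class TestNGD:
    def test_always_warm_onset_at_critical_count(self):
        assert predict_ngd(constant_series(20.0), NGDParams(t_base=5.0, ngd_crit=6)).bgs_doy == 6

    def test_never_warm_missing(self):
        assert predict_ngd(constant_series(0.0), DNF_NGD).missing

    def test_standard_fixture_frozen_value(self, standard_series):
        assert predict_ngd(standard_series, DNF_NGD).bgs_doy == 114


class TestNCDGDD:
    def test_no_chilling_behaves_as_plain_gdd(self, warm_series):
        # winter never below the chill base: constant requirement g + h
        params = NCDGDDParams(t_chill=-100.0, t_base=-5.0, g=-100.0, h=700.0, w=-0.1)
        rec = predict_ncd_gdd(warm_series, params)
        gdd_equiv = predict_gdd(warm_series, GDDParams(t_base=-5.0, gdd_crit=600.0))
        assert rec.bgs_doy == gdd_equiv.bgs_doy

    def test_mild_winter_frozen_value(self, warm_series):
        assert predict_ncd_gdd(warm_series, DBF_NCDGDD).bgs_doy == 85

    def test_deep_chilling_triggers_immediately(self, standard_series):
        # 56 chilling days by Jan 1 push the requirement below zero
        assert predict_ncd_gdd(standard_series, DBF_NCDGDD).bgs_doy == 1

    def test_series_without_prefix_rejected(self):
        from springpheno.models import ncd_gdd_onset

        with pytest.raises(ValueError, match="prefix"):
            ncd_gdd_onset(np.zeros(365), DBF_NCDGDD)


class TestDispatch:
    def test_gdd_dispatch_identity(self, standard_series):
        ctx = SiteContext(latitude=45.0)
        assert (
            predict(ModelKind.GDD, standard_series, ctx, ENF_GDD).bgs_doy
            == predict_gdd(standard_series, ENF_GDD).bgs_doy
        )

    def test_bbgc_scheme_selects_variant(self, standard_series):
        ctx = SiteContext(latitude=45.0)
        grass = predict(ModelKind.BBGC, standard_series, ctx, GRASSLAND_GRASS, Scheme.GRASS)
        woody = predict(ModelKind.BBGC, standard_series, ctx, DBF_WOODY, Scheme.WOODY)
        assert grass.bgs_doy == 118 and woody.bgs_doy == 113

    def test_mismatched_params_rejected(self, standard_series):
        with pytest.raises(TypeError, match="needs"):
            predict(ModelKind.GDD, standard_series, SiteContext(), DNF_NGD)


@pytest.mark.parametrize("n_series", [200])
def test_all_predictors_match_naive_day_scan(rng, n_series):
    """Vectorized kernels agree exactly with the day-by-day loop oracles."""
    for i in range(n_series):
        met = random_series(rng, pixel_id=f"r{i}")
        t = list(met.tmean)
        ty = list(met.tmean_year)
        t_avg, ann_p = met.t_avg_annual, max(met.annual_precip, 1e-9)
        lat = float(rng.uniform(20.0, 70.0))

        assert predict_gdd(met, ENF_GDD).bgs_doy == oracles.naive_gdd(ty, 6.0, 50.0)
        assert predict_ngd(met, DNF_NGD).bgs_doy == oracles.naive_ngd(ty, 5.0, 6)
        assert predict_bbgc_woody(met, lat, DBF_WOODY).bgs_doy == oracles.naive_bbgc_woody(
            t, lat, -5.0, 5.505, 0.085, t_avg
        )
        assert predict_bbgc_grass(
            met, GRASSLAND_GRASS, avg_ann_precip=ann_p
        ).bgs_doy == oracles.naive_bbgc_grass(
            t, list(met.precip), -5.0, 15.0, 369.0, 0.05, t_avg, ann_p
        )
        assert predict_ncd_gdd(met, DBF_NCDGDD).bgs_doy == oracles.naive_ncd_gdd(
            t, 0.0, -5.0, -100.0, 700.0, -0.1
        )


def test_batch_prediction_equals_per_series(rng):
    series = [random_series(rng, pixel_id=f"b{i}") for i in range(40)]
    batch = MetBatch.from_series(series, latitudes=45.0)
    for kind, params, scheme in [
        (ModelKind.GDD, ENF_GDD, Scheme.WOODY),
        (ModelKind.NGD, DNF_NGD, Scheme.WOODY),
        (ModelKind.NCD_GDD, DBF_NCDGDD, Scheme.WOODY),
        (ModelKind.BBGC, DBF_WOODY, Scheme.WOODY),
        (ModelKind.BBGC, GRASSLAND_GRASS, Scheme.GRASS),
    ]:
        got = predict_batch(kind, params, batch, scheme)
        for j, met in enumerate(series):
            rec = predict(kind, met, SiteContext(latitude=45.0), params, scheme)
            assert (rec.bgs_doy or -1) == got[j]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(delta=st.floats(min_value=0.01, max_value=8.0), mean=st.floats(-3.0, 12.0))
def test_warming_never_delays_one_phase_onset(delta, mean):
    """Adding warmth never postpones GDD/NGD/fixed-threshold onsets."""
    met = sinusoid_series(mean=mean)
    warmer = sinusoid_series(mean=mean)
    warmer.tmean = warmer.tmean + delta
    fixed_crit_woody = BBGCWoodyParams(t_base=-5.0, a=np.log(400.0), b=0.0)
    for fn in (
        lambda m: predict_gdd(m, ENF_GDD).bgs_doy,
        lambda m: predict_ngd(m, DNF_NGD).bgs_doy,
        lambda m: predict_bbgc_woody(m, 45.0, fixed_crit_woody).bgs_doy,
    ):
        base, warm = fn(met), fn(warmer)
        if base is not None:
            assert warm is not None and warm <= base


def test_predicted_doy_always_within_calendar(rng):
    for i in range(50):
        met = random_series(rng, pixel_id=f"c{i}")
        for rec in (
            predict_gdd(met, ENF_GDD),
            predict_ngd(met, DNF_NGD),
            predict_bbgc_woody(met, 45.0, DBF_WOODY),
            predict_ncd_gdd(met, DBF_NCDGDD),
        ):
            assert rec.missing or 1 <= rec.bgs_doy <= 365
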