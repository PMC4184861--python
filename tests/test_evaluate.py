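"""Tests for the observed-vs-predicted comparison metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from springpheno.climate import Biome
from springpheno.evaluate import (
    PairedSeries,
    UndefinedMetricError,
    cumulative_within,
    evaluate_biome,
    interannual_r,
    mean_abs_error,
    pair,
    r_squared,
    r_squared_one_to_one,
    rmse,
)
from springpheno.models import GDDParams, ModelKind
from springpheno.synthetic import GradientSpec, generate_bgs_observations, generate_climate, generate_landscape
from springpheno.types import BGSRecord


def rec(pid, year, doy):
    return BGSRecord(pid, year, doy)


def pairs_from(errors, base=100):
    obs = [float(base + i) for i in range(len(errors))]
    pred = [o + e for o, e in zip(obs, errors)]
    keys = [(f"p{i}", 2001) for i in range(len(errors))]
    return PairedSeries(keys=keys, observed=np.array(obs), predicted=np.array(pred))


class TestPair:
    def test_identical_keys_all_retained(self):
        obs = [rec("a", 2001, 100), rec("b", 2001, 120)]
        pred = [rec("a", 2001, 105), rec("b", 2001, 118)]
        p = pair(obs, pred)
        assert len(p) == 2 and p.n_dropped == 0

    def test_missing_prediction_drops_pair(self):
        obs = [rec("a", 2001, 100), rec("b", 2001, 120)]
        pred = [rec("a", 2001, 105), rec("b", 2001, None)]
        p = pair(obs, pred)
        assert len(p) == 1 and p.n_dropped == 1

    def test_disjoint_keys_rejected(self):
        with pytest.raises(ValueError):
            pair([rec("a", 2001, 100)], [rec("b", 2001, 100)])


class TestErrorMetrics:
    def test_perfect_predictions(self):
        p = pairs_from([0, 0, 0])
        assert rmse(p) == 0.0 and mean_abs_error(p) == 0.0

    def test_symmetric_errors(self):
        p = pairs_from([3, -3])
        assert rmse(p) == 3.0 and mean_abs_error(p) == 3.0

    def test_unequal_errors_hand_computed(self):
        p = pairs_from([0, 6])
        assert rmse(p) == pytest.approx(np.sqrt(18.0))
        assert mean_abs_error(p) == 3.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-60, 60), min_size=1, max_size=40))
    def test_rmse_dominates_mean_abs_error(self, errors):
        p = pairs_from(errors)
        assert rmse(p) >= mean_abs_error(p) - 1e-12
        if len(set(abs(e) for e in errors)) == 1:
            assert rmse(p) == pytest.approx(mean_abs_error(p))

    def test_gaussian_errors_estimate_sigma(self, rng):
        # rmse -> sigma and R_A -> sigma*sqrt(2/pi) over 10,000 pairs
        sigma = 5.0
        errors = rng.normal(0.0, sigma, 10_000)
        obs = rng.integers(80, 160, 10_000).astype(float)
        p = PairedSeries(
            keys=[(f"p{i}", 2001) for i in range(10_000)],
            observed=obs,
            predicted=obs + errors,
        )
        se_rmse = sigma / np.sqrt(2 * len(errors))
        assert rmse(p) == pytest.approx(sigma, abs=3 * se_rmse)
        ra_expected = sigma * np.sqrt(2 / np.pi)
        se_ra = sigma * np.sqrt((1 - 2 / np.pi) / len(errors))
        assert mean_abs_error(p) == pytest.approx(ra_expected, abs=3 * se_ra)


class TestRSquared:
    def test_perfect_agreement(self):
        assert r_squared(pairs_from([0, 0, 0, 0])) == pytest.approx(1.0)

    def test_constant_prediction_rejected(self):
        p = PairedSeries(
            keys=[("a", 1), ("b", 1), ("c", 1)],
            observed=np.array([100.0, 110.0, 120.0]),
            predicted=np.array([105.0, 105.0, 105.0]),
        )
        with pytest.raises(UndefinedMetricError):
            r_squared(p)

    def test_affine_transform_invariance(self):
        obs = np.array([100.0, 110.0, 120.0, 130.0])
        p = PairedSeries(
            keys=[(f"p{i}", 1) for i in range(4)], observed=obs, predicted=2 * obs + 7
        )
        assert r_squared(p) == pytest.approx(1.0)
        # the 1:1-line variant is *not* invariant: it penalizes bias
        assert r_squared_one_to_one(p) < 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UndefinedMetricError):
            r_squared(pairs_from([1, 2]))


class TestInterannualR:
    def _pairs(self, year_effect, noise=None):
        keys, obs, pred = [], [], []
        for y, dy in enumerate(year_effect):
            for i in range(4):
                keys.append((f"p{i}", 2001 + y))
                obs.append(100 + dy + 2 * i)
                pred.append(100 + dy + 2 * i + (0 if noise is None else noise[y]))
        return PairedSeries(keys=keys, observed=np.array(obs, float), predicted=np.array(pred, float))

    def test_identical_series_correlate_perfectly(self):
        p = self._pairs([0, 5, -3, 8])
        out = interannual_r(p, {f"p{i}": Biome.GRASSLAND for i in range(4)})
        assert out[Biome.GRASSLAND] == pytest.approx(1.0)

    def test_constant_year_means_rejected(self):
        p = self._pairs([0, 5, -3], noise=[0, -5, 3])  # prediction year-means all equal
        with pytest.raises(UndefinedMetricError):
            interannual_r(p, {f"p{i}": Biome.GRASSLAND for i in range(4)})

    def test_too_few_years_rejected(self):
        p = self._pairs([0, 5])
        with pytest.raises(UndefinedMetricError):
            interannual_r(p, {f"p{i}": Biome.GRASSLAND for i in range(4)})

    def test_ten_year_fixture_matches_direct_formula(self, rng):
        year_effect = rng.normal(0, 6, 10)
        noise = rng.normal(0, 3, 10)
        p = self._pairs(year_effect, noise=noise)
        out = interannual_r(p, {f"p{i}": Biome.GRASSLAND for i in range(4)})
        obs_means = np.array([100 + dy + 3 for dy in year_effect])
        pred_means = obs_means + noise
        expected = sps.pearsonr(obs_means, pred_means).statistic
        assert out[Biome.GRASSLAND] == pytest.approx(expected)


class TestCumulativeWithin:
    def test_all_zero_errors(self):
        out = cumulative_within(pairs_from([0, 0]), [0, 5, 10])
        assert all(v == 100.0 for v in out.values())

    def test_half_within_ten(self):
        out = cumulative_within(pairs_from([2, 12]), [10])
        assert out[10] == 50.0

    def test_saturates_at_max_error(self):
        errors = [1, -4, 9, -16]
        p = pairs_from(errors)
        out = cumulative_within(p, list(range(0, 30)))
        vals = [out[t] for t in range(0, 30)]
        assert vals == sorted(vals)
        assert out[16] == 100.0 and out[15] < 100.0

    def test_order_invariance(self, rng):
        errors = list(rng.integers(-20, 20, 30))
        a = cumulative_within(pairs_from(errors), [5, 10, 15])
        b = cumulative_within(pairs_from(list(reversed(errors))), [5, 10, 15])
        assert a == b


class TestEvaluateBiome:
    def _setup(self, obs_noise):
        truth = GDDParams(t_base=6.0, gdd_crit=50.0)
        grad = GradientSpec(mean_annual_temp=(0.0, 10.0), temp_noise_sd=1.0)
        sites = generate_landscape(60, {Biome.EVERGREEN_NEEDLELEAF_FOREST: 1.0}, grad, seed=17)
        met = [generate_climate(s, y) for s in sites for y in range(2001, 2006)]
        obs = generate_bgs_observations(ModelKind.GDD, truth, met, obs_noise, seed=17)
        lookup = {(m.pixel_id, m.year): m for m in met}
        return truth, obs, lookup

    def test_self_consistent_data_perfect_metrics(self):
        truth, obs, lookup = self._setup(obs_noise=0.0)
        metrics = evaluate_biome(ModelKind.GDD, truth, obs, lookup)
        assert metrics.rmse == 0.0 and metrics.r_a == 0.0
        assert metrics.r2 == pytest.approx(1.0)

    def test_noise_five_rmse_near_five(self):
        truth, obs, lookup = self._setup(obs_noise=5.0)
        metrics = evaluate_biome(ModelKind.GDD, truth, obs, lookup)
        # integer rounding inflates the 5-day sd only slightly
        assert metrics.rmse == pytest.approx(5.0, rel=0.15)
        assert metrics.r_a == pytest.approx(5.0 * np.sqrt(2 / np.pi), rel=0.15)
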