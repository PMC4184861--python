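"""Comparison metrics between observed and predicted onset dates.

All metrics operate on pixel-year pairs after an inner join on
(pixel, year) that drops any pair with a missing side:

* ``r_squared`` — squared Pearson correlation of predicted vs observed
  (a regression-line R^2); the alternative one-to-one-line definition
  ``1 - SSE/SST`` is reported separately as ``r2_one_to_one``.
* ``rmse`` — root mean square error, days.
* ``mean_abs_error`` — mean absolute error, days (often labelled R_A).
* ``interannual_r`` — Pearson correlation between yearly biome-mean
  observed and predicted onset series.
* ``cumulative_within`` — percentage of pixel-years whose absolute error
  is within each of a list of day thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .climate import Biome, Scheme
from .models import ModelKind, ParamSet, predict
from .types import BGSRecord, DailyMetSeries, SiteContext


class UndefinedMetricError(ValueError):
    """A metric is undefined on the given pairs (e.g. zero variance)."""


@dataclass
class PairedSeries:
    """Matched observed/predicted onsets keyed by (pixel, year)."""

    keys: list[tuple[str, int]]
    observed: np.ndarray
    predicted: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if len(self.observed) != len(self.predicted) or len(self.observed) < 1:
            raise ValueError("paired series need equal, non-zero lengths")

    def __len__(self) -> int:
        return len(self.observed)

    @property
    def errors(self) -> np.ndarray:
        return self.predicted - self.observed


@dataclass
class EvalMetrics:
    r2: float
    r2_one_to_one: float
    rmse: float
    r_a: float
    n: int
    pearson_r_interannual: float | None = None
    cumfreq: dict[int, float] = field(default_factory=dict)


def pair(observations: list[BGSRecord], predictions: list[BGSRecord]) -> PairedSeries:
    """Inner join of observations and predictions on (pixel, year).

    Pairs where either side is missing are dropped and counted in
    ``n_dropped``; an empty join raises.
    """
    obs = {(r.pixel_id, r.year): r.bgs_doy for r in observations}
    pred = {(r.pixel_id, r.year): r.bgs_doy for r in predictions}
    shared = sorted(set(obs) & set(pred))
    keys = [k for k in shared if obs[k] is not None and pred[k] is not None]
    n_dropped = len(set(obs) | set(pred)) - len(keys)
    if not keys:
        raise ValueError("no overlapping non-missing (pixel, year) pairs")
    return PairedSeries(
        keys=keys,
        observed=np.array([obs[k] for k in keys], dtype=float),
        predicted=np.array([pred[k] for k in keys], dtype=float),
        n_dropped=n_dropped,
    )


def rmse(pairs: PairedSeries) -> float:
    """Root mean square error, days."""
    return float(np.sqrt(np.mean(pairs.errors**2)))


def mean_abs_error(pairs: PairedSeries) -> float:
    """Mean absolute error in days (the R_A statistic)."""
    return float(np.mean(np.abs(pairs.errors)))


def r_squared(pairs: PairedSeries) -> float:
    """Squared Pearson correlation of predicted vs observed."""
    if len(pairs) < 3:
        raise UndefinedMetricError("r_squared needs at least 3 pairs")
    if np.ptp(pairs.observed) == 0 or np.ptp(pairs.predicted) == 0:
        raise UndefinedMetricError("r_squared undefined with zero variance")
    r = stats.pearsonr(pairs.observed, pairs.predicted).statistic
    return float(r**2)


def r_squared_one_to_one(pairs: PairedSeries) -> float:
    """``1 - SSE/SST`` about the 1:1 line (can be negative)."""
    sst = float(np.sum((pairs.observed - pairs.observed.mean()) ** 2))
    if sst == 0:
        raise UndefinedMetricError("undefined with zero observed variance")
    return 1.0 - float(np.sum(pairs.errors**2)) / sst


def interannual_r(pairs: PairedSeries, biomes: dict[str, Biome]) -> dict[Biome, float]:
    """Pearson r between yearly biome-mean observed and predicted series.

    Pixel onsets are averaged (unweighted) per year within each biome;
    the correlation runs across years and needs at least 3 of them.
    """
    df = pd.DataFrame(
        {
            "pixel": [k[0] for k in pairs.keys],
            "year": [k[1] for k in pairs.keys],
            "obs": pairs.observed,
            "pred": pairs.predicted,
        }
    )
    df["biome"] = df["pixel"].map(biomes)
    out: dict[Biome, float] = {}
    for biome, grp in df.groupby("biome", observed=True):
        yearly = grp.groupby("year")[["obs", "pred"]].mean()
        if len(yearly) < 3:
            raise UndefinedMetricError(
                f"interannual r for {biome} needs >= 3 years, got {len(yearly)}"
            )
        if yearly["obs"].nunique() == 1 or yearly["pred"].nunique() == 1:
            raise UndefinedMetricError(f"interannual r for {biome} undefined: constant year-means")
        out[biome] = float(stats.pearsonr(yearly["obs"], yearly["pred"]).statistic)
    return out


def cumulative_within(pairs: PairedSeries, thresholds: list[int]) -> dict[int, float]:
    """Percentage of pairs with absolute error within each threshold."""
    abs_err = np.abs(pairs.errors)
    return {int(t): float(100.0 * np.mean(abs_err <= t)) for t in thresholds}


DEFAULT_THRESHOLDS = list(range(1, 31))


def evaluate_biome(
    model_kind: ModelKind | str,
    params: ParamSet,
    validation_records: list[BGSRecord],
    met_lookup: dict[tuple[str, int], DailyMetSeries],
    scheme: Scheme | str = Scheme.WOODY,
    latitudes: dict[str, float] | float = 45.0,
    thresholds: list[int] | None = None,
) -> EvalMetrics:
    """Predict on the validation pixel-years and compute all metrics."""
    preds = []
    for rec in validation_records:
        key = (rec.pixel_id, rec.year)
        if key not in met_lookup:
            raise KeyError(f"no met series for pixel-year {key}")
        lat = latitudes[rec.pixel_id] if isinstance(latitudes, dict) else latitudes
        preds.append(
            predict(model_kind, met_lookup[key], SiteContext(latitude=lat), params, scheme)
        )
    pairs = pair(validation_records, preds)
    try:
        r2 = r_squared(pairs)
    except UndefinedMetricError:
        r2 = float("nan")
    return EvalMetrics(
        r2=r2,
        r2_one_to_one=r_squared_one_to_one(pairs),
        rmse=rmse(pairs),
        r_a=mean_abs_error(pairs),
        n=len(pairs),
        cumfreq=cumulative_within(pairs, thresholds or DEFAULT_THRESHOLDS),
    )
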