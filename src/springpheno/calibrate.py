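"""Per-biome parameter estimation by SSE minimization.

Protocol: pixels are split at random into a calibration half and a
validation half (all years of a pixel stay together).  Within the
calibration half, parameters minimize the error sum of squares (days^2)
between predicted and observed onset over all pixel-years of the biome.

Predicted onset is a piecewise-constant (step) function of the thresholds,
so derivative-based optimizers are ill-posed here.  The estimator is a
deterministic full-factorial coarse grid followed by shrinking-grid local
refinement, with a Nelder-Mead polish on the continuous parameters
(integer day counts are searched over their neighborhood).  The incumbent
objective value never increases across refinement iterations.

Pixel-years where the model predicts no onset are charged a fixed penalty
(default 60 days, squared) so the optimizer cannot win by never
predicting; observation-missing pixel-years are skipped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .climate import Biome, Scheme
from .models import (
    MISSING,
    BBGCGrassParams,
    BBGCWoodyParams,
    GDDParams,
    MetBatch,
    ModelKind,
    NCDGDDParams,
    NGDParams,
    ParamSet,
    predict_batch,
)
from .types import BGSRecord, DailyMetSeries

logger = logging.getLogger(__name__)

#: default bounds bracketing every plausible calibrated value, with margin
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "t_base": (-10.0, 15.0),
    "t_chill": (-10.0, 15.0),
    "gdd_crit": (0.0, 1500.0),
    "ngd_crit": (1, 120),
    "a": (3.0, 8.0),
    "b": (0.0, 0.25),
    "c": (0.0, 30.0),
    "d": (0.0, 600.0),
    "k": (0.0, 1.0),
    "g": (-500.0, 200.0),
    "h": (1.0, 1500.0),
    "w": (-0.5, 0.0),
}

_DEFAULT_GRID: dict[str, int] = {
    "t_base": 26,
    "t_chill": 11,
    "gdd_crit": 51,
    "ngd_crit": 60,
    "a": 11,
    "b": 11,
    "c": 11,
    "d": 13,
    "k": 21,
    "g": 8,
    "h": 8,
    "w": 11,
}

_INTEGER_PARAMS = frozenset({"ngd_crit"})

#: tie-break priority (smaller wins) when several parameter sets reach the
#: same SSE; the day-count / critical-sum parameter is preferred first
_TIE_ORDER: dict[ModelKind, tuple[str, ...]] = {
    ModelKind.GDD: ("gdd_crit", "t_base"),
    ModelKind.NGD: ("ngd_crit", "t_base"),
    ModelKind.BBGC: ("a", "b", "c", "d", "k", "t_base"),
    ModelKind.NCD_GDD: ("h", "g", "w", "t_chill", "t_base"),
}

_PARAM_CLS = {
    (ModelKind.GDD, None): GDDParams,
    (ModelKind.NGD, None): NGDParams,
    (ModelKind.NCD_GDD, None): NCDGDDParams,
    (ModelKind.BBGC, Scheme.WOODY): BBGCWoodyParams,
    (ModelKind.BBGC, Scheme.GRASS): BBGCGrassParams,
}


def make_params(model_kind: ModelKind | str, values: dict, scheme: Scheme | str = Scheme.WOODY) -> ParamSet:
    """Build a model parameter set from a flat name -> value mapping."""
    kind = ModelKind(model_kind)
    cls = _PARAM_CLS[(kind, Scheme(scheme) if kind is ModelKind.BBGC else None)]
    vals = dict(values)
    if "ngd_crit" in vals:
        vals["ngd_crit"] = int(round(vals["ngd_crit"]))
    return cls(**vals)


@dataclass(frozen=True)
class FreeParam:
    """One calibrated parameter: bounds and coarse-grid resolution."""

    name: str
    lo: float
    hi: float
    n_grid: int = 11
    integer: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi) and self.lo <= self.hi):
            raise ValueError(f"bounds for {self.name} must be finite with lo <= hi")
        if self.n_grid < 1:
            raise ValueError("n_grid must be >= 1")

    def grid(self) -> np.ndarray:
        if self.integer:
            vals = np.unique(np.round(np.linspace(self.lo, self.hi, self.n_grid)).astype(int))
            return vals
        return np.linspace(self.lo, self.hi, self.n_grid)


def free_param(name: str, n_grid: int | None = None, bounds: tuple[float, float] | None = None) -> FreeParam:
    """A :class:`FreeParam` with the package's default bounds and grid."""
    lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS[name]
    return FreeParam(
        name=name,
        lo=lo,
        hi=hi,
        n_grid=n_grid if n_grid is not None else _DEFAULT_GRID[name],
        integer=name in _INTEGER_PARAMS,
    )


@dataclass
class CalibrationSpec:
    """What to calibrate: model family, free/fixed parameters, penalty."""

    model_kind: ModelKind
    biome: Biome | None = None
    free_params: list[FreeParam] = field(default_factory=list)
    fixed_params: dict[str, float] = field(default_factory=dict)
    penalty_days: float = 60.0
    seed: int = 0
    scheme: Scheme = Scheme.WOODY
    n_refine_rounds: int = 6
    polish: bool = True

    def __post_init__(self) -> None:
        self.model_kind = ModelKind(self.model_kind)
        self.scheme = Scheme(self.scheme)
        if self.penalty_days <= 0:
            raise ValueError("penalty_days must be > 0")
        if not self.free_params:
            raise ValueError("at least one free parameter is required")


@dataclass
class CalibrationResult:
    params: ParamSet
    sse: float
    n_train: int
    n_missing_pred: int
    converged: bool
    param_values: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data assembly and objective
# ---------------------------------------------------------------------------


@dataclass
class TrainingData:
    """Observed onsets stacked against their driving met series."""

    batch: MetBatch
    observed: np.ndarray  # days, one per row

    @classmethod
    def from_records(
        cls,
        records: list[BGSRecord],
        met_lookup: dict[tuple[str, int], DailyMetSeries],
        latitudes: dict[str, float] | float = 45.0,
    ) -> "TrainingData":
        kept = [r for r in records if not r.missing]
        if not kept:
            raise ValueError("no non-missing observations to calibrate on")
        series = []
        for r in kept:
            key = (r.pixel_id, r.year)
            if key not in met_lookup:
                raise KeyError(f"no met series for pixel-year {key}")
            series.append(met_lookup[key])
        batch = MetBatch.from_series(series, latitudes)
        return cls(batch=batch, observed=np.array([float(r.bgs_doy) for r in kept]))

    def __len__(self) -> int:
        return len(self.observed)


def _sse(
    model_kind: ModelKind,
    params: ParamSet,
    data: TrainingData,
    penalty_days: float,
    scheme: Scheme,
) -> tuple[float, int]:
    pred = predict_batch(model_kind, params, data.batch, scheme)
    miss = pred == MISSING
    err = pred[~miss] - data.observed[~miss]
    sse = float(np.sum(err.astype(float) ** 2) + miss.sum() * penalty_days**2)
    return sse, int(miss.sum())


def sse_objective(
    model_kind: ModelKind | str,
    params: ParamSet,
    train_records: list[BGSRecord],
    met_lookup: dict[tuple[str, int], DailyMetSeries],
    penalty_days: float = 60.0,
    scheme: Scheme | str = Scheme.WOODY,
    latitudes: dict[str, float] | float = 45.0,
) -> float:
    """Error sum of squares (days^2) of a parameter set on training records.

    Observation-missing records are skipped; prediction-missing records
    contribute ``penalty_days**2`` each.
    """
    data = TrainingData.from_records(train_records, met_lookup, latitudes)
    sse, _ = _sse(ModelKind(model_kind), params, data, penalty_days, Scheme(scheme))
    return sse


# ---------------------------------------------------------------------------
# split and search
# ---------------------------------------------------------------------------


def split_half(sites: list, seed: int = 0) -> tuple[list, list]:
    """Random disjoint half split by pixel; ``|train| = ceil(n/2)``."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    order = rng.permutation(len(sites))
    n_train = math.ceil(len(sites) / 2)
    train = [sites[i] for i in sorted(order[:n_train])]
    valid = [sites[i] for i in sorted(order[n_train:])]
    return train, valid


class _Search:
    """Incumbent-tracking evaluator with deterministic tie-breaking."""

    def __init__(self, spec: CalibrationSpec, data: TrainingData):
        self.spec = spec
        self.data = data
        self.names = [p.name for p in spec.free_params]
        tie = _TIE_ORDER.get(spec.model_kind, ())
        self.tie_order = [n for n in tie if n in self.names] + [
            n for n in self.names if n not in tie
        ]
        self.best_values: dict[str, float] | None = None
        self.best_sse = math.inf
        self.best_missing = 0
        self.n_eval = 0
        self.history: list[tuple[float, tuple, dict[str, float]]] = []

    def params_for(self, values: dict[str, float]) -> ParamSet:
        return make_params(self.spec.model_kind, {**self.spec.fixed_params, **values}, self.spec.scheme)

    def evaluate(self, values: dict[str, float], record: bool = False) -> float:
        sse, n_miss = _sse(
            self.spec.model_kind,
            self.params_for(values),
            self.data,
            self.spec.penalty_days,
            self.spec.scheme,
        )
        self.n_eval += 1
        if record:
            self.history.append((sse, self._tie_key(values), dict(values)))
        if self._better(sse, values):
            self.best_sse = sse
            self.best_values = dict(values)
            self.best_missing = n_miss
        return sse

    def _tie_key(self, values: dict[str, float]) -> tuple:
        return tuple(values[n] for n in self.tie_order)

    def _better(self, sse: float, values: dict[str, float]) -> bool:
        if sse < self.best_sse:
            return True
        if sse > self.best_sse or self.best_values is None:
            return sse < self.best_sse
        return self._tie_key(values) < self._tie_key(self.best_values)

    def sweep(
        self, grids: dict[str, np.ndarray], record: bool = False
    ) -> tuple[float, dict[str, float]]:
        """Evaluate a full factorial; return the sweep-local optimum."""
        axes = [grids[n] for n in self.names]
        local_sse, local_key, local_vals = math.inf, (), None
        for combo in itertools.product(*axes):
            values = dict(zip(self.names, (float(v) for v in combo)))
            sse = self.evaluate(values, record=record)
            key = self._tie_key(values)
            if sse < local_sse or (sse == local_sse and key < local_key):
                local_sse, local_key, local_vals = sse, key, values
        return local_sse, local_vals

    def top_starts(self, k: int, min_sep: dict[str, float]) -> list[dict[str, float]]:
        """Diverse low-SSE points from the recorded coarse sweep."""
        ranked = sorted(self.history, key=lambda t: (t[0], t[1]))
        starts: list[dict[str, float]] = []
        for _, _, vals in ranked:
            if any(
                all(abs(vals[n] - s[n]) < min_sep[n] for n in self.names) for s in starts
            ):
                continue
            starts.append(vals)
            if len(starts) >= k:
                break
        return starts


def calibrate(
    spec: CalibrationSpec,
    train_records: list[BGSRecord],
    met_lookup: dict[tuple[str, int], DailyMetSeries],
    latitudes: dict[str, float] | float = 45.0,
) -> CalibrationResult:
    """Fit the free parameters by coarse grid search plus local refinement.

    Deterministic given the spec: the coarse grid is scanned in a fixed
    order, ties resolve to the smallest critical-sum/day-count value, each
    shrinking-grid round only ever improves the incumbent, and the final
    Nelder-Mead polish is accepted only if it strictly lowers the SSE.
    """
    data = TrainingData.from_records(train_records, met_lookup, latitudes)
    search = _Search(spec, data)
    bounds = {p.name: (p.lo, p.hi) for p in spec.free_params}
    integer = {p.name: p.integer for p in spec.free_params}

    # stage 1: coarse full-factorial grid, recorded so diverse restart
    # points can be drawn from it
    grids = {p.name: p.grid() for p in spec.free_params}
    coarse_steps = {
        p.name: float(p.grid()[1] - p.grid()[0]) if len(p.grid()) > 1 else max(p.hi - p.lo, 1.0)
        for p in spec.free_params
    }
    search.sweep(grids, record=True)
    logger.info(
        "coarse grid: model=%s n_eval=%d sse=%.3f", spec.model_kind.value, search.n_eval, search.best_sse
    )

    def refine_from(start: dict[str, float]) -> None:
        center = dict(start)
        center_sse = math.inf
        steps = dict(coarse_steps)
        for _ in range(spec.n_refine_rounds):
            local = {}
            for name in search.names:
                lo_b, hi_b = bounds[name]
                if integer[name]:
                    span = max(2, int(steps[name]))
                    lo = max(lo_b, round(center[name]) - span)
                    hi = min(hi_b, round(center[name]) + span)
                    local[name] = np.arange(int(lo), int(hi) + 1)
                    steps[name] = max(1.0, steps[name] / 2.0)
                else:
                    half = 1.5 * steps[name]
                    lo = max(lo_b, center[name] - half)
                    hi = min(hi_b, center[name] + half)
                    local[name] = np.linspace(lo, hi, 5)
                    steps[name] = (hi - lo) / 4.0 if hi > lo else steps[name] / 4.0
            sse, vals = search.sweep(local)
            if sse < center_sse or vals != center:
                center_sse, center = sse, vals

    # stage 2: shrinking-grid refinement from several diverse coarse
    # optima (the SSE surface of threshold models has curved, stepped
    # valleys; a single incumbent track can stall on a shelf)
    starts = search.top_starts(k=5, min_sep={n: 1.5 * coarse_steps[n] for n in search.names})
    for start in starts:
        refine_from(start)

    # stage 3: cyclic 1-D line searches around the incumbent (robust on
    # piecewise-constant objectives where simplex moves stall)
    fine_steps = {n: max(coarse_steps[n] / 2.0**spec.n_refine_rounds, 1e-6) for n in search.names}
    n_local = 17 if len(search.names) <= 2 else 9
    stable = False
    for _ in range(2):
        # cyclic 1-D line searches around the incumbent
        for _ in range(3):
            before = (search.best_sse, dict(search.best_values))
            for name in search.names:
                center = search.best_values[name]
                lo_b, hi_b = bounds[name]
                if integer[name]:
                    lo = max(lo_b, round(center) - 3)
                    hi = min(hi_b, round(center) + 3)
                    axis = np.arange(int(lo), int(hi) + 1)
                else:
                    half = 8.0 * fine_steps[name]
                    axis = np.linspace(max(lo_b, center - half), min(hi_b, center + half), 17)
                others = {n: np.array([search.best_values[n]]) for n in search.names if n != name}
                search.sweep({name: axis, **others})
            if (search.best_sse, search.best_values) == before:
                stable = True
        # small full-factorial sweeps around the incumbent; 1-D moves
        # alone can miss a jointly-feasible pocket when parameters trade
        # off against each other
        for shrink in (8.0, 4.0, 2.0, 1.0, 0.5, 0.25):
            local = {}
            for name in search.names:
                lo_b, hi_b = bounds[name]
                center = search.best_values[name]
                if integer[name]:
                    local[name] = np.arange(
                        int(max(lo_b, round(center) - 1)), int(min(hi_b, round(center) + 1)) + 1
                    )
                else:
                    half = shrink * 4.0 * fine_steps[name]
                    local[name] = np.linspace(
                        max(lo_b, center - half), min(hi_b, center + half), n_local
                    )
            search.sweep(local)
        if search.best_sse == 0.0:
            break

    # stage 4: Nelder-Mead polish on the continuous parameters
    cont = [n for n in search.names if not integer[n]]
    if spec.polish and cont:
        fixed_ints = {n: search.best_values[n] for n in search.names if integer[n]}
        x0 = np.array([search.best_values[n] for n in cont])

        def fun(x: np.ndarray) -> float:
            vals = dict(fixed_ints)
            for n, v in zip(cont, x):
                lo, hi = bounds[n]
                vals[n] = float(np.clip(v, lo, hi))
            return search.evaluate(vals)

        minimize(
            fun,
            x0,
            method="Nelder-Mead",
            options={"maxfev": 400, "xatol": 1e-4, "fatol": 1e-8},
        )

    values = dict(search.best_values)
    logger.info(
        "calibrated: model=%s sse=%.3f n_eval=%d values=%s",
        spec.model_kind.value,
        search.best_sse,
        search.n_eval,
        {k: round(v, 5) for k, v in values.items()},
    )
    return CalibrationResult(
        params=search.params_for(values),
        sse=search.best_sse,
        n_train=len(data),
        n_missing_pred=search.best_missing,
        converged=stable or search.best_sse == 0.0,
        param_values=values,
    )
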