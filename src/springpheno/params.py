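"""Parameter-set loading: bundled calibrated values and user YAML/JSON files.

The bundled ``default_params.yaml`` holds a calibrated Northern Hemisphere
parameter set, one entry per vegetation class and model family.  User
files use the same layout: ``biome -> model -> {name: value}``.

Original (uncalibrated) host-model values kept for reference comparisons:
the IBIS vegetation model drives its GDD onset with base 0 degC and a
critical sum of 100 degree-days for winter-deciduous forest, and base
5 degC / 150 degree-days for grassland and shrub.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .climate import Biome, Scheme
from .models import (
    BBGCGrassParams,
    BBGCWoodyParams,
    GDDParams,
    ModelKind,
    NCDGDDParams,
    NGDParams,
    ParamSet,
)

#: IBIS host-model GDD defaults (uncalibrated), used as the comparison baseline
IBIS_GDD_DEFAULTS = {
    "winter_deciduous_forest": GDDParams(t_base=0.0, gdd_crit=100.0),
    "grassland_shrub": GDDParams(t_base=5.0, gdd_crit=150.0),
}


def _build(model: ModelKind, raw: dict, scheme: Scheme) -> ParamSet:
    if model is ModelKind.GDD:
        return GDDParams(t_base=raw["t_base"], gdd_crit=raw["gdd_crit"], t0=raw.get("t0", 1))
    if model is ModelKind.NGD:
        return NGDParams(t_base=raw["t_base"], ngd_crit=raw["ngd_crit"], t0=raw.get("t0", 1))
    if model is ModelKind.NCD_GDD:
        return NCDGDDParams(
            t_chill=raw["t_chill"], t_base=raw["t_base"], g=raw["g"], h=raw["h"], w=raw["w"]
        )
    if scheme is Scheme.GRASS:
        return BBGCGrassParams(t_base=raw["t_base"], c=raw["c"], d=raw["d"], k=raw["k"])
    return BBGCWoodyParams(t_base=raw["t_base"], a=raw["a"], b=raw["b"])


def load_param_table(path: str | Path | None = None) -> dict[Biome, dict[ModelKind, ParamSet]]:
    """Load a full biome -> model -> parameters table.

    With no ``path``, the bundled calibrated set is returned.  Files may be
    YAML or JSON.
    """
    if path is None:
        text = resources.files("springpheno.data").joinpath("default_params.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    table: dict[Biome, dict[ModelKind, ParamSet]] = {}
    for biome_name, models in raw.items():
        biome = Biome(biome_name)
        table[biome] = {
            ModelKind(m): _build(ModelKind(m), p, biome.phenology_scheme)
            for m, p in models.items()
        }
    return table


def default_params(biome: Biome, model: ModelKind | str) -> ParamSet:
    """Bundled calibrated parameters for one biome and model family."""
    return load_param_table()[biome][ModelKind(model)]


def dump_params(params: ParamSet) -> dict:
    """Plain-dict form of a parameter set (for YAML/JSON output)."""
    from dataclasses import asdict

    return asdict(params)
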