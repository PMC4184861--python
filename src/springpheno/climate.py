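"""Annual climate statistics and cool/warm biome subdivision.

Four IGBP vegetation types span such a wide latitude range that one
parameter set cannot serve them all: mixed forest, closed shrub, open
shrub, and woody savanna.  Each is split into a cool and a warm class from
three annual temperature statistics — the annual mean of daily temperature
(``T_mean``), the minimum daily temperature of the year (``T_c``), and the
annual range (``delta_T = T_w - T_c``).  The criteria:

* mixed forest, closed shrub, woody savanna: cool iff ``T_c < 0`` degC;
* open shrub: cool iff ``delta_T > 20`` degC or ``T_c < 5`` degC.

Boundary values resolve to the warm class (the cool criteria are strict
inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .types import DailyMetSeries


class Scheme(str, Enum):
    """Which onset rule family a biome uses under the Biome-BGC model."""

    WOODY = "woody"
    GRASS = "grass"


class Biome(str, Enum):
    """The 14 calibrated vegetation classes."""

    EVERGREEN_NEEDLELEAF_FOREST = "evergreen_needleleaf_forest"
    DECIDUOUS_NEEDLELEAF_FOREST = "deciduous_needleleaf_forest"
    DECIDUOUS_BROADLEAF_FOREST = "deciduous_broadleaf_forest"
    COOL_MIXED_FOREST = "cool_mixed_forest"
    WARM_MIXED_FOREST = "warm_mixed_forest"
    COOL_CLOSED_SHRUB = "cool_closed_shrub"
    WARM_CLOSED_SHRUB = "warm_closed_shrub"
    COOL_OPEN_SHRUB = "cool_open_shrub"
    WARM_OPEN_SHRUB = "warm_open_shrub"
    COOL_WOODY_SAVANNA = "cool_woody_savanna"
    WARM_WOODY_SAVANNA = "warm_woody_savanna"
    SAVANNA = "savanna"
    GRASSLAND = "grassland"
    PERMANENT_WETLAND = "permanent_wetland"

    @property
    def phenology_scheme(self) -> Scheme:
        # Grass-type onset (temperature + precipitation criterion) applies
        # to the grass and savanna classes; everything else, including
        # permanent wetland, follows the woody rule.
        if self in _GRASS_BIOMES:
            return Scheme.GRASS
        return Scheme.WOODY


_GRASS_BIOMES = frozenset(
    {
        Biome.COOL_WOODY_SAVANNA,
        Biome.WARM_WOODY_SAVANNA,
        Biome.SAVANNA,
        Biome.GRASSLAND,
    }
)

#: the four base types subject to cool/warm subdivision
SUBDIVIDED_TYPES = ("mixed_forest", "closed_shrub", "open_shrub", "woody_savanna")


@dataclass(frozen=True)
class ClimateStats:
    """Annual temperature statistics used by the subdivision criteria."""

    t_mean: float
    t_c: float
    t_w: float

    def __post_init__(self) -> None:
        if not self.t_c <= self.t_mean <= self.t_w:
            raise ValueError(
                f"require T_c <= T_mean <= T_w, got {self.t_c}, {self.t_mean}, {self.t_w}"
            )

    @property
    def delta_t(self) -> float:
        """Annual temperature range ``T_w - T_c``, degC."""
        return self.t_w - self.t_c


def compute_climate_stats(years: list[DailyMetSeries] | DailyMetSeries) -> ClimateStats:
    """Annual temperature statistics, averaged over the supplied years.

    Each statistic is computed over the Jan 1 .. Dec 31 window of each
    record, then averaged across records.  Adding a constant to all
    temperatures shifts ``T_mean``, ``T_c`` and ``T_w`` by that constant and
    leaves ``delta_T`` unchanged.
    """
    if isinstance(years, DailyMetSeries):
        years = [years]
    if not years:
        raise ValueError("at least one full year of daily temperature is required")
    t_mean = sum(float(s.tmean_year.mean()) for s in years) / len(years)
    t_c = sum(float(s.tmean_year.min()) for s in years) / len(years)
    t_w = sum(float(s.tmean_year.max()) for s in years) / len(years)
    return ClimateStats(t_mean=t_mean, t_c=t_c, t_w=t_w)


def subdivide(base_type: str, stats: ClimateStats) -> Biome:
    """Resolve a wide-latitude base type to its cool or warm class.

    Raises
    ------
    ValueError
        If ``base_type`` is not one of the four subdivided types; such
        types are used unchanged and must not be passed here.
    """
    if base_type not in SUBDIVIDED_TYPES:
        raise ValueError(
            f"{base_type!r} is not subdivided by climate; use the biome unchanged"
        )
    if base_type == "open_shrub":
        cool = stats.delta_t > 20.0 or stats.t_c < 5.0
    else:
        cool = stats.t_c < 0.0
    prefix = "cool" if cool else "warm"
    return Biome(f"{prefix}_{base_type}")
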