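"""Single-layer tipping-bucket water balance.

Provides the two quantities the rest of the model depends on: the
transpiration reduction factor TRANRF (actual / potential transpiration,
in [0, 1]) and the drought-dormancy trigger.  TRANRF declines linearly
from 1 at a critical water content — set by the crop transpiration
coefficient as a fraction of the plant-available range — to 0 at wilting
point.  The Monod-type water limitation factor

    WLIMIT = TRANRF / (K_WATER + TRANRF)

scales fertilizer nutrient release under drought.

The bucket deepens with root growth; soil newly reached by roots enters at
a configured subsoil moisture, and that inflow is reported so the daily
water balance closes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import SoilWaterParameters
from .weather import WeatherDay


@dataclass
class SoilWaterState:
    depth: float     # rooted depth, m
    water: float     # water stored in the rooted zone, mm

    @property
    def theta(self) -> float:
        """Mean volumetric water content of the rooted zone."""
        return self.water / (self.depth * 1000.0)


@dataclass(frozen=True)
class WaterStress:
    TRANRF: float    # transpiration reduction factor in [0, 1]
    dormancy: int    # 1 while the crop is drought-dormant

    def __post_init__(self):
        if not 0.0 <= self.TRANRF <= 1.0:
            raise ValueError(f"TRANRF out of [0, 1]: {self.TRANRF}")


@dataclass(frozen=True)
class WaterFluxes:
    """Daily water-balance terms (mm d-1), for closure checks and output."""

    rain: float
    drainage: float
    evaporation: float
    transpiration: float
    root_zone_inflow: float   # water gained as roots deepen into moist subsoil


def initialize_soil_water(params: SoilWaterParameters) -> SoilWaterState:
    depth = params.initial_rooting_depth
    return SoilWaterState(depth=depth, water=params.initial_theta * depth * 1000.0)


def transpiration_reduction(theta: float, params: SoilWaterParameters) -> float:
    """Linear ramp: 0 at wilting point, 1 at the critical water content."""
    theta_crit = params.WP + params.crit_fraction * (params.FC - params.WP)
    if theta >= theta_crit:
        return 1.0
    if theta <= params.WP:
        return 0.0
    return (theta - params.WP) / (theta_crit - params.WP)


def wlimit(tranrf: float, k_water: float) -> float:
    """Monod water limitation of fertilizer release: TRANRF/(K_WATER+TRANRF)."""
    if not 0.0 <= tranrf <= 1.0:
        raise ValueError(f"TRANRF out of [0, 1]: {tranrf}")
    if k_water <= 0:
        raise ValueError("K_WATER must be > 0")
    return tranrf / (k_water + tranrf)


def step_water_balance(state: SoilWaterState, day: WeatherDay, lai: float,
                       params: SoilWaterParameters, k: float,
                       dormancy: int = 0, delt: float = 1.0,
                       ) -> tuple[SoilWaterState, WaterStress, WaterFluxes]:
    """Advance the bucket one day and return the new state plus stress terms.

    Order within the day: root deepening (inflow at subsoil moisture),
    infiltration of rain with same-day drainage of any excess above field
    capacity, then transpiration (limited by the TRANRF ramp) and soil
    evaporation (limited by the water held above air-dry).
    """
    depth = state.depth
    water = state.water

    new_depth = min(depth + params.root_growth_rate * delt, params.max_rooting_depth)
    inflow = (new_depth - depth) * 1000.0 * params.subsoil_theta
    depth = new_depth
    water += inflow

    capacity = params.FC * depth * 1000.0
    water += day.rain * delt
    drainage = max(0.0, water - capacity)
    water -= drainage

    # reference ET from global radiation; canopy splits it by Beer's law
    et0 = params.et_coefficient * day.srad
    cover = 1.0 - math.exp(-k * lai)
    pot_transpiration = et0 * cover
    pot_evaporation = et0 * (1.0 - cover)

    theta = water / (depth * 1000.0)
    tranrf = transpiration_reduction(theta, params)
    transpiration = min(pot_transpiration * tranrf,
                        max(0.0, water - params.WP * depth * 1000.0) / delt)
    water -= transpiration * delt

    evaporation = min(pot_evaporation,
                      max(0.0, water - params.AD * depth * 1000.0) / delt)
    water -= evaporation * delt

    new_state = SoilWaterState(depth=depth, water=water)

    # dormancy: arms when the root zone is nearly at wilting point and the
    # canopy has collapsed; releases when soil water recovers
    rel = ((new_state.theta - params.WP) / (params.FC - params.WP)
           if params.FC > params.WP else 1.0)
    if dormancy:
        new_dormancy = 0 if rel > params.recovery_water_fraction else 1
    else:
        new_dormancy = 1 if (rel < params.dormancy_water_fraction
                             and lai < 1e-9 + _lai_threshold(params)) else 0

    stress = WaterStress(TRANRF=tranrf, dormancy=new_dormancy)
    fluxes = WaterFluxes(rain=day.rain, drainage=drainage, evaporation=evaporation,
                         transpiration=transpiration, root_zone_inflow=inflow)
    return new_state, stress, fluxes


def _lai_threshold(params: SoilWaterParameters) -> float:
    # kept separate so the crop-side dormancy LAI threshold can be injected
    return getattr(params, "dormancy_lai", 0.75)
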