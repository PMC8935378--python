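"""Daily integration loop.

One simulated day executes a fixed order of operations, all rates taken
from start-of-day states and integrated with an explicit Euler step of one
day: weather -> thermal time -> water balance (TRANRF, WLIMIT, dormancy) ->
fertilizer events -> soil nutrient release -> plant Min/Max/Opt from the
concentration lookups -> nutrient-equivalent demand and supply -> uptake
and allocation -> nutrition indices and NPKI (with the thermal-time gate)
-> growth rate -> partitioning -> leaf death with nutrient rerouting ->
translocation -> state update.  Identical inputs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import pandas as pd

from . import crop_growth, crop_npk, soil_npk, soil_water, weather as weather_mod
from .config import ModelParameters, NUTRIENTS, ORGANS, Scenario


class EngineError(RuntimeError):
    """Raised when the integration produces a non-finite or negative state."""


@dataclass
class CropState:
    weights: dict = field(default_factory=lambda: {o: 0.0 for o in ORGANS})
    dead_leaf: float = 0.0
    amounts: dict = field(default_factory=lambda: {(o, n): 0.0
                                                   for o in ORGANS for n in NUTRIENTS})
    tsum: float = 0.0
    sprouted: bool = False
    dormancy: int = 0
    cutting_input: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})


def simulate(params: ModelParameters, scenario: Scenario,
             weather=None, nutrient_limitation: bool = True) -> pd.DataFrame:
    """Run one season and return one tidy row per day.

    ``weather`` is a sequence of :class:`~cassava_npk.weather.WeatherDay`
    covering at least the scenario's season length; if omitted it is read
    from ``scenario.weather_path``.  With ``nutrient_limitation=False`` the
    whole nutrient module is bypassed (NPKI held at 1) and the run is the
    water-limited baseline.
    """
    params.validate()
    if weather is None:
        if scenario.weather_path is None:
            raise ValueError("no weather given and scenario has no weather_path")
        weather = weather_mod.read_weather(scenario.weather_path)
    sl = scenario.season_length
    if len(weather) < sl:
        raise ValueError(f"weather covers {len(weather)} days < season length {sl}")
    override = scenario.tranrf_override
    if override is not None and len(override) < sl:
        raise ValueError("tranrf_override shorter than the season")

    crop = params.crop
    soil = soil_npk.initialize_soil(scenario.supply, scenario)
    water = soil_water.initialize_soil_water(params.soil_water)
    state = CropState()
    schedule = {e.day: e for e in scenario.schedule}
    delt = params.DELT

    records = []
    for day_index in range(sl):
        wd = weather[day_index]
        dtsum = weather_mod.daily_thermal_increment(wd, crop.base_temperature, delt)

        # sprouting: the cutting's reserves build the first organs, split by
        # the assimilate partitioning fractions at the sprouting thermal time
        if not state.sprouted and state.tsum >= crop.TSUM_sprouting:
            fracs = crop_growth.base_partitioning(state.tsum, crop.partitioning_table)
            for o in ORGANS:
                state.weights[o] = crop.initial_biomass * fracs[o]
            if nutrient_limitation:
                for n in NUTRIENTS:
                    content = crop.initial_biomass * crop.cutting_conc[n]
                    state.cutting_input[n] = content
                    for o in ORGANS:
                        state.amounts[(o, n)] = content * fracs[o]
            state.sprouted = True

        lai = crop.SLA * state.weights["leaf"]

        # --- water balance ---
        if override is not None:
            tranrf = float(override[day_index])
            stress = soil_water.WaterStress(TRANRF=tranrf, dormancy=0)
            fluxes = soil_water.WaterFluxes(wd.rain, 0.0, 0.0, 0.0, 0.0)
        else:
            water, stress, fluxes = soil_water.step_water_balance(
                water, wd, lai, params.soil_water, crop.k,
                dormancy=state.dormancy, delt=delt)
            tranrf = stress.TRANRF
        dormancy_ended = state.dormancy == 1 and stress.dormancy == 0
        state.dormancy = stress.dormancy
        wlim = soil_water.wlimit(tranrf, params.K_WATER)

        # --- fertilizer and soil nutrient release ---
        event = schedule.get(day_index)
        if event is not None:
            soil_npk.apply_fertilizer(soil, event)
        soil_npk.step_soil_nutrients(soil, params, sl, wlim)

        # --- crop nutrient demand, uptake, indices ---
        bounds = crop_npk.organ_concentration_bounds(params.tables, state.tsum)
        if nutrient_limitation and state.sprouted:
            amounts = crop_npk.plant_amounts(
                state.weights, state.amounts, params.tables, state.tsum,
                params.FR_MAX, bounds=bounds)
            rates = crop_npk.uptake_rates(amounts, soil.A, params)
            soil_npk.withdraw_uptake(soil, rates.UP, delt)
            alloc = crop_npk.allocate_uptake(rates.UP, state.weights)
            for key, inc in alloc.items():
                state.amounts[key] += inc * delt
            act = {n: sum(state.amounts[(o, n)] for o in ORGANS) for n in NUTRIENTS}
            amounts = crop_npk.PlantAmounts(Act=act, Min=amounts.Min,
                                            Max=amounts.Max, Opt=amounts.Opt)
            indices = crop_npk.nutrition_indices(amounts, state.tsum, params)
        else:
            zero = {n: 0.0 for n in NUTRIENTS}
            amounts = crop_npk.PlantAmounts(Act=dict(zero), Min=dict(zero),
                                            Max=dict(zero), Opt=dict(zero))
            rates = crop_npk.UptakeRates(NED=0.0, NES=0.0, NEUP=0.0, UP=dict(zero))
            indices = crop_npk.NutrientIndices(NI={n: 1.0 for n in NUTRIENTS}, NPKI=1.0)
        npki = indices.NPKI

        # --- growth, partitioning, senescence ---
        par_int = weather_mod.intercepted_par(wd, lai, crop.k)
        dw = crop_growth.growth_rate(crop.RUE, par_int, tranrf, npki, state.dormancy)
        increments = crop_growth.partition_growth(dw, state.tsum, tranrf, npki, crop)
        death = crop_growth.leaf_death_rate(state.weights["leaf"], npki, state.tsum,
                                            params.RDRNS, crop, delt)
        w_leaf = state.weights["leaf"]
        dying_fraction = min(1.0, death * delt / w_leaf) if w_leaf > 0.0 else 0.0

        if nutrient_limitation and state.sprouted:
            leaf_amounts = {n: state.amounts[("leaf", n)] for n in NUTRIENTS}
            reroute = crop_npk.reroute_dead_leaf_nutrients(dying_fraction, leaf_amounts)
            act_now = {n: sum(state.amounts[(o, n)] for o in ORGANS) for n in NUTRIENTS}
            redis = crop_npk.redistribution_rates(
                state.weights, state.amounts, act_now, params.tables,
                state.tsum, params.TC_NPK_T, bounds=bounds)
        else:
            reroute = redis = None

        # --- state update (Euler) ---
        for o in ORGANS:
            state.weights[o] += increments[o] * delt
        state.weights["leaf"] -= death * delt
        state.dead_leaf += death * delt
        if reroute is not None:
            for key, transfer in reroute.items():
                state.amounts[key] += transfer
            for key, rate in redis.items():
                state.amounts[key] += rate * delt
                if state.amounts[key] < 0.0:   # translocation round-off guard
                    state.amounts[key] = 0.0 if state.amounts[key] > -1e-9 else state.amounts[key]

        if dormancy_ended and state.weights["storage"] > 0.0:
            storage_amounts = {n: state.amounts[("storage", n)] for n in NUTRIENTS}
            decrement, moved = crop_growth.dormancy_remobilization(
                state.weights["storage"], storage_amounts, crop)
            state.weights["storage"] -= decrement
            state.weights["leaf"] += decrement
            for n in NUTRIENTS:
                state.amounts[("storage", n)] -= moved[n]
                state.amounts[("leaf", n)] += moved[n]

        state.tsum += dtsum

        _check_state(state, soil, day_index)

        row = {
            "day": day_index,
            "date": wd.date,
            "TSUM": state.tsum,
            "TRANRF": tranrf,
            "WLIMIT": wlim,
            "dormancy": state.dormancy,
            "PARint": par_int,
            "dW": dw,
            "W_leaf": state.weights["leaf"],
            "W_stem": state.weights["stem"],
            "W_storage": state.weights["storage"],
            "W_root": state.weights["root"],
            "W_dead_leaf": state.dead_leaf,
            "LAI": crop.SLA * state.weights["leaf"],
            "NPKI": npki,
            "root_depth": water.depth,
            "soil_theta": water.theta,
            "rain": fluxes.rain,
            "drainage": fluxes.drainage,
            "evaporation": fluxes.evaporation,
            "transpiration": fluxes.transpiration,
            "root_zone_inflow": fluxes.root_zone_inflow,
            "NED": rates.NED,
            "NES": rates.NES,
            "NEUP": rates.NEUP,
        }
        for n in NUTRIENTS:
            row[f"A_{n}"] = soil.A[n]
            row[f"S_remaining_{n}"] = soil.S_remaining[n]
            row[f"F_remaining_{n}"] = soil.F_remaining[n]
            row[f"Act_{n}"] = sum(state.amounts[(o, n)] for o in ORGANS)
            row[f"Min_{n}"] = amounts.Min[n]
            row[f"Max_{n}"] = amounts.Max[n]
            row[f"Opt_{n}"] = amounts.Opt[n]
            row[f"UP_{n}"] = rates.UP[n]
            row[f"NI_{n}"] = indices.NI[n]
            row[f"cum_uptake_{n}"] = soil.cumulative_uptake[n]
            row[f"cum_soil_release_{n}"] = soil.cumulative_soil_release[n]
            row[f"cum_fert_release_{n}"] = soil.cumulative_fert_release[n]
            row[f"cutting_input_{n}"] = state.cutting_input[n]
            row[f"F_applied_{n}"] = soil.F_applied[n]
        records.append(row)

    return pd.DataFrame.from_records(records)


def _check_state(state: CropState, soil, day_index: int) -> None:
    for o in ORGANS:
        w = state.weights[o]
        if not math.isfinite(w) or w < -1e-9:
            raise EngineError(f"day {day_index}: weight of {o} is {w}")
        state.weights[o] = max(0.0, w)
    for key, amount in state.amounts.items():
        if not math.isfinite(amount) or amount < -1e-6:
            raise EngineError(f"day {day_index}: nutrient amount {key} is {amount}")
    for n in NUTRIENTS:
        for pool_name in ("A", "S_remaining", "F_remaining"):
            value = getattr(soil, pool_name)[n]
            if not math.isfinite(value) or value < -1e-9:
                raise EngineError(f"day {day_index}: soil pool {pool_name}[{n}] is {value}")


def run_battery(params: ModelParameters, scenarios: dict, weather,
                nutrient_limitation: bool = True) -> dict:
    """Simulate a dict of named scenarios on shared weather."""
    return {name: simulate(params, scen, weather, nutrient_limitation)
            for name, scen in scenarios.items()}
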