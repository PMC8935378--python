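"""Soil nutrient pools and daily plant-available N, P and K supply.

Each nutrient is tracked with three stocks (g m-2): the plant-available
pool A, the unreleased indigenous soil pool S, and the unreleased
fertilizer pool F.  A quarter of the total indigenous supply is available
at emergence; the remainder releases at a constant rate sized so the S
pool lasts 0.9 of the season length SL.  Fertilizer releases first-order
at the nutrient-specific relative rate rf, slowed by the water limitation
factor WLIMIT; only the fraction Rec of what leaves F reaches A, so the
asymptotic fertilizer recovery equals Rec.  The daily change of A is

    RA = 0.75 * S_total / (0.9 * SL) + Rec * rf * F * WLIMIT - uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import NUTRIENTS, FertilizerEvent, ModelParameters, Scenario, SiteSupply

#: fraction of the indigenous supply available at emergence
INITIAL_AVAILABLE_FRACTION = 0.25
#: fraction of the season length over which the S pool releases
SEASON_RELEASE_FRACTION = 0.9


@dataclass
class SoilNutrientState:
    """Per-nutrient soil stocks, all in g m-2."""

    A: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})
    S_total: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})
    S_remaining: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})
    F_remaining: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})
    F_applied: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})
    cumulative_soil_release: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})
    cumulative_fert_release: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})
    cumulative_uptake: dict = field(default_factory=lambda: {n: 0.0 for n in NUTRIENTS})


def extra_supply_active(scenario: Scenario, nutrient: str) -> bool:
    """Omission-derived extra supply of a nutrient counts only when the
    other two nutrients are actually applied in the schedule."""
    others = [n for n in NUTRIENTS if n != nutrient]
    return all(scenario.total_applied(n) > 0.0 for n in others)


def initialize_soil(supply: SiteSupply, scenario: Scenario | None = None) -> SoilNutrientState:
    """Set up the soil pools: 25% of the total supply available at emergence.

    The total indigenous supply per nutrient is the control-plot uptake plus
    — when the fertilizer schedule applies both other nutrients — the extra
    uptake measured in omission plots, scaled by the scenario's
    ``extra_supply_scale``.
    """
    state = SoilNutrientState()
    for n in NUTRIENTS:
        total = supply.base(n)
        if scenario is not None and extra_supply_active(scenario, n):
            total += scenario.extra_supply_scale * supply.extra(n)
        if total < 0:
            raise ValueError(f"negative total {n} supply: {total}")
        state.S_total[n] = total
        state.A[n] = INITIAL_AVAILABLE_FRACTION * total
        state.S_remaining[n] = (1.0 - INITIAL_AVAILABLE_FRACTION) * total
    return state


def apply_fertilizer(state: SoilNutrientState, event: FertilizerEvent) -> SoilNutrientState:
    """Add an application to the unreleased fertilizer pools (in place)."""
    for n in NUTRIENTS:
        amount = event.amount(n)
        state.F_remaining[n] += amount
        state.F_applied[n] += amount
    return state


def soil_release_rate(state: SoilNutrientState, nutrient: str, sl: float,
                      delt: float = 1.0) -> float:
    """Constant indigenous release, limited by what is left in S (g m-2 d-1)."""
    if sl <= 0:
        raise ValueError("season length SL must be > 0")
    constant = ((1.0 - INITIAL_AVAILABLE_FRACTION) * state.S_total[nutrient]
                / (SEASON_RELEASE_FRACTION * sl))
    return min(constant, state.S_remaining[nutrient] / delt)


def fertilizer_release_rate(state: SoilNutrientState, nutrient: str,
                            params: ModelParameters, wlim: float) -> float:
    """First-order gross fertilizer release rf * F * WLIMIT (g m-2 d-1)."""
    return params.rf(nutrient) * state.F_remaining[nutrient] * wlim


def step_soil_nutrients(state: SoilNutrientState, params: ModelParameters,
                        sl: float, wlim: float) -> dict:
    """Release one day of soil and fertilizer nutrients into A (in place).

    Returns the per-nutrient net release added to A this day.  Uptake is
    withdrawn separately (see :func:`withdraw_uptake`) after the crop's
    demand is known, so the available pool a crop sees on a given day
    already includes that day's release.
    """
    delt = params.DELT
    released = {}
    for n in NUTRIENTS:
        s_rel = soil_release_rate(state, n, sl, delt)
        f_gross = fertilizer_release_rate(state, n, params, wlim)
        f_net = params.rec(n) * f_gross
        state.S_remaining[n] -= s_rel * delt
        state.F_remaining[n] -= f_gross * delt
        state.A[n] += (s_rel + f_net) * delt
        state.cumulative_soil_release[n] += s_rel * delt
        state.cumulative_fert_release[n] += f_net * delt
        released[n] = (s_rel + f_net) * delt
    return released


def withdraw_uptake(state: SoilNutrientState, uptake_rates: dict,
                    delt: float = 1.0) -> None:
    """Remove the crop's uptake from A (in place); A never goes below 0."""
    for n in NUTRIENTS:
        take = uptake_rates[n] * delt
        if take > state.A[n] + 1e-12:
            raise ValueError(f"uptake of {n} exceeds available pool")
        state.A[n] = max(0.0, state.A[n] - take)
        state.cumulative_uptake[n] += take
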