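"""Crop-side N, P and K bookkeeping.

The crop's nutrient status is carried per organ (green leaf, stem, storage
organ, fine root) as absolute amounts in g m-2.  From the organ dry weights
and the thermal-time-dependent minimum/maximum concentration curves the
whole-plant Min, Max and Opt amounts follow; demand and soil supply are
converted into a common nitrogen-equivalent currency so that a shortage of
one nutrient also throttles uptake of the others (QUEFTS-style coupling).
Per-nutrient nutrition indices

    NI = (Act - Min) / (Opt - Min),   Opt = Min + FR_MAX * (Max - Min)

are combined multiplicatively and passed through a saturating Monod-type
transform to give the single growth-reduction factor NPKI.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import NUTRIENTS, ORGANS, ConcentrationTable, ModelParameters


@dataclass(frozen=True)
class PlantAmounts:
    """Whole-plant nutrient aggregates (g m-2), one value per nutrient."""

    Act: dict
    Min: dict
    Max: dict
    Opt: dict


@dataclass(frozen=True)
class NutrientIndices:
    NI: dict        # per-nutrient nutrition index in [0, 1]
    NPKI: float     # combined index in [0, 1]


@dataclass(frozen=True)
class UptakeRates:
    NED: float      # nutrient-equivalent demand, g m-2
    NES: float      # nutrient-equivalent soil supply, g m-2
    NEUP: float     # nutrient-equivalent uptake rate, g m-2 d-1
    UP: dict        # per-nutrient uptake rate, g m-2 d-1


def organ_concentration_bounds(tables: ConcentrationTable, tsum: float) -> dict:
    """(cmin, cmax) per (organ, nutrient) at one thermal time."""
    return {(o, n): tables.interpolate(o, n, tsum) for o in ORGANS for n in NUTRIENTS}


def plant_amounts(weights: dict, amounts: dict, tables: ConcentrationTable,
                  tsum: float, fr_max: float, bounds: dict | None = None,
                  ) -> PlantAmounts:
    """Aggregate actual/min/max/optimal plant nutrient amounts.

    ``weights`` maps organ -> g DM m-2; ``amounts`` maps (organ, nutrient)
    -> g m-2 of stored nutrient.  Act comes from the stored amounts; Min and
    Max from concentration curves times organ weights; Opt interpolates
    between them with the FR_MAX fraction.  ``bounds`` may carry
    precomputed concentration bounds for this thermal time.
    """
    if bounds is None:
        bounds = organ_concentration_bounds(tables, tsum)
    act, mn, mx, opt = {}, {}, {}, {}
    for n in NUTRIENTS:
        act[n] = sum(amounts[(o, n)] for o in ORGANS)
        mn[n] = sum(bounds[(o, n)][0] * weights[o] for o in ORGANS)
        mx[n] = sum(bounds[(o, n)][1] * weights[o] for o in ORGANS)
        opt[n] = mn[n] + fr_max * (mx[n] - mn[n])
    return PlantAmounts(Act=act, Min=mn, Max=mx, Opt=opt)


def nutrient_equivalent_demand(act: dict, mx: dict) -> float:
    """Whole-plant demand in N-equivalents.

    The N gap counts as-is; P and K gaps are scaled by Max_N/Max_x so one
    "equivalent" of any nutrient represents the same relative shortfall.
    Terms with Max_x = 0 (no biomass yet) contribute 0; the result is
    floored at 0.
    """
    ned = 0.0
    if mx["N"] > 0.0:
        ned += mx["N"] - act["N"]
        for x in ("P", "K"):
            if mx[x] > 0.0:
                ned += (mx[x] - act[x]) / mx[x] * mx["N"]
    return max(0.0, ned)


def nutrient_equivalent_supply(available: dict, mx: dict) -> float:
    """Plant-available soil nutrients expressed in N-equivalents."""
    nes = 0.0
    if mx["N"] > 0.0:
        nes += available["N"]
        for x in ("P", "K"):
            if mx[x] > 0.0:
                nes += available[x] / mx[x] * mx["N"]
    return nes


def uptake_rates(amounts: PlantAmounts, available: dict,
                 params: ModelParameters) -> UptakeRates:
    """Daily uptake, limited by demand, soil availability and the NE rate.

    The nutrient-equivalent uptake rate is RNE * min(NES, NED); each
    nutrient's uptake is then the least of its remaining demand, its
    available pool, and its N-equivalent share of the NE uptake.
    """
    ned = nutrient_equivalent_demand(amounts.Act, amounts.Max)
    nes = nutrient_equivalent_supply(available, amounts.Max)
    neup = params.RNE * min(ned, nes)
    delt = params.DELT
    up = {}
    for n in NUTRIENTS:
        if amounts.Max["N"] <= 0.0 or amounts.Max[n] <= 0.0:
            up[n] = 0.0
            continue
        demand = max(0.0, amounts.Max[n] - amounts.Act[n]) / delt
        supply = max(0.0, available[n]) / delt
        share = amounts.Max[n] / amounts.Max["N"] * neup
        up[n] = max(0.0, min(demand, supply, share))
    return UptakeRates(NED=ned, NES=nes, NEUP=neup, UP=up)


def allocate_uptake(up: dict, weights: dict) -> dict:
    """Split uptake over organs proportionally to organ dry weight.

    Returns (organ, nutrient) -> g m-2 d-1 increments summing exactly to the
    whole-plant uptake.  With zero total biomass nothing is allocated.
    """
    total = sum(weights[o] for o in ORGANS)
    out = {(o, n): 0.0 for o in ORGANS for n in NUTRIENTS}
    if total <= 0.0:
        return out
    for n in NUTRIENTS:
        remaining = up[n]
        for i, o in enumerate(ORGANS):
            if i == len(ORGANS) - 1:
                share = remaining   # last organ absorbs rounding residue
            else:
                share = up[n] * weights[o] / total
                remaining -= share
            out[(o, n)] = share
    return out


def redistribution_rates(weights: dict, amounts: dict, act: dict,
                         tables: ConcentrationTable, tsum: float,
                         tc_npk: float, bounds: dict | None = None) -> dict:
    """Translocation between organs toward equal relative nutrient saturation.

    Every organ's target holding is the whole-plant actual amount shared in
    proportion to the organ's maximum-content capacity (so all organs sit at
    the same relative distance to their concentration bounds).  Transfers
    relax toward the target at rate 1/TC_NPK_T and sum to zero per nutrient.
    """
    if bounds is None:
        bounds = organ_concentration_bounds(tables, tsum)
    rate = 1.0 / tc_npk
    out = {}
    for n in NUTRIENTS:
        cap = {o: bounds[(o, n)][1] * weights[o] for o in ORGANS}
        total_cap = sum(cap.values())
        if total_cap <= 0.0:
            for o in ORGANS:
                out[(o, n)] = 0.0
            continue
        targets = {o: act[n] * cap[o] / total_cap for o in ORGANS}
        transfers = {o: rate * (targets[o] - amounts[(o, n)]) for o in ORGANS}
        # exact zero-sum: fold the arithmetic residue into the largest pool
        residue = sum(transfers.values())
        largest = max(ORGANS, key=lambda o: cap[o])
        transfers[largest] -= residue
        for o in ORGANS:
            out[(o, n)] = transfers[o]
    return out


def reroute_dead_leaf_nutrients(dying_fraction: float, leaf_amounts: dict) -> dict:
    """Salvage nutrients from dying leaf tissue before it drops.

    Dead leaves carry no nutrients: the N held in the dying leaf fraction
    moves to the stem and the P and K move to the storage organs.  Returns
    (organ, nutrient) -> transfer in g m-2 (zero-sum per nutrient).
    """
    if not 0.0 <= dying_fraction <= 1.0:
        raise ValueError(f"dying fraction out of [0, 1]: {dying_fraction}")
    out = {(o, n): 0.0 for o in ORGANS for n in NUTRIENTS}
    for n, sink in (("N", "stem"), ("P", "storage"), ("K", "storage")):
        moved = dying_fraction * leaf_amounts[n]
        out[("leaf", n)] = -moved
        out[(sink, n)] = moved
    return out


# ---------------------------------------------------------------------------
# nutrition indices
# ---------------------------------------------------------------------------


def nutrition_index(act: float, mn: float, opt: float) -> float:
    """Per-nutrient index (Act - Min)/(Opt - Min), clamped to [0, 1]."""
    if opt < mn:
        raise ValueError("Opt < Min in nutrition index")
    if opt == mn:
        # degenerate span (no biomass or FR_MAX = 0): sufficiency iff Act >= Min
        return 1.0 if act >= mn else 0.0
    return min(1.0, max(0.0, (act - mn) / (opt - mn)))


def combine_npki(ni_product: float, k_ni: float, kmax: float) -> float:
    """Combined NPK index via the saturating Monod transform.

    With c = K_NI + 1 the two branches

        NPKI = c * pi / (K_NI + pi)                    (K_NI <= KMAX)
        NPKI = 1 - c * (1 - pi) / (K_NI + (1 - pi))    (K_NI >  KMAX)

    both pass through NPKI = 1 exactly at pi = 1, for any K_NI.  The second
    branch penalises simultaneous multi-nutrient stress more strongly.
    """
    if not 0.0 <= ni_product <= 1.0:
        raise ValueError(f"NI product out of [0, 1]: {ni_product}")
    c = k_ni + 1.0
    if k_ni <= kmax:
        npki = c * ni_product / (k_ni + ni_product) if (k_ni + ni_product) > 0 else 1.0
    else:
        npki = 1.0 - c * (1.0 - ni_product) / (k_ni + (1.0 - ni_product))
    return min(1.0, max(0.0, npki))


def nutrition_indices(amounts: PlantAmounts, tsum: float,
                      params: ModelParameters) -> NutrientIndices:
    """Per-nutrient indices and the combined NPKI with the thermal-time gate.

    Before TSUM_NPKI the young plant still lives off its cutting reserves,
    so nutrient limitation is not allowed to reduce growth: NPKI is forced
    to 1 (the per-nutrient indices are still reported).
    """
    ni = {n: nutrition_index(amounts.Act[n], amounts.Min[n], amounts.Opt[n])
          for n in NUTRIENTS}
    if tsum < params.TSUM_NPKI:
        npki = 1.0
    else:
        product = ni["N"] * ni["P"] * ni["K"]
        npki = combine_npki(product, params.K_NI, params.KMAX)
    return NutrientIndices(NI=ni, NPKI=npki)
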