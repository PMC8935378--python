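"""Dry-matter growth, partitioning, leaf senescence and dormancy recovery.

Daily growth follows the radiation-use-efficiency concept: intercepted PAR
times RUE, cut by the stricter of the water stress factor TRANRF and the
combined nutrient stress index NPKI, and switched off entirely while the
crop is drought-dormant:

    dW/dt = RUE * PARint * min(TRANRF, NPKI) * (1 - Dormancy)

(The min form is identical to a piecewise definition that applies TRANRF
when TRANRF <= NPKI and NPKI otherwise.)  New dry matter is partitioned
over organs by a thermal-time-indexed table; stress shifts partitioning
toward the fine roots in the same manner as water deficiency does in the
underlying water-limited model.
"""

from __future__ import annotations

import numpy as np

from .config import CropParameters, ORGANS


def growth_rate(rue: float, par_int: float, tranrf: float, npki: float,
                dormancy: int) -> float:
    """Daily crop growth rate, g DM m-2 d-1 (the stricter stress binds)."""
    return rue * par_int * min(tranrf, npki) * (1 - dormancy)


def growth_rate_piecewise(rue: float, par_int: float, tranrf: float,
                          npki: float, dormancy: int) -> float:
    """Literal two-branch form of the growth rule (reference for testing)."""
    if tranrf <= npki:
        return rue * par_int * tranrf * (1 - dormancy)
    return rue * par_int * npki * (1 - dormancy)


def base_partitioning(tsum: float, table) -> dict:
    """Interpolate the organ partitioning fractions at one thermal time."""
    xs = [row[0] for row in table]
    out = {}
    for i, organ in enumerate(ORGANS):
        ys = [row[1 + i] for row in table]
        out[organ] = float(np.interp(tsum, xs, ys))
    # linear interpolation of fractions that each sum to 1 stays on the simplex,
    # but guard against table round-off
    total = sum(out.values())
    return {o: v / total for o, v in out.items()}


def stressed_partitioning(tsum: float, stress: float, crop: CropParameters) -> dict:
    """Partitioning fractions with the stress-driven fine-root boost.

    ``stress`` is min(TRANRF, NPKI).  The fine-root fraction is multiplied
    by max(1, 1/(stress + root_boost)) — the classic water-stress root
    modifier, here driven by the stricter of water and nutrient stress —
    capped at ``max_root_fraction``; shoot fractions are rescaled so the
    four fractions still sum to 1.
    """
    fracs = base_partitioning(tsum, crop.partitioning_table)
    modifier = max(1.0, 1.0 / (stress + crop.root_boost))
    root = min(crop.max_root_fraction, fracs["root"] * modifier)
    shoot = 1.0 - fracs["root"]
    if shoot <= 0.0:
        return {"leaf": 0.0, "stem": 0.0, "storage": 0.0, "root": 1.0}
    scale = (1.0 - root) / shoot
    out = {o: fracs[o] * scale for o in ("leaf", "stem", "storage")}
    out["root"] = root
    return out


def partition_growth(dw: float, tsum: float, tranrf: float, npki: float,
                     crop: CropParameters) -> dict:
    """Split the day's growth over organs; increments sum to dW exactly."""
    fracs = stressed_partitioning(tsum, min(tranrf, npki), crop)
    out = {}
    remaining = dw
    for i, o in enumerate(ORGANS):
        if i == len(ORGANS) - 1:
            out[o] = remaining
        else:
            out[o] = dw * fracs[o]
            remaining -= out[o]
    return out


def leaf_death_rate(w_leaf: float, npki: float, tsum: float,
                    rdrns: float, crop: CropParameters,
                    delt: float = 1.0) -> float:
    """Leaf senescence, g DM m-2 d-1.

    Nutrient stress kills leaves at up to the relative rate RDRNS, scaled
    by (1 - NPKI); background ageing senescence starts beyond a thermal-time
    onset.  The two causes combine by maximum (not addition) to avoid double
    counting, and the rate never drives leaf weight negative.
    """
    stress_component = w_leaf * rdrns * (1.0 - npki)
    base_component = w_leaf * crop.RDR_base if tsum >= crop.RDR_TSUM_onset else 0.0
    return min(max(stress_component, base_component), w_leaf / delt)


def dormancy_remobilization(w_storage: float, storage_amounts: dict,
                            crop: CropParameters) -> tuple[float, dict]:
    """Regrow leaves from storage-root reserves when dormancy ends.

    A configured fraction of storage-root dry matter converts to new leaf
    biomass; the N, P and K carried along are proportional to the biomass
    decrement, so whole-plant totals are conserved.  Returns the biomass
    decrement and the per-nutrient amounts moved from storage to leaf.
    """
    decrement = crop.regrowth_fraction * w_storage
    if w_storage <= 0.0 or decrement <= 0.0:
        return 0.0, {n: 0.0 for n in storage_amounts}
    fraction = decrement / w_storage
    moved = {n: fraction * amount for n, amount in storage_amounts.items()}
    return decrement, moved
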