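"""Factory helpers for NPK fertilizer-treatment scenarios.

Builds the kind of omission/rate factorial used in cassava response trials:
full rates of 300 kg N, 100 kg P and 300 kg K ha-1, single-nutrient
omissions, a K-rate ladder and reduced-rate combinations.  Treatment names
follow the field convention: ``NfPfK0`` means full N, full P, no K.
"""

from __future__ import annotations

from .config import FertilizerEvent, Scenario, SiteSupply, kg_ha_to_g_m2

#: full application rates, kg ha-1
FULL_N = 300.0
FULL_P = 100.0
FULL_K = 300.0

#: split-application days after planting and their dose fractions
SPLIT_DAYS = (30, 90)
SPLIT_FRACTIONS = (0.5, 0.5)


def edo_2016_supply() -> SiteSupply:
    """Indigenous supply of the humid rainforest-transition calibration site.

    Control-plot uptakes of 194.2 kg N, 19.9 kg P and 88.0 kg K ha-1 with
    omission-plot extras of 62.7 kg N and 11.5 kg P ha-1; the measured extra
    K was negative (sampling noise) and enters as zero.
    """
    return SiteSupply(
        base_N=kg_ha_to_g_m2(194.2),
        base_P=kg_ha_to_g_m2(19.9),
        base_K=kg_ha_to_g_m2(88.0),
        extra_N=kg_ha_to_g_m2(62.7),
        extra_P=kg_ha_to_g_m2(11.5),
        extra_K=0.0,   # measured -27.9 kg ha-1, clamped
    )


def edo_like_supply() -> SiteSupply:
    """Edo-like supply for omission batteries, with a usable extra-K term.

    Identical to :func:`edo_2016_supply` except that the extra K supply —
    measured negative in 2016 (−27.9 ± 26.1 kg ha⁻¹, i.e. dominated by
    sampling noise) — is replaced by the same site's 2017-season
    measurement of +7.2 kg K ha⁻¹.  A positive extra supply of the omitted
    nutrient is what distinguishes an omission treatment from the control
    in this model, so batteries that compare the two use this variant.
    """
    supply = edo_2016_supply()
    supply.extra_K = kg_ha_to_g_m2(7.2)
    return supply


def fertilizer_schedule(n_kg_ha: float, p_kg_ha: float, k_kg_ha: float,
                        days=SPLIT_DAYS, fractions=SPLIT_FRACTIONS):
    """Split-application schedule; P goes basal with the first split."""
    events = []
    for i, (day, frac) in enumerate(zip(days, fractions)):
        events.append(FertilizerEvent(
            day=day,
            amount_N=kg_ha_to_g_m2(n_kg_ha) * frac,
            amount_P=kg_ha_to_g_m2(p_kg_ha) if i == 0 else 0.0,
            amount_K=kg_ha_to_g_m2(k_kg_ha) * frac,
        ))
    return tuple(events)


#: 12-treatment NPK factorial: (N, P, K) rates in kg ha-1
STANDARD_TREATMENTS: dict[str, tuple[float, float, float]] = {
    "control": (0.0, 0.0, 0.0),
    "N0PfKf": (0.0, FULL_P, FULL_K),
    "NfP0Kf": (FULL_N, 0.0, FULL_K),
    "NfPfK0": (FULL_N, FULL_P, 0.0),
    "NfPfK60": (FULL_N, FULL_P, 60.0),
    "NfPfK120": (FULL_N, FULL_P, 120.0),
    "NfPfK180": (FULL_N, FULL_P, 180.0),
    "NfPfK240": (FULL_N, FULL_P, 240.0),
    "NfPfKf": (FULL_N, FULL_P, FULL_K),
    "N150P40K180": (150.0, 40.0, 180.0),
    "N150PfKf": (150.0, FULL_P, FULL_K),
    "NfP40Kf": (FULL_N, 40.0, FULL_K),
}

#: treatments used to estimate the soil supply terms (excluded in the
#: stricter evaluation mode)
SUPPLY_ESTIMATION_TREATMENTS = ("control", "N0PfKf", "NfP0Kf", "NfPfK0")


def make_scenario(name: str, rates: tuple[float, float, float],
                  supply: SiteSupply | None = None, season_length: int = 420,
                  planting_date: str = "2016-05-24") -> Scenario:
    """One treatment scenario on a given site supply (default: the humid
    calibration-site values)."""
    n, p, k = rates
    return Scenario(
        name=name,
        supply=supply if supply is not None else edo_2016_supply(),
        schedule=fertilizer_schedule(n, p, k),
        season_length=season_length,
        planting_date=planting_date,
    )


def standard_battery(supply: SiteSupply | None = None, season_length: int = 420,
                     treatments=None) -> dict[str, Scenario]:
    """Scenario per treatment name (default: the full 12-treatment factorial)."""
    names = treatments if treatments is not None else list(STANDARD_TREATMENTS)
    return {name: make_scenario(name, STANDARD_TREATMENTS[name], supply,
                                season_length)
            for name in names}
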