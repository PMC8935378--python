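# cassava-npk

Daily simulation of cassava (*Manihot esculenta*) growth and storage-root
yield under combined nitrogen, phosphorus and potassium limitation, for
agronomists and crop modellers studying fertilizer response and nutrient
use efficiency in the humid tropics.

## The model

The crop engine is a light-interception / radiation-use-efficiency model
on a daily time step: intercepted photosynthetically active radiation
(Beer's law on LAI, PAR = 0.5 × global radiation) times a radiation use
efficiency *RUE*, with assimilate partitioning a tabulated function of
thermal time (TSUM). On top of this water-limited base sits an explicit
N–P–K economy:

**Soil supply.** Each nutrient x ∈ {N, P, K} has three soil stocks
(g m⁻²): plant-available *A*, unreleased indigenous supply *S* and
unreleased fertilizer *F*. A quarter of *S* is available at emergence and
the rest releases at a constant rate over 0.9 of the season length *SL*;
fertilizer releases first-order at a nutrient-specific relative rate
*rf*ₓ, slowed under drought by a Monod factor of the transpiration
reduction factor, WLIMIT = TRANRF / (K_WATER + TRANRF), and recovered at
most at the fraction *Rec*ₓ:

    dA/dt = 0.75 S / (0.9 SL) + Rec · rf · F · WLIMIT − uptake

**Demand, supply and uptake in nutrient equivalents.** Whole-plant
actual/minimum/maximum contents follow from organ dry weights and
thermal-time-dependent concentration bounds. Demand and soil supply are
converted to a common N-equivalent currency (a QUEFTS-style coupling, so
shortage of one nutrient throttles uptake of the others):

    NED = (Maxₙ − Actₙ) + (Maxₚ − Actₚ)/Maxₚ · Maxₙ + (Maxₖ − Actₖ)/Maxₖ · Maxₙ
    NES = Aₙ + Aₚ/Maxₚ · Maxₙ + Aₖ/Maxₖ · Maxₙ
    dNEUP/dt = RNE · min(NED, NES)
    UPₓ = min((Maxₓ − Actₓ)/Δt, Aₓ/Δt, Maxₓ/Maxₙ · dNEUP/dt)

**Nutrition indices and growth reduction.** Per nutrient,
NI = (Act − Min)/(Opt − Min) with Opt = Min + FR_MAX (Max − Min), clamped
to [0, 1]. The product π = NIₙ·NIₚ·NIₖ passes through a saturating Monod
transform with c = K_NI + 1:

    NPKI = c·π / (K_NI + π)                    if K_NI ≤ KMAX
    NPKI = 1 − c·(1 − π) / (K_NI + (1 − π))    if K_NI > KMAX

Both branches give NPKI = 1 exactly at π = 1. With the calibrated
constants K_NI = 6.1 and KMAX = 4 a product of 0.8 maps to NPKI = 0.77 —
simultaneous multi-nutrient stress is penalised more than proportionally.
Before a thermal-time threshold TSUM_NPKI the young plant lives off its
cutting reserves and NPKI is held at 1. Daily growth takes the stricter
of water and nutrient stress:

    dW/dt = RUE · PARint · min(TRANRF, NPKI) · (1 − Dormancy)

Uptake is allocated to organs by biomass, translocated between organs
toward equal relative saturation with a 10-day time coefficient, salvaged
from dying leaves (N to stems, P and K to storage roots), and nutrient
stress additionally kills leaves at up to RDRNS = 0.05 d⁻¹.

The package also ships a synthetic humid-tropical weather generator
(wet and dry-spell profiles), a 12-treatment NPK factorial scenario
battery, evaluation metrics (RMSEP, R², slope of simulated vs observed)
and a deterministic grid-plus-simplex calibration of
(K_NI, KMAX, TSUM_NPKI).

## Worked example

Simulate a fully fertilized treatment (300 kg N, 100 kg P, 300 kg K ha⁻¹,
split applications at 30 and 90 days) on a humid site with strong
indigenous supply, using a seeded synthetic wet season:

```bash
cassava-npk run examples/humid_site_full_npk.yaml --seed 1 --out full_npk.csv
```

prints

```
full-npk: 420 days, final storage-root DM 2741.8 g m-2, N/P/K uptake 34.64/4.32/30.97 g m-2
```

i.e. about 27 t ha⁻¹ of storage-root dry matter at 14 months after
planting, with season totals of ≈ 346 kg N, 43 kg P and 310 kg K ha⁻¹
taken up — the scale observed in well-fertilized cassava response trials
in southern Nigeria. The daily CSV holds one row per day: organ weights,
LAI, soil pools A/S/F, plant Act/Min/Max/Opt, uptake rates, NI and NPKI,
TRANRF and the water balance terms. The same battery run as the control
(no fertilizer) ends near 920 g m⁻² — the crop is then limited mainly by
indigenous potassium.

From Python:

```python
from cassava_npk import ModelParameters, generate_synthetic_weather, simulate
from cassava_npk.treatments import standard_battery, edo_like_supply

weather = generate_synthetic_weather(seed=1, n_days=420, climate_profile="wet")
scenarios = standard_battery(supply=edo_like_supply())
out = simulate(ModelParameters(), scenarios["NfPfKf"], weather)
print(out[["day", "W_storage", "NI_K", "NPKI"]].tail())
```

## Layout

| module | contents |
|---|---|
| `cassava_npk.config` | parameters, concentration lookup tables, scenarios, YAML I/O |
| `cassava_npk.weather` | weather CSV I/O, thermal time, intercepted PAR, synthetic weather |
| `cassava_npk.soil_water` | tipping-bucket water balance, TRANRF, WLIMIT, dormancy trigger |
| `cassava_npk.soil_npk` | soil nutrient pools and release kinetics |
| `cassava_npk.crop_npk` | plant nutrient amounts, nutrient equivalents, uptake, indices |
| `cassava_npk.crop_growth` | growth rate, partitioning, senescence, dormancy recovery |
| `cassava_npk.engine` | the daily integration loop and tidy per-day output |
| `cassava_npk.calibration` | RMSE/RMSEP/R²/slope, synthetic observations, parameter fitting |
| `cassava_npk.treatments` | NPK factorial scenario factories |
| `cassava_npk.cli` | `cassava-npk` subcommands: run, battery, calibrate, evaluate, synthesize-obs |

See `docs/methods.md` for the model description, default-parameter
rationale and known limitations.
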