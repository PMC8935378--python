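# Methods

This note documents the model equations as implemented, the default
parameter choices and their rationale, what the synthetic data emulate,
and the numerical conventions. Units are g m⁻² (areal mass), g g⁻¹ DM
(concentration), mm (water) and °C·d (thermal time) throughout; kg ha⁻¹
is accepted only at the I/O boundary (exact factor 10).

## Daily loop and integration

The engine advances an explicit Euler step of one day (DELT = 1 d is
fixed). Within a day the order of operations is: weather → thermal-time
increment → water balance (TRANRF, WLIMIT, dormancy) → fertilizer events
→ soil nutrient release → plant Min/Max/Opt from concentration lookups →
nutrient-equivalent demand/supply → uptake and allocation → nutrition
indices and NPKI (thermal-time gate applied) → growth rate →
partitioning → leaf death with nutrient rerouting → translocation →
state update. Rates are computed from start-of-day states, with two
deliberate exceptions that define the uptake contract: soil release
precedes uptake (the available pool a crop draws on already contains the
day's release), and the nutrition indices use the day's post-uptake
plant contents (stress responds to uptake without a one-day lag).
Identical inputs give bit-identical output; a non-finite or negative
state aborts the run naming the day and variable.

## Crop growth

Growth is dW/dt = RUE · PARint · min(TRANRF, NPKI) · (1 − Dormancy).
The min form is mathematically identical to the two-branch form that
applies TRANRF when TRANRF ≤ NPKI and NPKI otherwise; the test suite
verifies the equivalence exhaustively on a grid. PARint is Beer's law,
0.5 · srad · (1 − exp(−k·LAI)), and LAI = SLA · (green leaf weight).

New dry matter is partitioned by a thermal-time-indexed table
(development runs through three stages: planting→sprouting at 125 °C·d,
sprouting→first branching at 900 °C·d, branching→harvest). Stress —
the same min(TRANRF, NPKI) driver — multiplies the fine-root fraction by
max(1, 1/(stress + 0.5)), capped at 0.6, with shoot fractions rescaled;
this reuses the classic water-stress root-boost form so nutrient stress
shifts allocation below ground "in the same manner" as drought.
Nutrient limitation deliberately does not alter the shoot-internal
(leaf/stem/storage) ratios.

Leaf senescence combines a background ageing rate (0.008 d⁻¹ after
1200 °C·d) with a nutrient-stress rate RDRNS · (1 − NPKI), RDRNS =
0.05 d⁻¹, by **maximum**, not addition: the printed RDRNS is a maximum
rate and adding the two would double-count death under simultaneous
ageing and stress. Dead leaves are retained in a dead-leaf pool (the
dry-matter budget includes them) and carry zero nutrients — their N
moves to stems and their P and K to storage roots at the moment of
death.

After a drought-dormancy episode ends, a configured fraction (default
0.05) of storage-root dry matter converts to new leaf biomass, with N, P
and K moved in proportion to the biomass decrement, conserving
whole-plant totals.

## Soil nutrients

Per nutrient: A (plant-available), S (unreleased indigenous),
F (unreleased fertilizer). At emergence A = 0.25 · S_total, the
remaining 75% releasing at the constant rate 0.75·S_total/(0.9·SL).
Fertilizer depletes first-order at rf·F·WLIMIT (rf_N = 0.1, rf_P = 0.01,
rf_K = 0.04 d⁻¹) while the available pool gains only Rec·rf·F·WLIMIT
(Rec_N = 0.75, Rec_P = 0.28, Rec_K = 0.70): Rec is thereby the
*asymptotic* recovery fraction and the (1 − Rec) share is implicitly
lost, which reconciles the product form of the release equation with the
"maximum recovery" meaning of Rec. WLIMIT multiplies only the fertilizer
term; indigenous release is treated as water-independent (the release
equation's scope is ambiguous on this point; the narrower reading —
drought "reduces fertilizer release rates" — is adopted).

S_total is the control-plot uptake plus, when the schedule applies both
other nutrients at a nonzero rate, the omission-plot "extra" supply
(scalable 0–1 per scenario). A negative measured extra (sampling noise)
is clamped to zero with a warning. No leaching, sorption or
mineralization modelling: measured supply subsumes them.

## Plant nutrients

Min/Max whole-plant amounts are Σ organs (concentration bound × organ
weight), with per-organ bounds linearly interpolated in TSUM and held
constant beyond table ends. Opt = Min + FR_MAX·(Max − Min), FR_MAX =
0.8. NI = (Act − Min)/(Opt − Min) clamped to [0, 1]; luxury uptake above
Opt (bounded by Max) is allowed and clamps NI at 1. When Opt = Min
(no biomass) NI is 1 iff Act ≥ Min. The combined index uses the product
π of the three NIs and the saturating transform with c = K_NI + 1
(K_NI = 6.1, KMAX = 4; K_NI > KMAX selects the branch that penalises
joint stress). NPKI is forced to 1 while TSUM < TSUM_NPKI = 272 °C·d.

Demand terms with Max = 0 evaluate to 0, avoiding division by zero
before sprouting. Uptake is allocated over organs proportionally to dry
weight. Translocation relaxes each organ toward the target holding
Act · (organ Max share) at rate 1/TC_NPK_T = 0.1 d⁻¹ — the target
realises the assumption that all organs sit at the same relative
distance between their concentration bounds; transfers are exactly
zero-sum per nutrient (the arithmetic residue is folded into the
largest-capacity organ). The 10-day translocation time coefficient and
the 0.1 d⁻¹ redistribution rate are one mechanism (rate = 1/TC).

Cutting reserves: at sprouting, 25 g DM m⁻² enters the organ pools split
by the partitioning fractions at the sprouting thermal time, carrying
2.5% N, 0.3% P and 1.8% K. Rationale: cassava is planted from large
stem cuttings (~1.25 plants m⁻² × ~20 g DM mobilisable reserve), and
young shoots are nutrient-rich. These reserves, together with the
TSUM_NPKI gate, are what carry the crop through establishment, when
demand growth necessarily outruns the nutrient-equivalent uptake rate:
with relative growth rates near 8–10% d⁻¹ at canopy expansion, no
admissible uptake rate keeps Act at Opt, so an early dip of the indices
below 1 followed by recovery is intrinsic model behaviour, not a defect.

## Default concentration tables (synthetic)

The per-organ min/max concentration curves are **synthetic defaults**,
not measured calibration data: the measured tables live in unpublished
supplementary material. The shipped curves are plausible cassava values
assembled from the general tissue-analysis literature — leaves 4.0–5.8%
N, 0.30–0.45% P, 1.4–2.0% K at the maximum, storage roots an order of
magnitude more dilute, all declining with thermal time — with the
*minimum* taken as an acute-deficiency floor at roughly 15–20% of the
maximum, following the dilution-curve convention that lethal minima sit
far below critical concentrations. Setting the floors higher (e.g. at
40% of maximum) makes the nutrition indices so punitive that the canopy
never establishes; the chosen floors reproduce the qualitative behaviour
a working parameterization shows: an early sub-optimal dip, mid-season
sufficiency of N and P under full fertilization, and late-season K
limitation. Override the tables (config key `tables`/`tables_csv`) for
any quantitative site-specific application.

## Soil water

A single-layer tipping bucket deepens with root growth (0.012 m d⁻¹ to
3.2 m; soil newly reached enters at a configured subsoil moisture, and
that inflow is an explicit budget term so daily closure is exact). Rain
infiltrates up to field capacity; the excess drains the same day.
Reference ET is a fixed coefficient (0.25 mm per MJ m⁻²) on global
radiation, split into potential transpiration and soil evaporation by
canopy cover. TRANRF ramps linearly from 0 at wilting point to 1 at a
critical content set halfway between wilting point and field capacity
(the crop transpiration-coefficient convention, exposed in config);
evaporation is limited by water above air-dry. Dormancy arms when
root-zone water falls below 5% of the plant-available range while
LAI < 0.75, and releases above 25%. A per-day TRANRF override series
bypasses the bucket bit-exactly for testing. With the default deep
profile and the wet synthetic season the crop is essentially never
water-stressed (TRANRF = 1 on ≥ 95% of days), emulating a no-drought
calibration season; water-stress behaviour is exercised on shallow-soil
configurations and the dry-spell weather profile.

## Synthetic weather

The generator produces a humid-tropical series from a seeded RNG:
temperatures 21–33 °C with a small annual cycle, radiation 14–20 MJ m⁻²
d⁻¹, and rainfall from a gamma-depth wet/dry day process modulated by an
annual cycle with the wet peak at planting. The "wet" profile totals
≈ 2,800–3,800 mm over 420 days with a mild mid-season dry period; the
"dry-spell" profile additionally suppresses rain to 2% in a fixed 80-day
mid-season window. The generator does not emulate real-weather
autocorrelation beyond the annual cycle, extreme events, or
radiation–rain coupling; passing tests therefore demonstrate model
behaviour under plausible forcing, not site fidelity.

## Treatments and scenarios

The scenario battery is a 12-treatment NPK factorial (0–300 kg N, 0–100
kg P, 0–300 kg K ha⁻¹: control, three single omissions, a K ladder at
full NP, and reduced-rate combinations), applied as two splits at 30 and
90 days (P basal with the first split). The default site supply is the
humid rainforest-transition calibration site (control-plot uptakes
194.2/19.9/88.0 kg N/P/K ha⁻¹; extras 62.7/11.5 kg N/P ha⁻¹). For
omission batteries the site's 2016 extra-K measurement (−27.9 ± 26.1 kg
ha⁻¹, i.e. noise) is replaced by the same site's 2017 value (+7.2 kg
ha⁻¹): a positive extra supply of the omitted nutrient is the model's
only mechanism distinguishing an omission treatment from the control on
a K-limited site, and the negative value is physically meaningless.

## Calibration and evaluation

The calibration fits (K_NI, KMAX, TSUM_NPKI) by minimising Σ over
{storage-root DM, N, P, K uptake} of RMSE normalised by each variable's
observed mean (the variables are otherwise incommensurate; no weighting
scheme is implied by the data). The search is a deterministic coarse
grid (K_NI ∈ {1…11}, KMAX ∈ {4, 7, 10}, TSUM_NPKI ∈ {172, 272, 372})
followed by Nelder–Mead refinement of K_NI and TSUM_NPKI from the best
grid point. KMAX is intentionally not refined: it enters the model only
through the branch condition K_NI ≤ KMAX, so within a branch the
objective is exactly flat in KMAX; it is selected on the grid with ties
broken toward the lexicographically smallest triple. For the same reason
KMAX is identifiable only up to the branch it selects. TSUM_NPKI is
piecewise-constant in the objective (the gate can only move in daily
thermal-time steps of ~12–15 °C·d), so its recovered value is exact only
to that resolution. Evaluation reports RMSEP, R² and the OLS slope of
simulated on observed (slope ≈ 1 ⇒ unbiased; the regression orientation
is a convention and does not affect R²), optionally excluding the four
treatments whose uptakes define the soil-supply inputs.

Synthetic observations sample the simulator at ~4/8/14 months after
planting with multiplicative lognormal noise of a given CV (mean-one
parameterization).

## Problem sizes

The shipped tests and scripts use 420-day seasons, 5–12-treatment
batteries and a calibration with 3 treatments × ~170 objective
evaluations; one season simulates in ~70 ms, the full suite in ~90 s and
the calibration in ~30 s.

## Known limitations

- The concentration tables, base-crop block (RUE, SLA, k, phenology,
  partitioning) and soil-water constants are defensible defaults, not a
  fitted parameterization; quantitative site work must override them.
- No VPD/stomatal response; all drought action is through TRANRF.
- No nutrient effect on shoot-internal partitioning; no RUE response to
  leaf nutrient status (all nutrient stress routes through NPKI).
- No litter/soil recycling of fallen-leaf nutrients within the season
  (dead leaves are stripped of nutrients at death by construction).
- Fine roots share the shoot-derived concentration-table structure; no
  organ-specific measurements back their curves.
- Extra supply activation is binary in the other two nutrients'
  presence (config-scalable); the true dependence on their rates is
  unknown.
- Single soil layer, same-day drainage, no runoff or capillary rise.
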