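"""Model configuration: parameters, concentration lookup tables, scenarios.

All internal state is carried in g m-2 (areal mass) and g g-1 DM
(concentration).  Field units of kg ha-1 are accepted only at the I/O
boundary and converted on entry (1 kg ha-1 = 0.1 g m-2).

The nutrient-limitation constants keep their conventional upper-case names
(``RDRNS``, ``TSUM_NPKI``, ``FR_MAX``, ``Rec_N`` ...) so that configuration
files read like the agronomy literature they come from.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

NUTRIENTS = ("N", "P", "K")
#: plant organs tracked by the model: green leaf, stem, storage organ, fine root
ORGANS = ("leaf", "stem", "storage", "root")

KG_HA_PER_G_M2 = 10.0


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


def kg_ha_to_g_m2(value: float) -> float:
    """Convert an areal mass from kg ha-1 to g m-2 (exact factor 10)."""
    return value / KG_HA_PER_G_M2


def g_m2_to_kg_ha(value: float) -> float:
    """Convert an areal mass from g m-2 to kg ha-1 (exact factor 10)."""
    return value * KG_HA_PER_G_M2


_QUANTITY_RE = re.compile(
    r"^\s*(?P<num>[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s*(?P<unit>.*?)\s*$"
)

_AREAL_UNITS = {
    "": 1.0,
    "g/m2": 1.0,
    "g m-2": 1.0,
    "g_per_m2": 1.0,
    "kg/ha": 1.0 / KG_HA_PER_G_M2,
    "kg ha-1": 1.0 / KG_HA_PER_G_M2,
    "kg_per_ha": 1.0 / KG_HA_PER_G_M2,
}


def parse_areal_mass(value) -> float:
    """Parse an areal mass given as a number (g m-2) or a tagged string.

    Accepted unit tags: ``g/m2``, ``g m-2``, ``kg/ha``, ``kg ha-1`` (with an
    optional nutrient symbol, e.g. ``"194.2 kg N ha-1"``).
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANTITY_RE.match(str(value))
    if not m:
        raise ConfigError(f"cannot parse quantity {value!r}")
    unit = m.group("unit")
    # drop an embedded nutrient symbol: "kg N ha-1" -> "kg ha-1"
    unit = re.sub(r"\b[NPK]\b\s*", "", unit).strip()
    unit = unit.replace("⁻¹", "-1").replace("ha−1", "ha-1")
    if unit not in _AREAL_UNITS:
        raise ConfigError(f"unknown unit tag {unit!r} in {value!r}")
    return float(m.group("num")) * _AREAL_UNITS[unit]


# ---------------------------------------------------------------------------
# concentration lookup tables
# ---------------------------------------------------------------------------


class ConcentrationTable:
    """Minimum/maximum nutrient concentrations per organ vs. thermal time.

    For each (organ, nutrient) pair the table holds breakpoints
    ``(tsum, cmin, cmax)`` in degC d and g g-1 DM.  Between breakpoints the
    concentrations are linearly interpolated; beyond the ends they are held
    constant.  Concentrations decline with thermal time (nutrient dilution
    as structural carbon accumulates).
    """

    def __init__(self, entries: Mapping[tuple[str, str], Sequence[tuple[float, float, float]]]):
        self._tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, rows in entries.items():
            organ, nutrient = key
            if organ not in ORGANS:
                raise ConfigError(f"unknown organ {organ!r} in concentration table")
            if nutrient not in NUTRIENTS:
                raise ConfigError(f"unknown nutrient {nutrient!r} in concentration table")
            rows = sorted(rows)
            tsum = np.asarray([r[0] for r in rows], dtype=float)
            cmin = np.asarray([r[1] for r in rows], dtype=float)
            cmax = np.asarray([r[2] for r in rows], dtype=float)
            if len(tsum) == 0:
                raise ConfigError(f"empty concentration table for {key}")
            if np.any(np.diff(tsum) <= 0):
                raise ConfigError(f"TSUM breakpoints not strictly increasing for {key}")
            if np.any(cmin > cmax):
                raise ConfigError(f"cmin > cmax in concentration table for {key}")
            if np.any(cmin < 0):
                raise ConfigError(f"negative concentration in table for {key}")
            self._tables[(organ, nutrient)] = (tsum, cmin, cmax)
        for organ in ORGANS:
            for nutrient in NUTRIENTS:
                if (organ, nutrient) not in self._tables:
                    raise ConfigError(f"concentration table missing entry ({organ}, {nutrient})")

    def interpolate(self, organ: str, nutrient: str, tsum: float) -> tuple[float, float]:
        """Return ``(cmin, cmax)`` at a thermal time, clamped at table ends."""
        try:
            xs, cmin, cmax = self._tables[(organ, nutrient)]
        except KeyError:
            raise KeyError(f"no concentration table for organ={organ!r} nutrient={nutrient!r}")
        # np.interp holds the end values outside the breakpoint range
        return float(np.interp(tsum, xs, cmin)), float(np.interp(tsum, xs, cmax))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (organ, nutrient), (xs, cmin, cmax) in sorted(self._tables.items()):
            for t, lo, hi in zip(xs, cmin, cmax):
                rows.append({"organ": organ, "nutrient": nutrient,
                             "tsum": t, "cmin": lo, "cmax": hi})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConcentrationTable":
        required = {"organ", "nutrient", "tsum", "cmin", "cmax"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigError(f"concentration CSV missing columns: {sorted(missing)}")
        entries: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
        for _, row in frame.iterrows():
            entries.setdefault((row["organ"], row["nutrient"]), []).append(
                (float(row["tsum"]), float(row["cmin"]), float(row["cmax"])))
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        return cls.from_frame(pd.read_csv(path))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        if set(self._tables) != set(other._tables):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._tables[k], other._tables[k]))
            for k in self._tables
        )


def default_concentration_table() -> ConcentrationTable:
    """Built-in min/max concentration curves (synthetic defaults).

    These breakpoints are plausible dilution curves assembled from the
    general cassava tissue-analysis literature, NOT measured calibration
    data: leaves are N-rich (2-6% N), storage organs dilute strongly, and
    all concentrations decline with thermal time.  They make the model
    self-contained for synthetic experiments; override them (``tables:``
    key or a CSV) for any quantitative site-specific work.
    """
    # (tsum, cmin, cmax) in degC d and g g-1 DM; cmin is the acute-deficiency
    # floor, far below the critical concentration (dilution-curve convention,
    # roughly 15-20% of the maximum), not a near-optimal value
    entries = {
        ("leaf", "N"): [(0, 0.010, 0.058), (1000, 0.009, 0.054),
                        (3000, 0.008, 0.048), (6000, 0.007, 0.040)],
        ("leaf", "P"): [(0, 0.0008, 0.0045), (1000, 0.0007, 0.0040),
                        (3000, 0.0006, 0.0034), (6000, 0.0005, 0.0030)],
        ("leaf", "K"): [(0, 0.0035, 0.020), (1000, 0.0032, 0.018),
                        (3000, 0.0028, 0.016), (6000, 0.0025, 0.014)],
        ("stem", "N"): [(0, 0.0035, 0.020), (1000, 0.0030, 0.017),
                        (3000, 0.0025, 0.014), (6000, 0.0021, 0.012)],
        ("stem", "P"): [(0, 0.00045, 0.0025), (1000, 0.00038, 0.0021),
                        (3000, 0.00032, 0.0018), (6000, 0.00027, 0.0015)],
        ("stem", "K"): [(0, 0.0032, 0.018), (1000, 0.0029, 0.016),
                        (3000, 0.0025, 0.014), (6000, 0.0021, 0.012)],
        ("storage", "N"): [(0, 0.0014, 0.008), (1000, 0.0013, 0.0075),
                           (3000, 0.0012, 0.0067), (6000, 0.0011, 0.006)],
        ("storage", "P"): [(0, 0.00021, 0.0012), (1000, 0.00020, 0.0011),
                           (3000, 0.00018, 0.0010), (6000, 0.00017, 0.0010)],
        ("storage", "K"): [(0, 0.0021, 0.012), (1000, 0.0020, 0.0115),
                           (3000, 0.0019, 0.0107), (6000, 0.0018, 0.010)],
        ("root", "N"): [(0, 0.0027, 0.015), (1000, 0.0023, 0.013),
                        (3000, 0.0020, 0.011), (6000, 0.0018, 0.010)],
        ("root", "P"): [(0, 0.00032, 0.0018), (1000, 0.00029, 0.0016),
                        (3000, 0.00025, 0.0014), (6000, 0.00022, 0.0012)],
        ("root", "K"): [(0, 0.0021, 0.012), (1000, 0.0019, 0.011),
                        (3000, 0.0016, 0.009), (6000, 0.0014, 0.008)],
    }
    return ConcentrationTable(entries)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class CropParameters:
    """Base-crop block: light use, phenology, partitioning, senescence.

    Defaults describe a generic high-yielding cassava variety in the humid
    tropics; the values are configuration entries, not calibrated constants.
    """

    RUE: float = 2.4             # g DM MJ-1 intercepted PAR
    k: float = 0.7               # canopy light extinction coefficient
    SLA: float = 0.018           # m2 leaf g-1 DM
    base_temperature: float = 13.0   # degC, threshold for thermal time
    TSUM_sprouting: float = 125.0    # degC d, planting -> sprouting
    TSUM_branching: float = 900.0    # degC d, sprouting -> first branching
    #: partitioning of new dry matter vs TSUM: (tsum, leaf, stem, storage, root)
    partitioning_table: tuple = (
        (0.0, 0.43, 0.32, 0.00, 0.25),
        (300.0, 0.43, 0.32, 0.05, 0.20),
        (900.0, 0.36, 0.32, 0.22, 0.10),
        (1800.0, 0.25, 0.28, 0.42, 0.05),
        (3000.0, 0.13, 0.22, 0.62, 0.03),
        (4500.0, 0.06, 0.14, 0.78, 0.02),
        (6500.0, 0.02, 0.08, 0.89, 0.01),
    )
    RDR_base: float = 0.008      # d-1 background leaf senescence after onset
    RDR_TSUM_onset: float = 1200.0  # degC d before which no background senescence
    root_boost: float = 0.5      # stress modifier constant for fine-root partitioning
    max_root_fraction: float = 0.6
    initial_biomass: float = 25.0    # g DM m-2 mobilised from the planted cuttings
    cutting_conc: dict = field(default_factory=lambda: {"N": 0.025, "P": 0.003, "K": 0.018})
    dormancy_lai: float = 0.75       # LAI below which drought can trigger dormancy
    regrowth_fraction: float = 0.05  # storage-root fraction remobilised after dormancy

    def validate(self) -> None:
        for name in ("RUE", "k", "SLA", "TSUM_sprouting", "TSUM_branching",
                     "RDR_base", "initial_biomass"):
            if getattr(self, name) < 0:
                raise ConfigError(f"crop parameter {name} must be >= 0")
        if not 0 <= self.regrowth_fraction <= 1:
            raise ConfigError("regrowth_fraction must be in [0, 1]")
        for row in self.partitioning_table:
            if len(row) != 5:
                raise ConfigError("partitioning_table rows must be (tsum, 4 fractions)")
            fracs = row[1:]
            if any(f < 0 for f in fracs):
                raise ConfigError("partitioning fractions must be >= 0")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ConfigError(
                    f"partitioning fractions at TSUM {row[0]} sum to {sum(fracs)}, not 1")
        tsums = [row[0] for row in self.partitioning_table]
        if any(b <= a for a, b in zip(tsums, tsums[1:])):
            raise ConfigError("partitioning_table TSUM breakpoints must increase")


@dataclass
class SoilWaterParameters:
    """Single-layer tipping-bucket soil water block (volumetric fractions)."""

    FC: float = 0.32             # field capacity
    WP: float = 0.15             # wilting point
    SAT: float = 0.45            # saturation
    AD: float = 0.05             # air dry
    initial_theta: float = 0.32
    subsoil_theta: float = 0.32  # moisture of soil newly reached by roots
    initial_rooting_depth: float = 0.10   # m
    max_rooting_depth: float = 3.2        # m
    root_growth_rate: float = 0.012       # m d-1
    crit_fraction: float = 0.5   # critical point as fraction of (FC - WP) above WP
    et_coefficient: float = 0.25  # mm reference ET per MJ m-2 global radiation
    dormancy_water_fraction: float = 0.05  # relative content below which drought dormancy arms
    recovery_water_fraction: float = 0.25  # relative content above which dormancy releases

    def validate(self) -> None:
        if not (0 <= self.AD <= self.WP <= self.FC <= self.SAT <= 1):
            raise ConfigError("soil water fractions must satisfy AD <= WP <= FC <= SAT")
        if not self.AD <= self.initial_theta <= self.SAT:
            raise ConfigError("initial_theta outside [AD, SAT]")
        if not 0 < self.crit_fraction <= 1:
            raise ConfigError("crit_fraction must be in (0, 1]")
        for name in ("initial_rooting_depth", "max_rooting_depth",
                     "root_growth_rate", "et_coefficient"):
            if getattr(self, name) < 0:
                raise ConfigError(f"soil water parameter {name} must be >= 0")


@dataclass
class ModelParameters:
    """All model constants, nutrient-limitation block first (literature names)."""

    RDRNS: float = 0.05       # d-1, max relative leaf death rate under nutrient stress
    TSUM_NPKI: float = 272.0  # degC d before which nutrient stress does not cut growth
    FR_MAX: float = 0.8       # optimal NPK amount as fraction of the max-min span
    Rec_N: float = 0.75       # maximum fertilizer N recovery
    Rec_P: float = 0.28
    Rec_K: float = 0.70
    TC_NPK_T: float = 10.0    # d, time coefficient for NPK translocation
    K_NI: float = 6.1         # Monod constant of the combined stress index
    KMAX: float = 4.0         # branch-selection cap for K_NI
    K_WATER: float = 0.20     # Monod constant linking TRANRF to fertilizer release
    RNE: float = 0.012        # d-1, maximum nutrient-equivalent uptake rate
    rf_N: float = 0.1         # d-1, relative fertilizer release rates
    rf_P: float = 0.01
    rf_K: float = 0.04
    DELT: float = 1.0         # d, integration step (fixed daily)
    crop: CropParameters = field(default_factory=CropParameters)
    soil_water: SoilWaterParameters = field(default_factory=SoilWaterParameters)
    tables: ConcentrationTable = field(default_factory=default_concentration_table)

    def rec(self, nutrient: str) -> float:
        return getattr(self, f"Rec_{nutrient}")

    def rf(self, nutrient: str) -> float:
        return getattr(self, f"rf_{nutrient}")

    def validate(self) -> None:
        for name in ("RDRNS", "TSUM_NPKI", "TC_NPK_T", "RNE",
                     "rf_N", "rf_P", "rf_K"):
            if getattr(self, name) < 0:
                raise ConfigError(f"parameter {name} must be >= 0")
        if not 0 <= self.FR_MAX <= 1:
            raise ConfigError(f"FR_MAX must be in [0, 1], got {self.FR_MAX}")
        for nutrient in NUTRIENTS:
            rec = self.rec(nutrient)
            if not 0 <= rec <= 1:
                raise ConfigError(f"Rec_{nutrient} must be in [0, 1], got {rec}")
        if self.K_NI <= 0:
            raise ConfigError(f"K_NI must be > 0, got {self.K_NI}")
        if self.K_WATER <= 0:
            raise ConfigError(f"K_WATER must be > 0, got {self.K_WATER}")
        if self.DELT != 1.0:
            raise ConfigError("DELT is fixed at 1 d")
        self.crop.validate()
        self.soil_water.validate()


# ---------------------------------------------------------------------------
# site supply, fertilizer schedule, scenario
# ---------------------------------------------------------------------------


@dataclass
class SiteSupply:
    """Indigenous soil NPK supply for one site-season (g m-2).

    ``base_*`` is the uptake measured in unfertilized control plots;
    ``extra_*`` the additional uptake of the omitted nutrient measured in
    omission plots where the other two nutrients were applied.  Negative
    measured extras (sampling noise) are clamped to zero with a warning.
    """

    base_N: float
    base_P: float
    base_K: float
    extra_N: float = 0.0
    extra_P: float = 0.0
    extra_K: float = 0.0

    def __post_init__(self):
        for name in ("base_N", "base_P", "base_K"):
            if getattr(self, name) < 0:
                raise ConfigError(f"site supply {name} must be >= 0")
        for name in ("extra_N", "extra_P", "extra_K"):
            value = getattr(self, name)
            if value < 0:
                warnings.warn(
                    f"measured {name} = {value} g m-2 is negative; clamped to 0",
                    stacklevel=2)
                setattr(self, name, 0.0)

    def base(self, nutrient: str) -> float:
        return getattr(self, f"base_{nutrient}")

    def extra(self, nutrient: str) -> float:
        return getattr(self, f"extra_{nutrient}")


@dataclass(frozen=True)
class FertilizerEvent:
    """One fertilizer application (supports split applications)."""

    day: int                  # day after planting
    amount_N: float = 0.0     # g m-2
    amount_P: float = 0.0
    amount_K: float = 0.0

    def __post_init__(self):
        if self.day < 0:
            raise ConfigError("fertilizer event day must be >= 0")
        for name in ("amount_N", "amount_P", "amount_K"):
            if getattr(self, name) < 0:
                raise ConfigError(f"fertilizer {name} must be >= 0")

    def amount(self, nutrient: str) -> float:
        return getattr(self, f"amount_{nutrient}")


@dataclass
class Scenario:
    """One simulated site-season: supply, schedule, season, weather source."""

    name: str
    supply: SiteSupply
    schedule: tuple = ()              # FertilizerEvent, sorted by day
    season_length: int = 420          # d, planting to harvest (SL)
    planting_date: str = "2016-05-24"
    weather_path: str | None = None   # CSV path; None = caller passes weather
    #: optional per-day TRANRF override (test hook, bit-exact pass-through)
    tranrf_override: tuple | None = None
    #: 0-1 scaling of the omission-derived extra supply activation rule
    extra_supply_scale: float = 1.0

    def __post_init__(self):
        if self.season_length <= 0:
            raise ConfigError("season_length must be > 0")
        if not 0 <= self.extra_supply_scale <= 1:
            raise ConfigError("extra_supply_scale must be in [0, 1]")
        self.schedule = tuple(sorted(self.schedule, key=lambda e: e.day))

    def total_applied(self, nutrient: str) -> float:
        return sum(e.amount(nutrient) for e in self.schedule)


# ---------------------------------------------------------------------------
# config file I/O
# ---------------------------------------------------------------------------

_TABLE1_KEYS = ("RDRNS", "TSUM_NPKI", "FR_MAX", "Rec_N", "Rec_P", "Rec_K",
                "TC_NPK_T", "K_NI", "KMAX", "K_WATER", "RNE",
                "rf_N", "rf_P", "rf_K", "DELT")


def load_config(path) -> tuple[ModelParameters, Scenario]:
    """Read a YAML configuration file into a validated parameter set and scenario.

    Missing optional fields fall back to the package defaults.  Site supply
    and fertilizer amounts accept unit-tagged strings (``"194.2 kg N ha-1"``)
    or bare numbers in g m-2.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    params_raw = dict(raw.get("parameters", {}))
    unknown = set(params_raw) - set(_TABLE1_KEYS)
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = {k: float(v) for k, v in params_raw.items()}
    crop = CropParameters(**_coerce_block(raw.get("crop", {}), CropParameters))
    soil_water = SoilWaterParameters(
        **_coerce_block(raw.get("soil_water", {}), SoilWaterParameters))
    if "tables" in raw:
        tables = ConcentrationTable.from_frame(pd.DataFrame(raw["tables"]))
    elif "tables_csv" in raw:
        tables = ConcentrationTable.from_csv(path.parent / raw["tables_csv"])
    else:
        tables = default_concentration_table()
    params = ModelParameters(crop=crop, soil_water=soil_water, tables=tables, **kwargs)
    params.validate()

    sup_raw = dict(raw.get("site_supply", {}))
    sup_kwargs = {k: parse_areal_mass(v) for k, v in sup_raw.items()}
    for key in ("base_N", "base_P", "base_K"):
        sup_kwargs.setdefault(key, 0.0)
    supply = SiteSupply(**sup_kwargs)

    schedule = []
    for ev in raw.get("fertilizer", []):
        schedule.append(FertilizerEvent(
            day=int(ev["day"]),
            amount_N=parse_areal_mass(ev.get("N", 0.0)),
            amount_P=parse_areal_mass(ev.get("P", 0.0)),
            amount_K=parse_areal_mass(ev.get("K", 0.0))))

    scen_raw = dict(raw.get("scenario", {}))
    scenario = Scenario(
        name=scen_raw.get("name", path.stem),
        supply=supply,
        schedule=tuple(schedule),
        season_length=int(scen_raw.get("season_length", 420)),
        planting_date=str(scen_raw.get("planting_date", "2016-05-24")),
        weather_path=scen_raw.get("weather"),
        extra_supply_scale=float(scen_raw.get("extra_supply_scale", 1.0)),
    )
    return params, scenario


def _coerce_block(block: Mapping, cls) -> dict:
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    out = {}
    for k, v in block.items():
        if k == "partitioning_table":
            out[k] = tuple(tuple(float(x) for x in row) for row in v)
        elif k == "cutting_conc":
            out[k] = {n: float(v[n]) for n in NUTRIENTS}
        else:
            out[k] = float(v) if isinstance(v, (int, float, str)) else v
    return out


def save_config(path, params: ModelParameters, scenario: Scenario) -> None:
    """Write a configuration file that ``load_config`` reads back identically."""
    doc = {
        "parameters": {k: getattr(params, k) for k in _TABLE1_KEYS},
        "crop": _plain(asdict(params.crop)),
        "soil_water": _plain(asdict(params.soil_water)),
        "tables": _plain(params.tables.to_frame().to_dict(orient="list")),
        "site_supply": {k: getattr(scenario.supply, k)
                        for k in ("base_N", "base_P", "base_K",
                                  "extra_N", "extra_P", "extra_K")},
        "fertilizer": [{"day": e.day, "N": e.amount_N, "P": e.amount_P, "K": e.amount_K}
                       for e in scenario.schedule],
        "scenario": {
            "name": scenario.name,
            "season_length": scenario.season_length,
            "planting_date": scenario.planting_date,
            **({"weather": scenario.weather_path} if scenario.weather_path else {}),
            "extra_supply_scale": scenario.extra_supply_scale,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
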