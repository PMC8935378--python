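"""Calibration of the stress-index constants and model evaluation metrics.

Three constants of the combined nutrient stress index are fitted jointly —
the Monod constant K_NI, its branch cap KMAX and the thermal-time gate
TSUM_NPKI — by minimizing the summed root-mean-square error between
observed and simulated storage-root dry matter and whole-plant N, P and K
uptakes, each RMSE normalized by the observed mean of its variable so the
four terms are commensurate.  The search is a deterministic coarse grid
followed by Nelder-Mead refinement of the continuously identifiable
parameters (K_NI, TSUM_NPKI); KMAX enters the model only through the
branch condition K_NI <= KMAX, so it is selected on the grid, with ties
broken toward the lexicographically smallest (K_NI, KMAX, TSUM_NPKI).

Evaluation reports RMSEP, the coefficient of determination R2 and the
slope of the ordinary-least-squares line of simulated on observed values
(slope near 1 = little bias), per variable, optionally excluding the
treatments that were used to estimate the soil supply terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import optimize

from .config import ModelParameters
from .engine import simulate
from .treatments import SUPPLY_ESTIMATION_TREATMENTS

#: observation variables: DailyRecord column per observable
VARIABLES = {
    "storage_root_dm": "W_storage",
    "N_uptake": "Act_N",
    "P_uptake": "Act_P",
    "K_uptake": "Act_K",
    "leaf_dm": "W_leaf",
    "stem_dm": "W_stem",
}

#: variables entering the calibration objective
CALIBRATION_VARIABLES = ("storage_root_dm", "N_uptake", "P_uptake", "K_uptake")

#: default sampling days (~4, 8 and 14 months after planting)
DEFAULT_SAMPLE_DAYS = (120, 240, 419)

OBSERVATION_COLUMNS = ("treatment", "dap", "variable", "value")


def rmse(observed, simulated) -> float:
    """Root mean square error between two equal-length value sequences."""
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if observed.shape != simulated.shape:
        raise ValueError("observed and simulated must have equal length")
    if observed.size == 0:
        raise ValueError("rmse of empty input")
    return float(np.sqrt(np.mean((observed - simulated) ** 2)))


def validate_observations(observations: pd.DataFrame) -> pd.DataFrame:
    missing = set(OBSERVATION_COLUMNS) - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    if (observations["value"] < 0).any():
        raise ValueError("negative observation value")
    keys = observations[["treatment", "dap", "variable"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(f"duplicate observation key {tuple(dup)}")
    return observations


def match_pairs(records: dict, observations: pd.DataFrame) -> pd.DataFrame:
    """Join observations with simulated values at the same treatment and day.

    ``records`` maps treatment name -> daily output frame.  Returns the
    observation rows with an added ``simulated`` column; observations for
    unknown treatments/variables or days outside the run are dropped.
    """
    rows = []
    for _, obs in observations.iterrows():
        frame = records.get(obs["treatment"])
        if frame is None or obs["variable"] not in VARIABLES:
            continue
        day = int(obs["dap"])
        sel = frame.loc[frame["day"] == day, VARIABLES[obs["variable"]]]
        if sel.empty:
            continue
        rows.append({**obs, "simulated": float(sel.iloc[0])})
    return pd.DataFrame(rows)


def evaluate(records: dict, observations: pd.DataFrame,
             exclude_supply_treatments: bool = False) -> pd.DataFrame:
    """Per-variable RMSEP, R2 and slope of simulated-vs-observed.

    With ``exclude_supply_treatments`` the treatments whose uptakes define
    the soil supply inputs (control and the three single omissions) are
    removed from the pairing before computing the metrics.
    """
    observations = validate_observations(observations)
    if exclude_supply_treatments:
        observations = observations[
            ~observations["treatment"].isin(SUPPLY_ESTIMATION_TREATMENTS)]
    pairs = match_pairs(records, observations)
    if pairs.empty:
        raise ValueError("no matched observation/simulation pairs")
    out = []
    for variable, group in pairs.groupby("variable"):
        if len(group) < 2:
            continue
        obs = group["value"].to_numpy(dtype=float)
        sim = group["simulated"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(obs, sim, 1)
        predicted = slope * obs + intercept
        ss_res = float(np.sum((sim - predicted) ** 2))
        ss_tot = float(np.sum((sim - np.mean(sim)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        out.append({"variable": variable, "n": len(group),
                    "RMSEP": rmse(obs, sim), "R2": r2, "slope": float(slope)})
    return pd.DataFrame(out).set_index("variable")


# ---------------------------------------------------------------------------
# synthetic observations
# ---------------------------------------------------------------------------


def generate_synthetic_observations(params: ModelParameters, scenarios: dict,
                                    weather, noise_cv: float = 0.0,
                                    seed: int = 0,
                                    sample_days=DEFAULT_SAMPLE_DAYS,
                                    variables=CALIBRATION_VARIABLES) -> pd.DataFrame:
    """Sample the simulator at harvest-like days, with multiplicative noise.

    Noise is lognormal with coefficient of variation ``noise_cv`` (0 gives
    the simulator outputs exactly); reproducible for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    rows = []
    for name, scenario in scenarios.items():
        frame = simulate(params, scenario, weather)
        for day in sample_days:
            sel = frame[frame["day"] == int(day)]
            if sel.empty:
                raise ValueError(f"sample day {day} outside the simulated season")
            for variable in variables:
                value = float(sel[VARIABLES[variable]].iloc[0])
                if noise_cv > 0:
                    value *= float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
                rows.append({"treatment": name, "dap": int(day),
                             "variable": variable, "value": value})
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    K_NI: float
    KMAX: float
    TSUM_NPKI: float
    objective: float
    per_variable_rmse: dict
    trace: list = field(default_factory=list)   # (K_NI, KMAX, TSUM_NPKI, objective)


DEFAULT_BOUNDS = {"K_NI": (1.0, 12.0), "KMAX": (4.0, 10.0), "TSUM_NPKI": (150.0, 400.0)}
GRID_POINTS = {"K_NI": (1.0, 3.5, 6.0, 8.5, 11.0),
               "KMAX": (4.0, 7.0, 10.0),
               "TSUM_NPKI": (172.0, 272.0, 372.0)}


def _objective(triple, params, scenarios, weather, observations, means, trace):
    k_ni, kmax, tsum_npki = triple
    candidate = replace(params, K_NI=float(k_ni), KMAX=float(kmax),
                        TSUM_NPKI=float(tsum_npki))
    try:
        records = {name: simulate(candidate, scen, weather)
                   for name, scen in scenarios.items()}
    except Exception:
        trace.append((float(k_ni), float(kmax), float(tsum_npki), float("inf")))
        return float("inf"), {}
    pairs = match_pairs(records, observations)
    per_var = {}
    total = 0.0
    for variable in CALIBRATION_VARIABLES:
        group = pairs[pairs["variable"] == variable]
        if group.empty:
            continue
        err = rmse(group["value"], group["simulated"])
        per_var[variable] = err
        total += err / means[variable] if means[variable] > 0 else err
    trace.append((float(k_ni), float(kmax), float(tsum_npki), total))
    return total, per_var


def calibrate(params: ModelParameters, scenarios: dict, weather,
              observations: pd.DataFrame, bounds: dict | None = None,
              grid: dict | None = None, xatol: float = 0.02,
              fatol: float = 1e-8) -> FitResult:
    """Fit (K_NI, KMAX, TSUM_NPKI) to observations by grid + simplex search.

    Deterministic given its inputs.  The coarse grid scans all three
    parameters; Nelder-Mead then refines K_NI and TSUM_NPKI from the best
    grid point, with KMAX fixed at its grid-best value (the model output
    depends on KMAX only through the branch condition, so within a branch
    the objective is flat in KMAX and ties go to the smallest value).
    """
    observations = validate_observations(observations)
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    grid = dict(GRID_POINTS, **(grid or {}))
    for key in ("K_NI", "KMAX", "TSUM_NPKI"):
        lo, hi = bounds[key]
        if any(not lo <= g <= hi for g in grid[key]):
            raise ValueError(f"grid for {key} outside bounds {bounds[key]}")

    means = {}
    for variable in CALIBRATION_VARIABLES:
        sel = observations.loc[observations["variable"] == variable, "value"]
        means[variable] = float(sel.mean()) if not sel.empty else 0.0

    trace: list = []
    best_triple, best_value = None, float("inf")
    for k_ni in grid["K_NI"]:
        for kmax in grid["KMAX"]:
            for tsum_npki in grid["TSUM_NPKI"]:
                triple = (k_ni, kmax, tsum_npki)
                value, _ = _objective(triple, params, scenarios, weather,
                                      observations, means, trace)
                if value < best_value or (value == best_value
                                          and (best_triple is None or triple < best_triple)):
                    best_triple, best_value = triple, value

    k_ni0, kmax_best, tsum0 = best_triple

    def refine(x):
        k_ni = min(max(x[0], bounds["K_NI"][0]), bounds["K_NI"][1])
        tsum = min(max(x[1], bounds["TSUM_NPKI"][0]), bounds["TSUM_NPKI"][1])
        value, _ = _objective((k_ni, kmax_best, tsum), params, scenarios,
                              weather, observations, means, trace)
        return value

    result = optimize.minimize(
        refine, x0=[k_ni0, tsum0], method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": 200,
                 "initial_simplex": [[k_ni0, tsum0],
                                     [k_ni0 + 1.0, tsum0],
                                     [k_ni0, tsum0 + 30.0]]})
    k_ni_fit = min(max(float(result.x[0]), bounds["K_NI"][0]), bounds["K_NI"][1])
    tsum_fit = min(max(float(result.x[1]), bounds["TSUM_NPKI"][0]),
                   bounds["TSUM_NPKI"][1])
    final_value, per_var = _objective((k_ni_fit, kmax_best, tsum_fit), params,
                                      scenarios, weather, observations, means, trace)
    if final_value <= best_value:
        fit = (k_ni_fit, kmax_best, tsum_fit, final_value)
    else:   # simplex failed to improve on the grid
        fit = (*best_triple, best_value)
        _, per_var = _objective(best_triple, params, scenarios, weather,
                                observations, means, trace)
    return FitResult(K_NI=fit[0], KMAX=fit[1], TSUM_NPKI=fit[2],
                     objective=fit[3], per_variable_rmse=per_var, trace=trace)
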