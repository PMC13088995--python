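"""Exposure-response: concentrations -> attributable deaths per stratum.

Two functional forms cover the ten disease-pollutant categories:

* GEMM (Global Exposure Mortality Model) for the six PM2.5 causes
  (stroke, lung cancer, lower respiratory infections, COPD, ischemic heart
  disease, type 2 diabetes). The hazard ratio above the counterfactual
  concentration z_cf is

      z  = max(0, C - z_cf)
      HR = exp( theta * log(1 + z/alpha) / (1 + exp(-(z - mu)/nu)) )

  with cause-specific theta, alpha, mu, nu (and age-specific theta for
  ischemic heart disease and stroke).

* log-linear relative risk for the four gaseous-pollutant causes
  (cardiovascular/cerebrovascular disease from CO and SO2, respiratory
  disease from NO2 and SO2):

      RR = exp( beta * max(0, C - C0) / scale )

  where scale is the concentration increment beta refers to (10 ug/m^3 for
  SO2/NO2 rows, 1 mg/m^3 for the CO row).

Attributable deaths in a stratum follow the population attributable
fraction: deaths = count * baseline_rate * (RR - 1)/RR. PM2.5 causes apply
to ages 25+ except lower respiratory infections (all ages); gaseous causes
apply to all ages.

The packaged parameter table ships as ``data/erf_table.csv``; every
non-authoritative row (the gaseous beta values, the T2DM extension, the
age-profile theta schedule) is flagged in its ``note`` column.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from aviahealth.constants import AGE_BANDS, AGE_MIDPOINTS, DISEASES

#: GEMM counterfactual concentration, ug/m^3
Z_CF_DEFAULT = 2.4

_GROUP_COLUMNS = {
    "scenario": "scenario_id",
    "year": "year",
    "sex": "sex",
    "age_band": "age_band",
    "disease": "disease_id",
    "airport": "airport_id",
}


def load_erf_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the exposure-response parameter table (packaged default)."""
    if path is None:
        with resources.files("aviahealth").joinpath("data/erf_table.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    missing = set(DISEASES) - set(table["disease_id"])
    if missing:
        raise ValueError(f"ERF table missing diseases: {sorted(missing)}")
    return table


def _require_form(params: Mapping, form: str) -> None:
    got = params.get("form") if hasattr(params, "get") else params["form"]
    if got != form:
        raise ValueError(f"expected {form} parameters, got form={got!r}")


def gemm_hazard_ratio(C, params: Mapping) -> float | np.ndarray:
    """GEMM hazard ratio at concentration C (ug/m^3); HR = 1 at or below z_cf."""
    _require_form(params, "GEMM")
    theta = float(params["theta"])
    alpha = float(params["alpha"])
    mu = float(params["mu"])
    nu = float(params["nu"])
    z_cf = float(params.get("z_cf", Z_CF_DEFAULT))
    if alpha <= 0 or nu <= 0:
        raise ValueError("GEMM requires alpha > 0 and nu > 0")
    z = np.maximum(0.0, np.asarray(C, dtype=float) - z_cf)
    log_hr = theta * np.log1p(z / alpha) / (1.0 + np.exp(-(z - mu) / nu))
    hr = np.exp(log_hr)
    return float(hr) if np.isscalar(C) else hr


def loglinear_rr(C, params: Mapping) -> float | np.ndarray:
    """Log-linear relative risk at concentration C (ug/m^3)."""
    _require_form(params, "log-linear")
    beta = float(params["beta"])
    c0 = float(params.get("c0", 0.0))
    scale = float(params.get("beta_scale_ugm3", 10.0))
    delta = np.maximum(0.0, np.asarray(C, dtype=float) - c0)
    rr = np.exp(beta * delta / scale)
    return float(rr) if np.isscalar(C) else rr


def attributable_fraction(RR) -> float | np.ndarray:
    """Population attributable fraction (RR - 1)/RR, in [0, 1)."""
    rr = np.asarray(RR, dtype=float)
    if np.any(rr < 1.0):
        raise ValueError("attributable_fraction requires RR >= 1")
    paf = (rr - 1.0) / rr
    return float(paf) if np.isscalar(RR) else paf


def _relative_risk(C: np.ndarray, row: Mapping) -> np.ndarray:
    if row["form"] == "GEMM":
        return np.asarray(gemm_hazard_ratio(C, row))
    return np.asarray(loglinear_rr(C, row))


def _band_lower_bound(band: str) -> int:
    return int(band.split("-")[0].rstrip("+"))


def attributable_deaths(
    concentrations: pd.DataFrame,
    population: pd.DataFrame,
    baseline_rates: pd.DataFrame,
    erf_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attributable deaths per (airport, year[, scenario], disease, age, sex).

    ``concentrations`` must carry airport_id, year, pollutant, conc_ugm3 and
    optionally scenario_id. Deaths in each stratum are
    ``count * rate * PAF(RR(C))`` with the disease's functional form; causes
    with age-specific parameter rows get a band-specific RR. Strata below a
    cause's minimum age contribute zero and are omitted from the output.
    """
    erf = load_erf_table() if erf_table is None else erf_table
    has_scenario = "scenario_id" in concentrations.columns
    keys = ["airport_id", "year"] + (["scenario_id"] if has_scenario else [])

    # baseline deaths per (airport, disease, age, sex)
    base = population.merge(baseline_rates, on=["age_band", "sex"], how="left")
    missing = base[base["rate"].isna()]
    if not missing.empty:
        row = missing.iloc[0]
        raise ValueError(
            "missing baseline rate for stratum "
            f"(age_band={row['age_band']}, sex={row['sex']})")
    strata_needed = {(b, s) for b in AGE_BANDS for s in ("male", "female")}
    strata_have = set(map(tuple, population[["age_band", "sex"]].drop_duplicates().values))
    lacking = strata_needed - strata_have
    if lacking:
        raise ValueError(f"population table missing strata: {sorted(lacking)[:4]} ...")

    results = []
    for disease, rows in erf.groupby("disease_id", sort=False):
        pollutant = rows["pollutant"].iloc[0]
        conc = concentrations[concentrations["pollutant"] == pollutant]
        if conc.empty:
            continue
        c_vals = conc["conc_ugm3"].to_numpy(dtype=float)
        min_age = int(rows["min_age"].iloc[0])

        age_rows = rows[rows["age_band"].notna()]
        uniform = rows[rows["age_band"].isna()]
        rr_frames = []
        if not age_rows.empty:
            for _, prow in age_rows.iterrows():
                rr = _relative_risk(c_vals, prow)
                frame = conc[keys].copy()
                frame["age_band"] = prow["age_band"]
                frame["rr"] = rr
                rr_frames.append(frame)
            covered = set(age_rows["age_band"])
            fallback = uniform.iloc[0] if not uniform.empty else None
            for band in AGE_BANDS:
                if band in covered or _band_lower_bound(band) < min_age:
                    continue
                if fallback is None:
                    raise ValueError(
                        f"{disease}: no parameters for age band {band}")
                frame = conc[keys].copy()
                frame["age_band"] = band
                frame["rr"] = _relative_risk(c_vals, fallback)
                rr_frames.append(frame)
            rr_df = pd.concat(rr_frames, ignore_index=True)
            merge_keys = ["airport_id", "age_band"]
        else:
            rr_df = conc[keys].copy()
            rr_df["rr"] = _relative_risk(c_vals, uniform.iloc[0])
            merge_keys = ["airport_id"]

        b = base[base["disease_id"] == disease]
        b = b[b["age_band"].map(_band_lower_bound) >= min_age]
        merged = b.merge(rr_df, on=merge_keys, how="inner")
        merged["attributable_deaths"] = (
            merged["count"] * merged["rate"] * (merged["rr"] - 1.0) / merged["rr"])
        results.append(merged[keys + ["disease_id", "age_band", "sex",
                                      "attributable_deaths"]])

    if not results:
        raise ValueError("no concentration rows matched any ERF pollutant")
    out = pd.concat(results, ignore_index=True)
    order = keys + ["disease_id", "age_band", "sex"]
    return out.sort_values(order, kind="mergesort").reset_index(drop=True)


def aggregate_mortality(
    results: pd.DataFrame, by: Sequence[str] | Iterable[str] = (),
) -> pd.DataFrame:
    """Group attributable deaths by a subset of the reporting dimensions.

    ``by`` draws from {scenario, year, sex, age_band, disease, airport};
    an empty selection returns the single grand-total row. Every marginal
    sums to the same grand total by construction.
    """
    if results.empty:
        raise ValueError("results table is empty")
    by = list(by)
    unknown = [k for k in by if k not in _GROUP_COLUMNS]
    if unknown:
        raise KeyError(f"unknown grouping keys: {unknown}")
    cols = [_GROUP_COLUMNS[k] for k in by]
    for col in cols:
        if col not in results.columns:
            raise KeyError(f"results table has no column {col!r}")
    if not cols:
        return pd.DataFrame({"attributable_deaths": [results["attributable_deaths"].sum()]})
    return (results.groupby(cols, sort=True, observed=True)["attributable_deaths"]
            .sum().reset_index())


def top_airports(results: pd.DataFrame, k: int = 10,
                 scenario: str | None = None, year: int | None = None) -> pd.DataFrame:
    """Airports ranked by total attributable deaths (descending, stable)."""
    sub = results
    if scenario is not None:
        sub = sub[sub["scenario_id"] == scenario]
    if year is not None:
        sub = sub[sub["year"] == year]
    agg = aggregate_mortality(sub, ["airport"])
    agg = agg.sort_values(["attributable_deaths", "airport_id"],
                          ascending=[False, True], kind="mergesort")
    return agg.head(k).reset_index(drop=True)
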