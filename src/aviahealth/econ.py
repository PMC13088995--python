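"""Cost-benefit model of CCUS pathway adoption.

Per year and pathway:

    CAE = NA * PA        cost of alternative energy (tonnes x USD/t)
    CJF = NJ * PJ        displaced jet-fuel cost
    C   = CAE - CJF      net adoption cost
    Re  = SNC * PC       revenue: saved net carbon x carbon price
    N   = Re - C         net benefit

The carbon price is a [low, high] band, so Re and N are bands. Pathway
fuel costs PA interpolate between published 2020 and 2050 anchors; the
JET-A and carbon price series default to packaged placeholder paths
(overridable by CSV). Nominal USD throughout, no discounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aviahealth.constants import SCENARIOS

#: published per-ton fuel cost anchors (USD/t fuel) at 2020 and 2050
COST_ANCHORS: dict[str, tuple[float, float]] = {
    "DAC-CCS": (2649.90, 1144.30),
    "DAC-CCU": (7549.90, 4062.50),
    "PSC-CCS": (856.65, 697.00),
    "PSC-CCU": (4283.25, 3252.88),
}

ANCHOR_YEARS = (2020, 2050)

#: tonnes of CO2 emitted per tonne of jet fuel burnt (used to infer BAU
#: fuel service from the CO2 inventory)
JET_A_CO2_PER_TONNE = 3.16


@dataclass(frozen=True)
class CostSchedule:
    """Fuel-cost anchors for one pathway, USD per tonne of fuel."""

    scenario_id: str
    anchor_2020: float
    anchor_2050: float
    interpolation: str = "linear"  # or "exponential"

    def __post_init__(self) -> None:
        if self.anchor_2020 <= 0 or self.anchor_2050 <= 0:
            raise ValueError("cost anchors must be positive")
        if self.interpolation not in ("linear", "exponential"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


def default_cost_schedules() -> dict[str, CostSchedule]:
    return {sid: CostSchedule(sid, *COST_ANCHORS[sid]) for sid in SCENARIOS}


def cost_per_ton(scenario_id: str, year, schedule: CostSchedule | None = None):
    """PA: pathway fuel cost (USD/t) at ``year``, interpolated between anchors."""
    if schedule is None:
        try:
            schedule = default_cost_schedules()[scenario_id]
        except KeyError:
            raise KeyError(f"no cost schedule for scenario {scenario_id!r}") from None
    y = np.asarray(year, dtype=float)
    y0, y1 = ANCHOR_YEARS
    if np.any(y < y0) or np.any(y > y1):
        raise ValueError(f"year must lie within [{y0}, {y1}]")
    t = (y - y0) / (y1 - y0)
    if schedule.interpolation == "linear":
        pa = schedule.anchor_2020 + t * (schedule.anchor_2050 - schedule.anchor_2020)
    else:
        pa = schedule.anchor_2020 * (schedule.anchor_2050 / schedule.anchor_2020) ** t
    return float(pa) if np.isscalar(year) else pa


def pathway_cost(NA: float, PA: float, NJ: float, PJ: float) -> tuple[float, float, float]:
    """(CAE, CJF, C): alternative-energy cost, displaced jet-fuel cost, net cost."""
    if NA < 0 or NJ < 0:
        raise ValueError("fuel quantities must be non-negative")
    if PA <= 0 or PJ <= 0:
        raise ValueError("prices must be positive")
    cae = NA * PA
    cjf = NJ * PJ
    return cae, cjf, cae - cjf


def revenue(SNC: float, PC_min: float, PC_max: float) -> tuple[float, float]:
    """(Re_min, Re_max): saved net carbon monetized at the carbon-price band."""
    if SNC < 0:
        raise ValueError("SNC must be non-negative")
    if PC_min > PC_max:
        raise ValueError("PC_min must not exceed PC_max")
    return SNC * PC_min, SNC * PC_max


def default_price_series(years=range(2024, 2051)) -> pd.DataFrame:
    """Placeholder JET-A and carbon price paths (overridable by CSV).

    JET-A flat at 500 USD/t; carbon price rising linearly 10 -> 35 USD/t
    (low) and 15 -> 55 USD/t (high) over 2024-2050. The paths are chosen so
    the carbon price stays below the per-tonne-CO2 abatement premium of the
    cheapest pathway throughout — the regime in which pathway adoption runs
    at a net loss in every year, the qualitative configuration the packaged
    defaults encode. Non-authoritative placeholders.
    """
    years = np.asarray(list(years))
    t = (years - 2024) / (2050 - 2024)
    return pd.DataFrame({
        "year": years,
        "jet_a_price": np.full(len(years), 500.0),
        "carbon_price_low": 10.0 + t * (35.0 - 10.0),
        "carbon_price_high": 15.0 + t * (55.0 - 15.0),
    })


def load_price_series(path: str | Path) -> pd.DataFrame:
    prices = pd.read_csv(path)
    required = {"year", "jet_a_price", "carbon_price_low", "carbon_price_high"}
    missing = required - set(prices.columns)
    if missing:
        raise ValueError(f"price series missing columns: {sorted(missing)}")
    if (prices[["jet_a_price", "carbon_price_low", "carbon_price_high"]] <= 0).any().any():
        raise ValueError("prices must be positive")
    if (prices["carbon_price_low"] > prices["carbon_price_high"]).any():
        raise ValueError("carbon_price_low must not exceed carbon_price_high")
    return prices


def net_benefit(rows: pd.DataFrame) -> pd.DataFrame:
    """Complete CostBenefitRows: N band = Re band minus cost C, per year.

    ``rows`` must carry year, scenario_id, C, Re_min, Re_max (CAE/CJF pass
    through if present). Years must be unique per scenario.
    """
    required = {"year", "scenario_id", "C", "Re_min", "Re_max"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if rows.duplicated(["scenario_id", "year"]).any():
        raise ValueError("duplicate (scenario, year) rows")
    if (rows["Re_min"] > rows["Re_max"]).any():
        raise ValueError("Re_min must not exceed Re_max")
    out = rows.copy()
    out["N_min"] = out["Re_min"] - out["C"]
    out["N_max"] = out["Re_max"] - out["C"]
    return out


def scenario_cost_benefit(
    bau: pd.DataFrame,
    scenario_inventory: pd.DataFrame,
    spec,
    prices: pd.DataFrame | None = None,
    schedule: CostSchedule | None = None,
    years=None,
    co2_per_tonne_fuel: float = JET_A_CO2_PER_TONNE,
) -> pd.DataFrame:
    """Full cost-benefit table for one scenario over ``years``.

    BAU fuel service per year is inferred from the BAU CO2 inventory
    (CO2 mass / co2_per_tonne_fuel); the deployment ramp then sets the
    alternative-energy and displaced-JET-A tonnages NA = NJ = f * fuel.
    """
    from aviahealth.scenario_engine import co2_saved, fuel_quantities

    prices = default_price_series() if prices is None else prices
    if schedule is None:
        schedule = default_cost_schedules()[spec.scenario_id]
    if years is None:
        years = sorted(bau["year"].unique())
    price_idx = prices.set_index("year")

    bau_co2 = (bau[bau["pollutant"] == "CO2"]
               .groupby("year")["mass_tonnes"].sum())
    records = []
    for year in years:
        if year not in price_idx.index:
            raise ValueError(f"no price data for year {year}")
        fuel = float(bau_co2.loc[year]) / co2_per_tonne_fuel
        na, nj = fuel_quantities(fuel, spec, year)
        pa = cost_per_ton(spec.scenario_id, year, schedule)
        pj = float(price_idx.loc[year, "jet_a_price"])
        cae, cjf, c = pathway_cost(na, pa, nj, pj)
        snc = co2_saved(bau, scenario_inventory, spec, year)
        re_min, re_max = revenue(
            snc,
            float(price_idx.loc[year, "carbon_price_low"]),
            float(price_idx.loc[year, "carbon_price_high"]))
        records.append({
            "year": year, "scenario_id": spec.scenario_id,
            "NA": na, "NJ": nj, "PA": pa, "PJ": pj, "SNC": snc,
            "CAE": cae, "CJF": cjf, "C": c,
            "Re_min": re_min, "Re_max": re_max,
        })
    columns = ["year", "scenario_id", "NA", "NJ", "PA", "PJ", "SNC",
               "CAE", "CJF", "C", "Re_min", "Re_max"]
    return net_benefit(pd.DataFrame.from_records(records, columns=columns))
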