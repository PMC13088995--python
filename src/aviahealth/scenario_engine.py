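"""CCUS scenario construction.

Four pathways are assessed against a business-as-usual (BAU) inventory:
capture mode DAC (direct air capture) or PSC (point-source capture at a
waste-to-energy plant), crossed with fate CCS (geological storage) or CCU
(conversion to synthetic jet fuel). Adoption is zero at the start year and
ramps linearly to full deployment by the end year.

Local pollutants scale with a per-pathway multiplier kappa interpolated by
the deployment fraction; CO2 is handled by the fate rule: CCS leaves source
emissions unchanged but books an offset stream (captured elsewhere), CCU
replaces the deployed fraction of fossil CO2 with synthetic-fuel CO2 whose
net contribution is governed by a carbon-neutrality factor. The saved net
carbon (SNC) relative to BAU is what the revenue side of the cost-benefit
model monetizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aviahealth.constants import LOCAL_POLLUTANTS, SCENARIOS


@dataclass(frozen=True)
class RampSchedule:
    """Linear adoption ramp: 0 before start_year, 1 at and after end_year."""

    start_year: int = 2025
    end_year: int = 2050

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")


@dataclass
class ScenarioSpec:
    """One CCUS pathway: capture mode, CO2 fate, ramp and kappa multipliers.

    ``pollutant_multipliers`` maps each local pollutant to kappa, its
    fully-deployed emission factor relative to BAU (kappa < 1: co-benefit;
    kappa > 1: process penalty). The packaged defaults are illustrative, not
    authoritative: they encode only the qualitative pathway ordering
    (PSC-CCS cleanest, CCU conversion adds local emissions).
    ``ccu_neutrality`` is the fraction of displaced fossil CO2 treated as
    net-neutral under CCU (1.0: synthetic fuel fully displaces fossil CO2).
    """

    scenario_id: str
    capture_mode: str  # DAC | PSC
    fate: str          # CCS | CCU
    ramp: RampSchedule = field(default_factory=RampSchedule)
    pollutant_multipliers: dict[str, float] = field(default_factory=dict)
    ccu_neutrality: float = 1.0

    def __post_init__(self) -> None:
        if self.capture_mode not in ("DAC", "PSC"):
            raise ValueError(f"unknown capture mode {self.capture_mode!r}")
        if self.fate not in ("CCS", "CCU"):
            raise ValueError(f"unknown fate {self.fate!r}")
        unknown = set(self.pollutant_multipliers) - set(LOCAL_POLLUTANTS)
        if unknown:
            raise ValueError(
                f"unknown pollutants in multipliers: {sorted(unknown)} "
                f"(CO2 is handled by the fate rule, not by kappa)")
        bad = {p: k for p, k in self.pollutant_multipliers.items() if k < 0}
        if bad:
            raise ValueError(f"kappa must be non-negative: {bad}")

    def kappa(self, pollutant: str) -> float:
        return self.pollutant_multipliers.get(pollutant, 1.0)


#: packaged kappa defaults (illustrative; flue-gas co-capture benefit for
#: PSC-CCS, DAC energy penalty, conversion-process emissions for CCU)
_DEFAULT_KAPPA: dict[str, dict[str, float]] = {
    "PSC-CCS": {"PM2.5": 0.85, "SO2": 0.60, "NO2": 0.85, "CO": 0.95},
    "DAC-CCS": {"PM2.5": 1.05, "SO2": 1.05, "NO2": 1.05, "CO": 1.05},
    "PSC-CCU": {"PM2.5": 1.05, "SO2": 1.20, "NO2": 1.30, "CO": 1.10},
    "DAC-CCU": {"PM2.5": 1.05, "SO2": 1.20, "NO2": 1.30, "CO": 1.10},
}


def default_scenarios(ramp: RampSchedule | None = None) -> dict[str, ScenarioSpec]:
    """The four packaged pathway specs keyed by scenario id."""
    ramp = ramp or RampSchedule()
    out = {}
    for sid in SCENARIOS:
        mode, fate = sid.split("-")
        out[sid] = ScenarioSpec(
            scenario_id=sid, capture_mode=mode, fate=fate, ramp=ramp,
            pollutant_multipliers=dict(_DEFAULT_KAPPA[sid]))
    return out


def load_scenarios(path: str | Path) -> dict[str, ScenarioSpec]:
    """Read scenario specs from YAML (list of mappings)."""
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for entry in raw:
        ramp_raw = entry.pop("ramp", {})
        spec = ScenarioSpec(ramp=RampSchedule(**ramp_raw), **entry)
        out[spec.scenario_id] = spec
    return out


def save_scenarios(specs: dict[str, ScenarioSpec], path: str | Path) -> None:
    entries = []
    for spec in specs.values():
        d = dataclasses.asdict(spec)
        entries.append(d)
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


def ramp_fraction(year, schedule: RampSchedule) -> float | np.ndarray:
    """Deployment fraction: 0 before start, 1 at and after end, linear between."""
    span = schedule.end_year - schedule.start_year
    f = (np.asarray(year, dtype=float) - schedule.start_year) / span
    out = np.clip(f, 0.0, 1.0)
    return float(out) if np.isscalar(year) else out


def apply_scenario(bau: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Turn a BAU inventory into the scenario inventory.

    Local pollutants (p != CO2): ``mass_s(y) = mass_bau(y) * (1 + f(y) *
    (kappa_p - 1))``. CO2: source mass is unchanged; an ``offset_tonnes``
    column books the captured (CCS) or displaced-neutral (CCU) stream,
    ``f(y) * mass_bau_CO2(y)`` scaled by the CCU neutrality factor. Net
    scenario CO2 is ``mass - offset``.
    """
    years = bau["year"].to_numpy()
    f = ramp_fraction(years, spec.ramp)
    kappa = bau["pollutant"].map(spec.kappa).to_numpy(dtype=float)
    is_co2 = (bau["pollutant"] == "CO2").to_numpy()

    mass = bau["mass_tonnes"].to_numpy(dtype=float)
    new_mass = np.where(is_co2, mass, mass * (1.0 + f * (kappa - 1.0)))
    neutrality = spec.ccu_neutrality if spec.fate == "CCU" else 1.0
    offset = np.where(is_co2, f * mass * neutrality, 0.0)

    out = bau.copy()
    out["scenario_id"] = spec.scenario_id
    out["mass_tonnes"] = new_mass
    out["offset_tonnes"] = offset
    return out


def co2_saved(
    bau: pd.DataFrame, scenario_inventory: pd.DataFrame, spec: ScenarioSpec, year: int,
) -> float:
    """Saved net carbon SNC(y) in tonnes: net BAU CO2 minus net scenario CO2.

    Offsets count against the scenario's net emissions, so for a CCS pathway
    at full deployment SNC equals the entire BAU CO2 mass for that year.
    """
    bau_y = bau[(bau["year"] == year) & (bau["pollutant"] == "CO2")]
    scen_y = scenario_inventory[
        (scenario_inventory["year"] == year)
        & (scenario_inventory["pollutant"] == "CO2")]
    if bau_y.empty or scen_y.empty:
        raise ValueError(f"year {year} not covered by both inventories")
    net_bau = bau_y["mass_tonnes"].sum()
    net_scen = scen_y["mass_tonnes"].sum() - scen_y["offset_tonnes"].sum()
    return float(net_bau - net_scen)


def fuel_quantities(bau_fuel: float, spec: ScenarioSpec, year: int) -> tuple[float, float]:
    """Alternative-energy and displaced jet-fuel tonnage for one year.

    The pathway covers fraction f(y) of BAU fuel service — synthetic fuel
    tonnage under CCU, fuel tonnage whose emissions are offset under CCS —
    displacing the same tonnage of JET-A purchases: NA = NJ = f * bau_fuel.
    """
    if bau_fuel < 0:
        raise ValueError("bau_fuel must be non-negative")
    f = ramp_fraction(year, spec.ramp)
    return f * bau_fuel, f * bau_fuel
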