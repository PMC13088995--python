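"""Seeded synthetic world: airports, exposed populations, baseline mortality
rates and business-as-usual (BAU) emission inventories.

The generator emulates the statistical structure of the study inputs — a
global airport registry with mean wind speeds, the population living within
20 km of each airport, cause-specific baseline mortality, and BAU emission
trajectories from an aviation projection model — without reproducing any
real airport. Everything is driven by one master seed; each stage derives
its own child seed deterministically so stages can be regenerated
independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aviahealth.constants import (
    AGE_BANDS,
    AGE_MIDPOINTS,
    DISEASES,
    POLLUTANTS,
    SEXES,
)

# child-seed keys: master seed + stage key -> independent stream per stage
_STAGE_AIRPORTS = 11
_STAGE_POPULATION = 12
_STAGE_EMISSIONS = 13


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class WorldConfig:
    """Packaged defaults for the synthetic world.

    Distribution choices (lognormal wind, geometric age decay above 60,
    exponential traffic growth) reproduce the qualitative structure the
    downstream analysis assumes — elderly-skewed mortality, gently rising
    emissions — and every value is overridable.
    """

    n_airports: int = 30

    # airport registry
    wind_median: float = 3.5          # m/s, lognormal median
    wind_sigma_log: float = 0.4       # lognormal shape
    release_height: float = 0.0       # m; ground-level aircraft operations
    exposure_radius: float = 20_000.0  # m; residents within 20 km

    # population
    population_median: float = 1.0e6   # persons within the disk, lognormal median
    population_sigma_log: float = 0.8
    age_decay_above_60: float = 0.70   # geometric decay per 5-yr band above 60
    male_fraction: float = 0.5

    # baseline mortality: per-disease rate at age 60 (deaths/person/yr) and
    # exponential age slope (per year of age); male multiplier applies a fixed
    # sex differential (T2DM is the one female-dominant cause)
    rate_at_60: dict[str, float] = field(default_factory=lambda: {
        "stroke": 1.5e-3, "LC": 8.0e-4, "LRI": 4.0e-4, "COPD": 1.0e-3,
        "IHD": 2.0e-3, "T2DM": 3.0e-4, "CCVD-CO": 2.5e-3, "RD-NO2": 1.2e-3,
        "CCVD-SO2": 2.5e-3, "RD-SO2": 1.2e-3,
    })
    rate_age_slope: dict[str, float] = field(default_factory=lambda: {
        "stroke": 0.080, "LC": 0.055, "LRI": 0.060, "COPD": 0.075,
        "IHD": 0.075, "T2DM": 0.060, "CCVD-CO": 0.075, "RD-NO2": 0.080,
        "CCVD-SO2": 0.075, "RD-SO2": 0.080,
    })
    male_rate_multiplier: dict[str, float] = field(default_factory=lambda: {
        "stroke": 1.25, "LC": 1.40, "LRI": 1.15, "COPD": 1.30,
        "IHD": 1.35, "T2DM": 0.90, "CCVD-CO": 1.30, "RD-NO2": 1.35,
        "CCVD-SO2": 1.30, "RD-SO2": 1.35,
    })
    child_lri_boost: float = 3.0      # LRI elevation in the 0-4 band
    rate_cap: float = 0.4             # hard ceiling keeping rates < 1

    # BAU emissions
    fuel_median: float = 2.0e5        # t fuel/yr per airport, lognormal median
    fuel_sigma_log: float = 1.0
    annual_growth: float = 0.015      # traffic growth per year
    # emitted tonnes per tonne of fuel burnt
    emission_factors: dict[str, float] = field(default_factory=lambda: {
        "CO2": 3.16, "PM2.5": 2.0e-4, "CO": 1.0e-2, "SO2": 8.0e-4, "NO2": 1.5e-2,
    })

    def validate(self) -> None:
        if self.wind_median <= 0 or self.wind_sigma_log <= 0:
            raise ValueError("wind-speed distribution must be positive")
        if self.exposure_radius <= 0:
            raise ValueError("exposure_radius must be positive")
        if self.population_median <= 0:
            raise ValueError("population_median must be positive")
        if not (0 < self.age_decay_above_60 <= 1):
            raise ValueError("age_decay_above_60 must lie in (0, 1]")
        missing = [d for d in DISEASES if d not in self.rate_at_60
                   or d not in self.rate_age_slope
                   or d not in self.male_rate_multiplier]
        if missing:
            raise ValueError(f"rate schedule missing diseases: {missing}")
        bad = {p: v for p, v in self.emission_factors.items() if v < 0}
        if bad:
            raise ValueError(f"negative emission factors: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorldConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown WorldConfig keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# generators


def generate_airports(n: int, seed: int, config: WorldConfig | None = None) -> pd.DataFrame:
    """Generate a registry of ``n`` synthetic airports.

    Wind speeds are lognormal (median ``wind_median``, log-sd
    ``wind_sigma_log``); identical ``(n, seed, config)`` yields an identical
    registry.

    Returns a DataFrame with columns ``airport_id, name, mean_wind_speed,
    release_height, exposure_radius, region_tag``.
    """
    config = config or WorldConfig()
    config.validate()
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _rng(seed, _STAGE_AIRPORTS)
    wind = config.wind_median * np.exp(
        rng.normal(0.0, config.wind_sigma_log, size=n))
    regions = ("north", "south", "east", "west")
    return pd.DataFrame({
        "airport_id": [f"AP{i:04d}" for i in range(n)],
        "name": [f"Synthetic Airport {i:04d}" for i in range(n)],
        "mean_wind_speed": wind,
        "release_height": np.full(n, config.release_height),
        "exposure_radius": np.full(n, config.exposure_radius),
        "region_tag": [regions[i % len(regions)] for i in range(n)],
    })


def _age_weights(config: WorldConfig) -> np.ndarray:
    """Normalised age-pyramid weights: flat to 60, geometric decay above."""
    w = []
    for band in AGE_BANDS:
        lo = AGE_MIDPOINTS[band] - 2.5
        if lo < 60:
            w.append(1.0)
        else:
            w.append(config.age_decay_above_60 ** ((lo - 60) / 5 + 1))
    w = np.asarray(w)
    return w / w.sum()


def generate_population_and_rates(
    registry: pd.DataFrame, seed: int, config: WorldConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population strata per airport and a global baseline-rate table.

    Each airport receives all ``age x sex`` strata (20 five-year bands x
    2 sexes); stratified counts sum exactly to the airport total. Baseline
    rates are shared across airports (one rate per disease, age band and
    sex), rise exponentially with age for the cardiovascular and respiratory
    categories, and carry a fixed sex differential.
    """
    config = config or WorldConfig()
    config.validate()
    if registry.empty:
        raise ValueError("registry must be non-empty")
    rng = _rng(seed, _STAGE_POPULATION)

    totals = config.population_median * np.exp(
        rng.normal(0.0, config.population_sigma_log, size=len(registry)))
    weights = _age_weights(config)

    rows = []
    for airport_id, total in zip(registry["airport_id"], totals):
        for band, w in zip(AGE_BANDS, weights):
            for sex in SEXES:
                frac = config.male_fraction if sex == "male" else 1 - config.male_fraction
                rows.append((airport_id, band, sex, total * w * frac))
    population = pd.DataFrame(rows, columns=["airport_id", "age_band", "sex", "count"])

    rate_rows = []
    for disease in DISEASES:
        base = config.rate_at_60[disease]
        slope = config.rate_age_slope[disease]
        for band in AGE_BANDS:
            mid = AGE_MIDPOINTS[band]
            rate = base * np.exp(slope * (mid - 60.0))
            if disease == "LRI" and mid < 5:
                rate *= config.child_lri_boost
            rate = min(rate, config.rate_cap)
            for sex in SEXES:
                mult = config.male_rate_multiplier[disease] if sex == "male" else 1.0
                rate_rows.append((disease, band, sex, min(rate * mult, config.rate_cap)))
    rates = pd.DataFrame(rate_rows, columns=["disease_id", "age_band", "sex", "rate"])
    return population, rates


def generate_bau_emissions(
    registry: pd.DataFrame,
    years: range,
    seed: int,
    config: WorldConfig | None = None,
) -> pd.DataFrame:
    """BAU emission inventory: tonnes/yr per (airport, year, pollutant).

    Per-airport fuel burn is lognormal across airports; each pollutant's
    mass is ``fuel x emission_factor`` growing at ``annual_growth`` per
    year from the first year of ``years``:
    ``mass(y) = mass(y0) * (1 + g) ** (y - y0)``.
    """
    config = config or WorldConfig()
    config.validate()
    if registry.empty:
        raise ValueError("registry must be non-empty")
    years = list(years)
    if not years:
        raise ValueError("year range must be non-empty")
    rng = _rng(seed, _STAGE_EMISSIONS)

    fuel0 = config.fuel_median * np.exp(
        rng.normal(0.0, config.fuel_sigma_log, size=len(registry)))
    y0 = years[0]
    rows = []
    for airport_id, f0 in zip(registry["airport_id"], fuel0):
        for year in years:
            scale = f0 * (1.0 + config.annual_growth) ** (year - y0)
            for pollutant in POLLUTANTS:
                rows.append((airport_id, year, pollutant,
                             scale * config.emission_factors[pollutant]))
    return pd.DataFrame(rows, columns=["airport_id", "year", "pollutant", "mass_tonnes"])


# ---------------------------------------------------------------------------
# bundle


@dataclass
class World:
    """One generated world: registry, strata, rates and BAU inventory."""

    airports: pd.DataFrame
    population: pd.DataFrame
    baseline_rates: pd.DataFrame
    emissions_bau: pd.DataFrame
    config: WorldConfig
    seed: int

    def airport_totals(self) -> pd.DataFrame:
        """Per-airport population totals (sum over all strata)."""
        return (self.population.groupby("airport_id", sort=True)["count"]
                .sum().reset_index(name="population"))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "airports": outdir / "airports.csv",
            "population": outdir / "population.csv",
            "baseline_rates": outdir / "baseline_rates.csv",
            "emissions_bau": outdir / "emissions_bau.csv",
        }
        self.airports.to_csv(paths["airports"], index=False)
        self.population.to_csv(paths["population"], index=False)
        self.baseline_rates.to_csv(paths["baseline_rates"], index=False)
        self.emissions_bau.to_csv(paths["emissions_bau"], index=False)
        self.config.to_yaml(outdir / "world_config.yaml")
        return paths


def generate_world(
    n: int,
    seed: int,
    config: WorldConfig | None = None,
    years: range = range(2025, 2051),
) -> World:
    """Generate the full bundle from one master seed."""
    config = config or WorldConfig()
    airports = generate_airports(n, seed, config)
    population, rates = generate_population_and_rates(airports, seed, config)
    emissions = generate_bau_emissions(airports, years, seed, config)
    return World(airports, population, rates, emissions, config, seed)
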