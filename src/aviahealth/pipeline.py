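"""Pipeline orchestration: generate -> scenario -> dispersion -> health -> econ.

`run_pipeline` chains the stages for every requested scenario, writes each
stage's table as CSV when an output directory is configured, and records a
manifest (inputs, seed, package version, SHA-256 checksums) so reruns can be
verified byte-for-byte. With ``resume=True`` any stage whose output file
already exists is reloaded instead of recomputed, so a deleted intermediate
is regenerated exactly.

`write_reports` produces the reporting cuts (scenario-year totals, sex, age
and disease splits, top-k airports, cost-benefit bands); `sensitivity_sweep`
re-runs the pipeline under named parameter perturbations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from aviahealth import econ
from aviahealth.constants import SCENARIOS
from aviahealth.dispersion import DispersionParams, concentration_table
from aviahealth.econ import default_cost_schedules, scenario_cost_benefit
from aviahealth.exposure_response import (
    aggregate_mortality,
    attributable_deaths,
    load_erf_table,
    top_airports,
)
from aviahealth.scenario_engine import apply_scenario, default_scenarios
from aviahealth.synthetic_world import World, WorldConfig, generate_world

log = logging.getLogger("aviahealth")

REPORT_CUTS = ("scenario_year", "sex", "age", "disease", "airports", "cost_benefit")


@dataclass
class RunConfig:
    """One pipeline run: seed, world size, years, scenarios, parameter paths."""

    seed: int = 1
    n_airports: int = 30
    start_year: int = 2025
    end_year: int = 2050
    scenarios: tuple[str, ...] = SCENARIOS
    world: WorldConfig = field(default_factory=WorldConfig)
    erf_path: str | None = None
    prices_path: str | None = None
    outdir: str | None = None
    report_years: tuple[int, ...] = (2030, 2040, 2050)
    top_k: int = 10
    econ_start_year: int = 2030  # cost-benefit window starts here

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        for attr in ("erf_path", "prices_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} does not exist: {p}")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        world_raw = raw.pop("world", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        if "report_years" in raw:
            raw["report_years"] = tuple(raw["report_years"])
        world = WorldConfig(**world_raw)
        world.validate()
        return cls(world=world, **raw)


@dataclass
class ResultBundle:
    """All stage outputs of one run plus the reproducibility manifest."""

    config: RunConfig
    world: World
    scenario_inventories: dict[str, pd.DataFrame]
    concentrations: pd.DataFrame
    mortality: pd.DataFrame
    cost_benefit: pd.DataFrame
    manifest: dict


def _read_csv(path) -> pd.DataFrame:
    # round_trip: cached stage outputs must reload to the exact doubles that
    # were written, or resumed runs would drift by an ulp
    return pd.read_csv(path, float_precision="round_trip")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig, resume: bool = False) -> ResultBundle:
    """Execute every stage for every configured scenario.

    Deterministic under a fixed (config, seed); when ``config.outdir`` is
    set, each stage's table is written as CSV and, with ``resume=True``,
    reloaded from disk if its file already exists.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def cached(name: str, compute, reader=_read_csv):
        path = outdir / name if outdir else None
        if resume and path and path.exists():
            log.info("stage %s: loading cached %s", name, path)
            return reader(path)
        try:
            df = compute()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if path is not None:
            _write_csv(df, path)
        return df

    # world
    try:
        world = generate_world(config.n_airports, config.seed, config.world,
                               years=config.years)
    except Exception as exc:
        raise RuntimeError(f"stage 'world' failed: {exc}") from exc
    if outdir and not (resume and (outdir / "airports.csv").exists()):
        world.write(outdir)
    elif outdir and resume:
        world = World(
            airports=_read_csv(outdir / "airports.csv"),
            population=_read_csv(outdir / "population.csv"),
            baseline_rates=_read_csv(outdir / "baseline_rates.csv"),
            emissions_bau=_read_csv(outdir / "emissions_bau.csv"),
            config=config.world, seed=config.seed)
    log.info("world: %d airports, %d strata, %d inventory rows",
             len(world.airports), len(world.population), len(world.emissions_bau))

    specs = default_scenarios()
    erf = load_erf_table(config.erf_path)
    prices = (econ.load_price_series(config.prices_path)
              if config.prices_path else econ.default_price_series())
    dparams = DispersionParams()

    inventories: dict[str, pd.DataFrame] = {}
    conc_parts = []
    cb_parts = []
    for sid in config.scenarios:
        spec = specs[sid]
        inv = cached(f"emissions_{sid}.csv",
                     lambda s=spec: apply_scenario(world.emissions_bau, s))
        inventories[sid] = inv
        conc = cached(f"concentrations_{sid}.csv",
                      lambda i=inv: concentration_table(i, world.airports, dparams))
        conc_parts.append(conc)
        econ_years = [y for y in config.years if y >= config.econ_start_year]
        cb = cached(f"cost_benefit_{sid}.csv",
                    lambda i=inv, s=spec: scenario_cost_benefit(
                        world.emissions_bau, i, s, prices=prices,
                        years=econ_years))
        cb_parts.append(cb)
        log.info("scenario %s: %d inventory, %d concentration rows", sid,
                 len(inv), len(conc))

    concentrations = pd.concat(conc_parts, ignore_index=True)
    cost_benefit = pd.concat(cb_parts, ignore_index=True)
    if outdir:
        _write_csv(cost_benefit, outdir / "cost_benefit.csv")

    mortality = cached(
        "mortality.csv",
        lambda: attributable_deaths(
            concentrations, world.population, world.baseline_rates, erf))
    log.info("mortality: %d stratum rows, grand total %.1f deaths/yr-sum",
             len(mortality), mortality["attributable_deaths"].sum())

    manifest = {
        "seed": config.seed,
        "package": "aviahealth",
        "config": _config_dict(config),
        "files": {},
    }
    if outdir:
        _write_csv(concentrations, outdir / "concentrations.csv")
        for p in sorted(outdir.glob("*.csv")):
            manifest["files"][p.name] = _sha256(p)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ResultBundle(config, world, inventories, concentrations,
                        mortality, cost_benefit, manifest)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["scenarios"] = list(d["scenarios"])
    d["report_years"] = list(d["report_years"])
    return d


def write_reports(bundle: ResultBundle, cuts=REPORT_CUTS) -> dict[str, Path]:
    """Write one CSV per reporting cut; returns {cut: path}.

    Every mortality cut sums to the same grand total as the stratified
    table. An empty cut list writes only the report manifest.
    """
    outdir = Path(bundle.config.outdir or ".") / "reports"
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(cuts) - set(REPORT_CUTS)
    if unknown:
        raise KeyError(f"unknown report cuts: {sorted(unknown)}")
    m = bundle.mortality
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        _write_csv(df, path)
        paths[name] = path

    if "scenario_year" in cuts:
        emit("scenario_year", aggregate_mortality(m, ["scenario", "year"]))
    if "sex" in cuts:
        emit("sex", aggregate_mortality(m, ["scenario", "year", "sex"]))
    if "age" in cuts:
        emit("age", aggregate_mortality(m, ["scenario", "year", "age_band"]))
    if "disease" in cuts:
        emit("disease", aggregate_mortality(m, ["scenario", "year", "disease"]))
    if "airports" in cuts:
        frames = []
        for sid in bundle.config.scenarios:
            for year in bundle.config.report_years:
                t = top_airports(m, bundle.config.top_k, scenario=sid, year=year)
                t.insert(0, "year", year)
                t.insert(0, "scenario_id", sid)
                frames.append(t)
        emit("top_airports", pd.concat(frames, ignore_index=True))
    if "cost_benefit" in cuts:
        emit("cost_benefit", bundle.cost_benefit)

    report_manifest = {name: _sha256(p) for name, p in paths.items()}
    (outdir / "report_manifest.json").write_text(
        json.dumps(report_manifest, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# sensitivity


def _perturbed_run(config: RunConfig, perturbation: dict) -> ResultBundle:
    cfg = replace(config, outdir=None)
    kind = perturbation.get("kind")
    if kind == "erf_theta_se":
        erf = load_erf_table(config.erf_path).copy()
        gemm = erf["form"] == "GEMM"
        erf.loc[gemm, "theta"] = (
            erf.loc[gemm, "theta"]
            + float(perturbation["amount"]) * erf.loc[gemm, "theta_se"]).clip(lower=0.0)
        import tempfile
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".csv", delete=False)
        erf.to_csv(tmp.name, index=False)
        cfg = replace(cfg, erf_path=tmp.name)
        return run_pipeline(cfg)
    if kind == "cost_anchor_scale":
        bundle = run_pipeline(cfg)
        econ_years = [y for y in cfg.years if y >= cfg.econ_start_year]
        factor = float(perturbation["amount"])
        which = perturbation.get("scenario")
        schedules = {
            sid: econ.CostSchedule(
                sid,
                s.anchor_2020 * (factor if which in (None, sid) else 1.0),
                s.anchor_2050 * (factor if which in (None, sid) else 1.0))
            for sid, s in default_cost_schedules().items()}
        specs = default_scenarios()
        prices = (econ.load_price_series(config.prices_path)
                  if config.prices_path else econ.default_price_series())
        cb = pd.concat(
            [scenario_cost_benefit(
                bundle.world.emissions_bau, bundle.scenario_inventories[sid],
                specs[sid], prices=prices, schedule=schedules[sid],
                years=econ_years)
             for sid in cfg.scenarios],
            ignore_index=True)
        bundle.cost_benefit = cb
        return bundle
    raise KeyError(f"unknown perturbation kind: {kind!r}")


def sensitivity_sweep(config: RunConfig, perturbations: list[dict]) -> pd.DataFrame:
    """One pipeline evaluation per perturbation; deltas vs baseline.

    Each perturbation is a mapping with ``name`` and ``kind`` —
    ``erf_theta_se`` (shift every GEMM theta by ``amount`` standard errors)
    or ``cost_anchor_scale`` (multiply cost anchors by ``amount``, optionally
    for one ``scenario``). Returns one row per run with total deaths, total
    cost and their deltas against the unperturbed baseline.
    """
    baseline = run_pipeline(replace(config, outdir=None))
    rows = [_summary_row("baseline", baseline)]
    for pert in perturbations:
        name = pert.get("name") or pert.get("kind")
        bundle = _perturbed_run(config, pert)
        rows.append(_summary_row(name, bundle))
    out = pd.DataFrame(rows)
    out["delta_deaths"] = out["total_deaths"] - out.loc[0, "total_deaths"]
    out["delta_cost"] = out["total_cost"] - out.loc[0, "total_cost"]
    return out


def _summary_row(name: str, bundle: ResultBundle) -> dict:
    return {
        "name": name,
        "total_deaths": float(bundle.mortality["attributable_deaths"].sum()),
        "total_cost": float(bundle.cost_benefit["C"].sum()),
        "total_cae": float(bundle.cost_benefit["CAE"].sum()),
        "total_net_benefit_max": float(bundle.cost_benefit["N_max"].sum()),
    }
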