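# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Scenario engine

Adoption of each CCUS pathway is a linear ramp `f(y) = (y − 2025)/25`,
clamped to [0, 1]: usage is zero today and complete by 2050, changing
proportionally in between. The start year coincides with the first year of
the mortality assessment window.

Local pollutants respond through a fully-deployed emission multiplier κ_p
per pathway, interpolated by the deployment fraction:
`m_s(y) = m_BAU(y)(1 + f(y)(κ_p − 1))`. The packaged κ values —
PSC-CCS {PM2.5 0.85, SO2 0.60, NO2 0.85, CO 0.95}, DAC-CCS all 1.05,
both CCU pathways {PM2.5 1.05, SO2 1.20, NO2 1.30, CO 1.10} — are
*illustrative defaults*, not measured process data. They encode three
mechanisms at the qualitative level: co-capture of flue-gas pollutants at a
point source, the energy penalty of running DAC plants, and the additional
process emissions of fuel synthesis. Every value is overridable in the
scenario YAML; analyses of a specific capture technology should replace
them with process-resolved factors.

CO2 never takes a κ. Under a CCS fate, source emissions are unchanged and
an offset stream `f(y)·m_CO2,BAU(y)` is booked (capture happens elsewhere);
under CCU, the deployed fraction of fossil CO2 is displaced by
synthetic-fuel CO2 whose net contribution is governed by a carbon-neutrality
factor (default 1.0 — full displacement — so saved net carbon, SNC, has the
same form under both fates; configurable). SNC(y) is net BAU CO2 minus net
scenario CO2 with offsets counted, so at full CCS deployment SNC equals the
entire BAU CO2 mass.

## Dispersion

The registry provides only a mean annual wind speed per airport — no wind
rose — so the only defensible long-term exposure model is a sector-averaged
Gaussian plume: the ground-level crosswind-integrated reflected plume
`Cy(r) = √(2/π)·Q/(u·σz(r))·exp(−H²/2σz²)` spread uniformly around the
compass, giving `C(r) = Cy(r)/(2πr)`, and averaged over the 20-km exposure
disk. The disk mean reduces to a one-dimensional integral
`C̄ = (πR²)⁻¹ ∫_{r_min}^{R} Cy(r) dr`, evaluated by composite trapezoid.

Numerical and physical choices:

* **Stability class D** (neutral) is the default for a long-term average;
  σy/σz follow the Briggs open-country interpolation formulas, all six
  classes packaged and selectable.
* **Release height H = 0** by default: aircraft landing/take-off emissions
  are effectively at ground level over the annual mean.
* **Inner cutoff r_min = 100 m** removes the 1/r singularity of the sector
  average; the excluded disk is 0.0025 % of the exposure area.
* **Quadrature n = 2000 points** over [r_min, R]: against a 10⁶-point
  refined evaluation the default grid is accurate to ~1 × 10⁻⁵ relative
  (the acceptance script recomputes this), and halving n moves the result
  by < 0.5 %.
* Annual mass converts to a steady rate `Q = m·10⁶/(365.25·24·3600)` g/s —
  a long-term-average plume with no diurnal or seasonal modulation.
* Concentrations are linear in Q, so the table builder computes one
  unit-rate disk integral per airport and scales by mass; this is exact,
  not an approximation.

Not modelled: wind-direction-resolved exposure, terrain and building wakes,
plume chemistry and secondary PM formation, and receptor-level population
weighting within the disk.

## Exposure-response

PM2.5 acts through the GEMM: `HR(z) = exp(θ·log(1+z/α)/(1+exp(−(z−μ)/ν)))`
with `z = max(0, C − z_cf)` and counterfactual `z_cf = 2.4 µg/m³`. The six
causes are stroke, lung cancer, lower respiratory infections (LRI), COPD,
ischemic heart disease (IHD) and type 2 diabetes. θ, α, μ, ν ship in
`data/erf_table.csv`. IHD and stroke additionally carry per-5-year-band θ
rows generated from the all-age θ by a monotone declining age profile
(multiplier 1.70 at ages 25–29 falling 0.02 per year of age, floored at
0.45) — a stand-in schedule, flagged `artifact` in the table, reproducing
the established pattern that proportional PM2.5 hazards for cardiovascular
causes decline with age. The T2DM row is likewise an artifact extension
(GEMM's published causes do not include it). GEMM causes apply to ages 25+,
except LRI (all ages).

The gaseous pollutants use log-linear relative risks
`RR = exp(β·max(0, C − C0)/scale)` for four causes: cardiovascular/
cerebrovascular disease from CO (β = 0.008 per 1 mg/m³) and from SO2
(β = 0.015 per 10 µg/m³), respiratory disease from SO2 (β = 0.018) and from
NO2 (β = 0.020, both per 10 µg/m³), reference level C0 = 0, all ages. These
β are placeholders calibrated only to the qualitative pattern that gaseous
causes dominate the burden near airports while PM2.5 causes are near zero;
none is authoritative and all are overridable by pointing the pipeline at a
replacement CSV.

Risk functions are sex-invariant and (outside the GEMM age-θ schedule)
age-invariant: sex and age differentials in the results arise from baseline
rates and population structure, not from the exposure side.

Deaths are an annual flow, not a cumulative count: per stratum,
`deaths = count × baseline_rate × PAF`, `PAF = (RR − 1)/RR`. Because
PAF < 1, attributable deaths can never exceed baseline deaths in a stratum,
and summing over any partition (sex, age, disease, airport) conserves the
grand total exactly.

## Economics

Per pathway and year: NA = NJ = f(y)·fuel_BAU(y) — the pathway covers the
deployed fraction of BAU fuel service and displaces the same tonnage of
JET-A purchases. BAU fuel is inferred from the BAU CO2 inventory at
3.16 t CO2 per tonne of jet fuel. Then `C = NA·PA − NJ·PJ`,
`Re = SNC·PC`, `N = Re − C`, with the carbon price a [low, high] band so
revenue and net benefit are bands; the band width is exactly
`SNC·(PC_max − PC_min)`.

PA interpolates linearly between the published 2020/2050 per-ton fuel-cost
anchors (DAC-CCS 2649.90 → 1144.30, DAC-CCU 7549.90 → 4062.50, PSC-CCS
856.65 → 697.00, PSC-CCU 4283.25 → 3252.88 USD/t); an exponential-decay
interpolation is available behind a config switch. The packaged price paths
are placeholders: JET-A flat at 500 USD/t, carbon price 10 → 35 (low) and
15 → 55 (high) USD/t over 2024–2050, chosen so the carbon price stays below
the per-tonne-CO2 abatement premium of the cheapest pathway throughout —
the regime in which every pathway runs at a net loss in every year, which
is the qualitative configuration the defaults are meant to reproduce. Both
paths are replaceable by a user CSV. All currency is nominal USD with no
discounting. The cost-benefit window is 2030–2050 (configurable via
`econ_start_year`); the mortality window is 2025–2050.

Not monetized: avoided mortality, retrofit/maintenance capital, and
itemized CO2 transport/storage (treated as embedded in the alternative-fuel
price).

## Synthetic world

The generator emulates the *statistical structure* of the study inputs, not
any real airport:

* **Airports** — lognormal mean wind speeds (median 3.5 m/s, log-sd 0.4),
  release height 0 m, exposure radius 20 km.
* **Population** — lognormal totals per airport (median 10⁶ within the
  disk, log-sd 0.8); 5-year age bands 0–95+ with a flat pyramid to 60 and
  geometric decay (factor 0.70 per band) above; equal sex split.
* **Baseline mortality** — per-disease exponential age schedules anchored
  at age 60 (e.g. 2.5 × 10⁻³/yr for the cardiovascular categories, slopes
  0.055–0.08 per year of age, capped at 0.4), male excess 15–40 % for all
  causes except type 2 diabetes (female-dominant, multiplier 0.9), and an
  elevated LRI rate in the 0–4 band.
* **BAU emissions** — lognormal fuel burn per airport (median 2 × 10⁵ t/yr,
  log-sd 1.0) growing 1.5 %/yr, with fixed emission factors per tonne of
  fuel (CO2 3.16, NO2 0.015, CO 0.01, SO2 8 × 10⁻⁴, PM2.5 2 × 10⁻⁴ t/t).
  These produce disk-mean NO2 concentrations of a few µg/m³ at a median
  airport — a realistic magnitude for an airport increment — and PM2.5
  increments well below the GEMM counterfactual, so PM2.5-attributable
  deaths are near zero, as expected for aviation increments alone.

One master seed drives everything; each stage derives an independent child
stream via `SeedSequence([master, stage_key])`, so stages can be
regenerated independently and the whole bundle is byte-reproducible.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: spatial correlation between traffic volume
and population density (the main driver of real airport rankings),
region-specific age pyramids and disease profiles, wind-rose anisotropy,
and absolute global totals. The packaged default world (30 airports,
2025–2050) is a deliberately scaled-down stand-in for a ~1100-airport
global registry: orderings, shares and ratios are meaningful; absolute
death counts and dollar totals are not comparable to a global assessment.

## Numerical and degenerate-input conventions

* Ramp fractions clamp outside the schedule rather than erroring.
* GEMM returns exactly HR = 1 at or below the counterfactual; PAF rejects
  RR < 1 rather than silently producing negative deaths.
* Zero-mass inventory rows yield exactly zero concentration (the quadrature
  is skipped).
* Airport rankings sort stably with airport id as tie-break.
* Cached stage CSVs are reloaded with round-trip float parsing so resumed
  runs are bit-identical to fresh ones.
* Tables are plain CSV with documented columns; every parameter table the
  pipeline consumes (ERF, prices, scenario specs, world config) can be
  replaced by a user file with the same schema.

## Problem sizes

The default test and acceptance configurations use 3–30 airports over
2025–2050 with all four pathways; the stratified mortality table for the
default world is ~1 million rows and the full pipeline completes in well
under a minute on one CPU. The generator scales linearly to the
~1100-airport scale of a global registry.

## Known limitations

Mortality is the sole health endpoint (no morbidity or years of life
lost); no concentration-mixture interactions; uniform treatment of CO2
logistics across airports; the κ multipliers, gaseous β values, GEMM age-θ
profile and price paths are flagged placeholders pending process- and
cohort-specific data.
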