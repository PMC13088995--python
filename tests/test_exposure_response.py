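"""Exposure-response: GEMM and log-linear risk functions, PAF accounting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aviahealth import (
    aggregate_mortality,
    attributable_deaths,
    attributable_fraction,
    concentration_table,
    gemm_hazard_ratio,
    load_erf_table,
    loglinear_rr,
)
from aviahealth.constants import AGE_BANDS, SEXES
from aviahealth.exposure_response import top_airports

NCD_STYLE = dict(form="GEMM", theta=0.1430, alpha=1.6, mu=15.5, nu=36.8, z_cf=2.4)


class TestGEMM:
    @pytest.mark.parametrize("C", [0.0, 1.0, 2.4])
    def test_unity_at_or_below_counterfactual(self, C):
        assert gemm_hazard_ratio(C, NCD_STYLE) == 1.0

    def test_null_effect_when_theta_zero(self):
        params = dict(NCD_STYLE, theta=0.0)
        for C in (0.0, 10.0, 300.0):
            assert gemm_hazard_ratio(C, params) == 1.0

    def test_matches_independent_formula_evaluation(self):
        # direct scalar evaluation with the math module, independent of the
        # vectorised implementation path
        C = 10.0
        z = max(0.0, C - 2.4)
        want = math.exp(0.1430 * math.log(1 + z / 1.6)
                        / (1 + math.exp(-(z - 15.5) / 36.8)))
        assert gemm_hazard_ratio(C, NCD_STYLE) == pytest.approx(want, rel=1e-14)
        assert want == pytest.approx(1.1181714446372188, rel=1e-12)

    def test_rejects_wrong_form(self):
        with pytest.raises(ValueError, match="GEMM"):
            gemm_hazard_ratio(10.0, {"form": "log-linear", "beta": 0.01})

    def test_vectorised_over_concentration(self):
        c = np.array([0.0, 5.0, 50.0])
        hr = gemm_hazard_ratio(c, NCD_STYLE)
        assert hr.shape == (3,)
        assert hr[0] == 1.0 and (np.diff(hr) > 0).all()


class TestLogLinear:
    def test_unity_at_reference(self):
        params = dict(form="log-linear", beta=0.02, c0=5.0, beta_scale_ugm3=10.0)
        assert loglinear_rr(5.0, params) == 1.0
        assert loglinear_rr(0.0, params) == 1.0

    def test_null_effect_when_beta_zero(self):
        params = dict(form="log-linear", beta=0.0, c0=0.0)
        assert loglinear_rr(400.0, params) == 1.0

    def test_direct_evaluation(self):
        params = dict(form="log-linear", beta=0.01, c0=3.0, beta_scale_ugm3=10.0)
        assert loglinear_rr(13.0, params) == pytest.approx(math.exp(0.01), rel=1e-14)

    def test_co_row_uses_milligram_scale(self, erf_table):
        row = erf_table[erf_table["disease_id"] == "CCVD-CO"].iloc[0]
        # beta is per 1 mg/m^3 = 1000 ug/m^3
        assert loglinear_rr(1000.0, row) == pytest.approx(math.exp(row["beta"]), rel=1e-12)


class TestPAF:
    @pytest.mark.parametrize("rr,want", [(1.0, 0.0), (2.0, 0.5), (4.0, 0.75)])
    def test_closed_form(self, rr, want):
        assert attributable_fraction(rr) == pytest.approx(want)

    def test_limit_approaches_one(self):
        # PAF(RR) = 1 - 1/RR, so at RR = 1e6 the gap is exactly 1e-6
        assert 1.0 - attributable_fraction(1e6) <= 1e-6 * (1 + 1e-9)

    def test_rr_below_one_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(0.99)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(c=st.floats(min_value=0.0, max_value=499.0),
       dc=st.floats(min_value=0.01, max_value=1.0))
def test_risk_functions_nondecreasing_for_every_packaged_row(c, dc):
    erf = load_erf_table()
    for _, row in erf.iterrows():
        if row["form"] == "GEMM":
            assert gemm_hazard_ratio(c + dc, row) >= gemm_hazard_ratio(c, row)
        else:
            assert loglinear_rr(c + dc, row) >= loglinear_rr(c, row)


def _bruteforce_deaths(conc, pop, rates, erf):
    """Independent per-stratum loop: scalar risk evaluation per output row."""
    out = {}
    rate_idx = rates.set_index(["disease_id", "age_band", "sex"])["rate"]
    pop_idx = pop.set_index(["airport_id", "age_band", "sex"])["count"]
    for _, crow in conc.iterrows():
        for _, erow in erf.iterrows():
            if erow["pollutant"] != crow["pollutant"]:
                continue
            disease = erow["disease_id"]
            bands = ([erow["age_band"]] if isinstance(erow["age_band"], str)
                     else [b for b in AGE_BANDS
                           if int(b.split("-")[0].rstrip("+")) >= erow["min_age"]])
            # skip the all-age fallback row where age-specific rows exist
            if not isinstance(erow["age_band"], str) and disease in ("IHD", "stroke"):
                continue
            if erow["form"] == "GEMM":
                rr = gemm_hazard_ratio(float(crow["conc_ugm3"]), erow)
            else:
                rr = loglinear_rr(float(crow["conc_ugm3"]), erow)
            paf = (rr - 1.0) / rr
            for band in bands:
                for sex in SEXES:
                    key = (crow["airport_id"], crow.get("scenario_id"),
                           crow["year"], disease, band, sex)
                    deaths = (pop_idx[(crow["airport_id"], band, sex)]
                              * rate_idx[(disease, band, sex)] * paf)
                    out[key] = out.get(key, 0.0) + deaths
    return out


class TestAttributableDeaths:
    def test_hand_checkable_stratum(self, uniform_stratum_tables):
        """count 100000 x rate 0.01 x PAF 0.5 = 500 deaths per stratum."""
        pop, rates = uniform_stratum_tables
        c_for_rr2 = 10.0 * math.log(2.0) / 0.015  # CCVD-SO2 beta row
        conc = pd.DataFrame({
            "airport_id": ["AP0000"], "year": [2030],
            "pollutant": ["SO2"], "conc_ugm3": [c_for_rr2]})
        res = attributable_deaths(conc, pop, rates)
        ccvd = res[res["disease_id"] == "CCVD-SO2"]
        assert len(ccvd) == len(AGE_BANDS) * 2
        np.testing.assert_allclose(ccvd["attributable_deaths"], 500.0, rtol=1e-12)

    def test_zero_concentration_gives_zero_deaths(self, uniform_stratum_tables):
        pop, rates = uniform_stratum_tables
        conc = pd.DataFrame({
            "airport_id": ["AP0000"] * 4, "year": [2030] * 4,
            "pollutant": ["PM2.5", "CO", "SO2", "NO2"], "conc_ugm3": [0.0] * 4})
        res = attributable_deaths(conc, pop, rates)
        assert (res["attributable_deaths"] == 0.0).all()

    def test_matches_bruteforce_stratum_loop(self, tiny_world, scenarios, erf_table):
        from aviahealth import apply_scenario
        inv = apply_scenario(tiny_world.emissions_bau, scenarios["DAC-CCU"])
        conc = concentration_table(inv, tiny_world.airports)
        conc = conc[conc["year"] == 2027]
        res = attributable_deaths(conc, tiny_world.population,
                                  tiny_world.baseline_rates, erf_table)
        brute = _bruteforce_deaths(conc, tiny_world.population,
                                   tiny_world.baseline_rates, erf_table)
        assert len(res) == len(brute)
        for _, row in res.iterrows():
            key = (row["airport_id"], row["scenario_id"], row["year"],
                   row["disease_id"], row["age_band"], row["sex"])
            assert row["attributable_deaths"] == pytest.approx(
                brute[key], rel=1e-9, abs=1e-15)

    def test_deaths_bounded_by_baseline_deaths(self, small_world, scenarios):
        from aviahealth import apply_scenario
        inv = apply_scenario(small_world.emissions_bau, scenarios["DAC-CCU"])
        conc = concentration_table(inv, small_world.airports)
        res = attributable_deaths(conc, small_world.population, small_world.baseline_rates)
        base = small_world.population.merge(
            small_world.baseline_rates, on=["age_band", "sex"])
        base["baseline_deaths"] = base["count"] * base["rate"]
        merged = res.merge(base, on=["airport_id", "disease_id", "age_band", "sex"])
        assert (merged["attributable_deaths"] >= 0).all()
        assert (merged["attributable_deaths"] <= merged["baseline_deaths"] + 1e-12).all()

    def test_missing_baseline_rate_names_stratum(self, tiny_world):
        rates = tiny_world.baseline_rates
        broken = rates[~((rates["age_band"] == "35-39") & (rates["sex"] == "male"))]
        inv = tiny_world.emissions_bau
        conc = concentration_table(inv, tiny_world.airports)
        with pytest.raises(ValueError, match="35-39"):
            attributable_deaths(conc, tiny_world.population, broken)

    def test_small_effect_linearisation(self, uniform_stratum_tables):
        """For beta*dC/scale <= 1e-3, deaths ~ count*rate*beta*dC/scale to 0.1%."""
        pop, rates = uniform_stratum_tables
        beta, scale = 0.015, 10.0  # CCVD-SO2 packaged row
        dc = 1e-3 * scale / beta * 0.9
        conc = pd.DataFrame({
            "airport_id": ["AP0000"], "year": [2030],
            "pollutant": ["SO2"], "conc_ugm3": [dc]})
        res = attributable_deaths(conc, pop, rates)
        got = res[res["disease_id"] == "CCVD-SO2"]["attributable_deaths"].iloc[0]
        approx = 100_000 * 0.01 * beta * dc / scale
        assert got == pytest.approx(approx, rel=1e-3)


class TestAggregation:
    def test_empty_grouping_returns_grand_total(self, tiny_world, scenarios, erf_table):
        from aviahealth import apply_scenario
        inv = apply_scenario(tiny_world.emissions_bau, scenarios["PSC-CCS"])
        conc = concentration_table(inv, tiny_world.airports)
        res = attributable_deaths(conc, tiny_world.population,
                                  tiny_world.baseline_rates, erf_table)
        total = aggregate_mortality(res)["attributable_deaths"].iloc[0]
        assert total == pytest.approx(res["attributable_deaths"].sum())
        for key in ("sex", "age_band", "disease", "airport", "year"):
            marg = aggregate_mortality(res, [key])
            assert marg["attributable_deaths"].sum() == pytest.approx(total)

    def test_unknown_grouping_key_rejected(self, tiny_world, scenarios):
        from aviahealth import apply_scenario
        inv = apply_scenario(tiny_world.emissions_bau, scenarios["PSC-CCS"])
        conc = concentration_table(inv, tiny_world.airports)
        res = attributable_deaths(conc, tiny_world.population, tiny_world.baseline_rates)
        with pytest.raises(KeyError, match="continent"):
            aggregate_mortality(res, ["continent"])

    def test_top_airports_matches_bruteforce_sort(self, small_world, scenarios):
        from aviahealth import apply_scenario
        inv = apply_scenario(small_world.emissions_bau, scenarios["DAC-CCU"])
        conc = concentration_table(inv, small_world.airports)
        res = attributable_deaths(conc, small_world.population, small_world.baseline_rates)
        ranked = top_airports(res, k=3, year=2050)
        brute = (res[res["year"] == 2050].groupby("airport_id")["attributable_deaths"]
                 .sum().sort_values(ascending=False))
        assert list(ranked["airport_id"]) == list(brute.index[:3])
        np.testing.assert_allclose(ranked["attributable_deaths"], brute.values[:3])
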