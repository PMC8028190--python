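"""Cost engine: per-cycle components, lifetime folding, TC1 identities."""

import numpy as np
import pandas as pd
import pytest

import tdtcost as t
from tdtcost.costs import TC2_COMPONENTS, breakdown_from_components
from tdtcost.markov import CohortTrace
from tdtcost.params import ENDOCRINE_COMPLICATIONS
from tdtcost.weight import WeightModel, constant_band
from tdtcost import reference as ref

from conftest import usd_table_params


def immortal_trace(entry=2, horizon=58):
    """Trace of a cohort that never dies nor develops complications."""
    ages = list(range(entry, horizon + 1))
    frame = pd.DataFrame(0.0, index=pd.Index(ages, name="age"),
                         columns=["no_cardiac", "cardiac_y1", "cardiac_y2p",
                                  "dead", "alive"]
                         + [f"{c}_{s}" for c in ENDOCRINE_COMPLICATIONS
                            for s in ("y1", "y2p")])
    frame["no_cardiac"] = 1.0
    frame["alive"] = 1.0
    return CohortTrace(frame)


class TestAnnualComponents:
    """Hand arithmetic on the printed USD unit costs, raw prescribed doses
    (no compliance scaling, daily dosing)."""

    def test_dfx_drug_cost_at_20kg(self, usd_params):
        drug, admin = t.annual_ict_cost(10, 20.0, usd_params)
        # 24.6 mg/kg/day * 20 kg * 365 d = 179,580 mg -> 179.58 g * 36.60
        assert drug == pytest.approx(6572.63, abs=0.01)
        assert admin == 0.0

    def test_dfo_drug_and_admin_cost_at_20kg(self):
        params = usd_table_params()
        params.regimen_policy.adult_regimen = {("DFO",): 1.0}
        drug, admin = t.annual_ict_cost(20, 20.0, params)
        # 47.4 * 20 * 365 = 346,020 mg -> 346.02 g * 10.81
        assert drug == pytest.approx(3740.48, abs=0.01)
        assert admin == pytest.approx(12 * 96.80, abs=0.01)

    def test_compliance_scaling_multiplies_drug_only(self):
        raw = usd_table_params(compliance_scales_cost=False)
        scaled = usd_table_params(compliance_scales_cost=True)
        raw.regimen_policy.adult_regimen = {("DFO",): 1.0}
        scaled.regimen_policy.adult_regimen = {("DFO",): 1.0}
        drug0, admin0 = t.annual_ict_cost(20, 20.0, raw)
        drug1, admin1 = t.annual_ict_cost(20, 20.0, scaled)
        assert drug1 == pytest.approx(drug0 * 0.773)
        assert admin1 == admin0  # consumables are supplied regardless

    def test_five_weekly_dfo_dosing_scales_drug_mass(self):
        daily = usd_table_params(dfo_days_per_week=7.0)
        weekly5 = usd_table_params(dfo_days_per_week=5.0)
        for p in (daily, weekly5):
            p.regimen_policy.adult_regimen = {("DFO",): 1.0}
        drug7, _ = t.annual_ict_cost(20, 20.0, daily)
        drug5, _ = t.annual_ict_cost(20, 20.0, weekly5)
        assert drug5 == pytest.approx(drug7 * 5.0 / 7.0)

    def test_combination_regimen_sums_agents(self, usd_params):
        usd_params.regimen_policy.adult_regimen = {("DFO", "DFP"): 1.0}
        drug, admin = t.annual_ict_cost(20, 20.0, usd_params)
        dfo = 47.4 * 20 * 365 / 1000 * 10.81
        dfp = 75.0 * 20 * 365 / 1000 * 0.49
        assert drug == pytest.approx(dfo + dfp, rel=1e-12)
        assert admin == pytest.approx(12 * 96.80, abs=0.01)

    def test_tiny_weight_gives_near_zero_cost(self, usd_params):
        drug, _ = t.annual_ict_cost(10, 1e-4, usd_params)
        assert 0 < drug < 0.1

    def test_transfusion_cost_at_20kg(self, usd_params):
        annual = t.annual_transfusion_cost(20.0, usd_params.transfusion)
        # per transfusion: 20*15*0.16 + 2.71 + 1.14 = 51.85
        assert annual == pytest.approx(12 * 51.85, abs=1e-9)

    def test_transfusion_volume_free_floor(self, usd_params):
        tc = usd_params.transfusion
        tc.ml_per_kg = 0.0
        assert t.annual_transfusion_cost(20.0, tc) == pytest.approx(
            12 * (2.71 + 1.14))

    def test_transfusion_linear_in_frequency(self, usd_params):
        tc = usd_params.transfusion
        base = t.annual_transfusion_cost(20.0, tc)
        tc.transfusions_per_year = 24
        assert t.annual_transfusion_cost(20.0, tc) == pytest.approx(2 * base)

    def test_monitoring_age_schedule(self, usd_params):
        m = usd_params.monitoring
        assert t.annual_monitoring_cost(5, m) == pytest.approx(12 * 55.39)
        assert t.annual_monitoring_cost(10, m) == pytest.approx(12 * 106.47)
        assert t.annual_monitoring_cost(9, m) == pytest.approx(12 * 55.39)

    def test_iol_cost_is_prevalence_weighted(self, usd_params):
        table = usd_params.complications
        strata = {c: (0.0, 0.0) for c in table}
        assert t.annual_iol_cost(strata, table) == 0.0
        strata["hypogonadism"] = (1.0, 0.0)
        assert t.annual_iol_cost(strata, table) == pytest.approx(175.40)
        strata["hypogonadism"] = (0.0, 0.0)
        strata["hypothyroidism"] = (0.0, 0.5)
        assert t.annual_iol_cost(strata, table) == pytest.approx(21.795)

    def test_iol_rejects_invalid_prevalence(self, usd_params):
        strata = {c: (0.0, 0.0) for c in usd_params.complications}
        strata["cardiac"] = (1.2, 0.0)
        with pytest.raises(ValueError):
            t.annual_iol_cost(strata, usd_params.complications)


class TestLifetimeFolding:
    def test_zero_mortality_constant_cost_is_annual_times_horizon(self):
        params = usd_table_params()
        params.regimen_policy.adult_regimen = params.regimen_policy.child_regimen
        params.monitoring.monthly_under10 = params.monitoring.monthly_10plus
        trace = immortal_trace()
        wm = WeightModel(bands=[constant_band(1, 60, 30.0)])
        b = t.lifetime_costs(trace, wm, params, mean_monthly_family_cost=10.0)
        h = 57  # cycles, ages 2..58
        drug, admin = t.annual_ict_cost(5, 30.0, params)
        assert b.components["ict_drug"] == pytest.approx(drug * h, rel=1e-12)
        assert b.components["monitoring"] == pytest.approx(
            t.annual_monitoring_cost(20, params.monitoring) * h, rel=1e-12)
        assert b.components["transfusion"] == pytest.approx(
            t.annual_transfusion_cost(30.0, params.transfusion) * h, rel=1e-12)
        assert b.components["iol"] == 0.0
        assert b.tc3 == pytest.approx(10.0 * 12 * h, rel=1e-12)

    def test_tc1_identity_in_both_currencies(self, base_params, base_trace,
                                             weight_model, mean_monthly):
        b = t.lifetime_costs(base_trace, weight_model, base_params,
                             mean_monthly)
        assert b.tc1 == b.tc2 + b.tc3
        assert b.in_usd(b.tc1) == pytest.approx(
            b.in_usd(b.tc2) + b.in_usd(b.tc3), rel=1e-12)

    def test_higher_survival_never_lowers_a_component(
            self, base_params, life_table, transitions, weight_model,
            mean_monthly):
        trace = t.run_cohort(base_params, life_table, transitions)
        boosted = CohortTrace(trace.frame.copy())
        extra = boosted.frame["dead"] * 0.5
        boosted.frame["no_cardiac"] += extra
        boosted.frame["alive"] += extra
        boosted.frame["dead"] -= extra
        b0 = t.lifetime_costs(trace, weight_model, base_params, mean_monthly)
        b1 = t.lifetime_costs(boosted, weight_model, base_params, mean_monthly)
        for k in TC2_COMPONENTS:
            assert b1.components[k] >= b0.components[k]
        assert b1.tc3 >= b0.tc3

    def test_component_monotone_in_unit_price(self, base_params, base_trace,
                                              weight_model, mean_monthly):
        dearer = base_params.copy()
        dearer.agents["DFX"].unit_price_per_g *= 1.5
        b0 = t.lifetime_costs(base_trace, weight_model, base_params,
                              mean_monthly)
        b1 = t.lifetime_costs(base_trace, weight_model, dearer, mean_monthly)
        assert b1.components["ict_drug"] > b0.components["ict_drug"]
        assert b1.components["transfusion"] == pytest.approx(
            b0.components["transfusion"])

    def test_cohort_and_microsimulated_traces_agree_on_tc2(
            self, base_params, life_table, transitions, weight_model,
            mean_monthly, base_trace):
        micro = t.microsimulate(base_params, life_table, transitions,
                                50_000, seed=5)
        b_cohort = t.lifetime_costs(base_trace, weight_model, base_params,
                                    mean_monthly)
        b_micro = t.lifetime_costs(micro, weight_model, base_params,
                                   mean_monthly)
        assert b_micro.tc2 == pytest.approx(b_cohort.tc2, rel=0.02)

    def test_weight_model_coverage_mismatch_rejected(self, base_params,
                                                     base_trace):
        wm = WeightModel(bands=[constant_band(1, 30, 30.0)])
        with pytest.raises(ValueError, match="cover"):
            t.lifetime_costs(base_trace, wm, base_params, 10.0)


class TestDecomposition:
    def test_published_components_reproduce_totals(self):
        b = breakdown_from_components(ref.LIFETIME_BREAKDOWN_USD, ref.TC3_USD,
                                      currency="USD")
        assert b.tc2 == pytest.approx(561_207.90, abs=0.01)
        assert b.tc1 == pytest.approx(606_665.46, abs=0.05)
        props = t.decompose_proportions(b)
        assert props["ict_drug"] == 56.9
        assert props["transfusion"] == 13.1
        assert props["tc3"] == 7.5

    def test_single_component_is_all_of_total(self):
        comps = {k: 0.0 for k in TC2_COMPONENTS}
        comps["ict_drug"] = 123.0
        b = breakdown_from_components(comps, 0.0)
        assert t.decompose_proportions(b)["ict_drug"] == 100.0

    def test_proportions_sum_to_hundred(self, base_params, base_trace,
                                        weight_model, mean_monthly):
        b = t.lifetime_costs(base_trace, weight_model, base_params,
                             mean_monthly)
        total = sum(t.decompose_proportions(b).values())
        assert total == pytest.approx(100.0, abs=0.2)

    def test_zero_total_rejected(self):
        b = breakdown_from_components({k: 0.0 for k in TC2_COMPONENTS}, 0.0)
        with pytest.raises(ValueError):
            t.decompose_proportions(b)

    def test_report_frame_carries_both_currencies(self, base_params,
                                                  base_trace, weight_model,
                                                  mean_monthly):
        b = t.lifetime_costs(base_trace, weight_model, base_params,
                             mean_monthly)
        frame = b.to_frame()
        assert list(frame.columns) == ["item", "usd", "myr", "pct_of_total"]
        row = frame.set_index("item").loc["tc1"]
        assert row["myr"] == pytest.approx(row["usd"] * 4.07, rel=1e-12)
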