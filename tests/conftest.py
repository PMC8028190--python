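"""Shared fixtures: packaged base case, calibrated synthetic inputs, and an
independent path-enumeration oracle for the cohort recursion."""

from __future__ import annotations

import numpy as np
import pytest

import tdtcost as t
from tdtcost.params import (
    ComplicationCost,
    CostParameters,
    CurrencyRate,
    ICTAgent,
    MonitoringCosts,
    MortalityInputs,
    RegimenPolicy,
    TransfusionCosts,
)


@pytest.fixture(scope="session")
def base_params() -> CostParameters:
    return t.default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return t.make_life_table(t.LifeTableSpec())


@pytest.fixture(scope="session")
def transitions():
    return t.make_transitions()


@pytest.fixture(scope="session")
def base_trace(base_params, life_table, transitions):
    return t.run_cohort(base_params, life_table, transitions)


@pytest.fixture(scope="session")
def survey():
    return t.make_survey(t.SurveySpec(seed=7))


@pytest.fixture(scope="session")
def weight_model(survey):
    records, _ = survey
    return t.fit_weight_model(records)


@pytest.fixture(scope="session")
def mean_monthly(survey):
    records, _ = survey
    return t.mean_monthly_expenditure(records).mean_total_monthly


def usd_table_params(compliance_scales_cost: bool = False,
                     dfo_days_per_week: float = 7.0) -> CostParameters:
    """The base case re-expressed in printed USD unit costs, with the raw
    365-day dosing arithmetic by default (for hand-checkable examples)."""
    params = CostParameters(
        agents={
            "DFO": ICTAgent("DFO", 10.81, 47.4, 0.773, 96.80,
                            "subcutaneous", dfo_days_per_week),
            "DFX": ICTAgent("DFX", 36.60, 24.6, 0.981, 0.0, "oral", 7.0),
            "DFP": ICTAgent("DFP", 0.49, 75.0, 0.903, 0.0, "oral", 7.0),
        },
        regimen_policy=RegimenPolicy(),
        monitoring=MonitoringCosts(55.39, 106.47),
        transfusion=TransfusionCosts(0.16, 2.71, 1.14),
        complications={
            "cardiac": ComplicationCost(536.36, 536.36),
            "diabetes": ComplicationCost(323.10, 323.10),
            "hypogonadism": ComplicationCost(175.40, 709.69),
            "hypoparathyroidism": ComplicationCost(128.72, 580.41),
            "hypothyroidism": ComplicationCost(40.43, 43.59),
        },
        mortality=MortalityInputs(),
        currency_rate=CurrencyRate(4.07),
        currency="USD",
        compliance_scales_cost=compliance_scales_cost,
    )
    params.validate()
    return params


@pytest.fixture()
def usd_params() -> CostParameters:
    return usd_table_params()


# ---------------------------------------------------------------------------
# independent oracle: brute-force enumeration of all individual event paths


def enumerate_cohort_paths(ages, q, relative_risk, cardiac_excess, p_onset):
    """State occupancies by exhaustive enumeration of event paths.

    Walks every sequence of per-cycle outcomes (onset yes/no, death yes/no)
    an individual can experience, multiplying branch probabilities, and
    accumulates the probability of occupying each state at the start of each
    cycle.  Exponential in the number of cycles; intended for <= 3 cycles.
    Conventions mirror the cohort model: onset first, then death; cardiac
    tunnel advances yearly.
    """
    occ = {age: {"no_cardiac": 0.0, "cardiac_y1": 0.0, "cardiac_y2p": 0.0,
                 "dead": 0.0} for age in ages}

    def state_label(state, years):
        if state == "dead":
            return "dead"
        if state == "nc":
            return "no_cardiac"
        return "cardiac_y1" if years == 0 else "cardiac_y2p"

    def walk(i, state, years_since_onset, prob):
        occ[ages[i]][state_label(state, years_since_onset)] += prob
        if i == len(ages) - 1:
            return
        if state == "dead":  # absorbing: dead for all remaining ages
            for j in range(i + 1, len(ages)):
                occ[ages[j]]["dead"] += prob
            return
        age = ages[i]
        base = min(1.0, q[age] * relative_risk)
        d_c = 1.0 - (1.0 - base) * (1.0 - cardiac_excess)
        if state == "nc":
            p = p_onset[age]
            walk(i + 1, "c", 0, prob * p * (1.0 - d_c))        # onset, survives
            walk(i + 1, "dead", None, prob * p * d_c)          # onset, dies
            walk(i + 1, "nc", None, prob * (1.0 - p) * (1.0 - base))
            walk(i + 1, "dead", None, prob * (1.0 - p) * base)
        else:  # cardiac
            walk(i + 1, "c", years_since_onset + 1, prob * (1.0 - d_c))
            walk(i + 1, "dead", None, prob * d_c)

    walk(0, "nc", None, 1.0)
    return occ


def assert_trace_close(cohort, micro, columns, n, z=3.0):
    """Every microsimulated occupancy within z binomial SE of the cohort."""
    for age in cohort.ages:
        for col in columns:
            p = float(cohort.frame.loc[age, col])
            est = float(micro.frame.loc[age, col])
            tol = z * np.sqrt(p * (1.0 - p) / n) + 1e-9
            assert abs(est - p) <= tol, (
                f"{col} at age {age}: cohort {p:.5f}, microsim {est:.5f}, "
                f"tol {tol:.5f}")
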