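"""Per-cycle component costs and their lifetime aggregation.

The societal lifetime cost per patient is

    TC1 = TC2 + TC3

where TC2 (provider perspective) folds annual chelation, DFO
administration, monitoring, transfusion and iron-overload complication
costs over the cohort's survival curve, and TC3 (patient and family
perspective) is the survey mean monthly expenditure times twelve, likewise
survival-weighted:

    component = sum_age annual_component(age) * alive(age)
    TC3       = mean_monthly * 12 * sum_age alive(age)

Costs accrue on start-of-cycle alive probability; no half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .markov import CohortTrace
from .params import (
    COMPLICATIONS,
    ComplicationCost,
    CostParameters,
    CurrencyRate,
    MonitoringCosts,
    TransfusionCosts,
    resolve_regimen,
)
from .weight import WeightModel, predict_weight

#: TC2 component keys, in reporting order.
TC2_COMPONENTS = ("ict_drug", "transfusion", "monitoring", "iol", "dfo_admin")


@dataclass
class AnnualCostVector:
    """Component costs for one cycle at one age (same currency as params)."""

    ict_drug: float
    dfo_admin: float
    monitoring: float
    transfusion: float
    iol: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ict_drug": self.ict_drug,
            "dfo_admin": self.dfo_admin,
            "monitoring": self.monitoring,
            "transfusion": self.transfusion,
            "iol": self.iol,
        }


def annual_ict_cost(age: int, weight: float, params: CostParameters
                    ) -> tuple[float, float]:
    """Annual drug acquisition and administration cost at ``age``.

    For each agent of each regimen in the resolved mix, the annual drug mass
    is dose (mg/kg/day) x weight x dosing days per year; the cost is that
    mass (in grams) times the per-gram price, scaled by compliance when
    ``params.compliance_scales_cost`` is set (consumed rather than dispensed
    doses).  Regimens containing DFO add twelve months of infusion-consumable
    administration cost, which is not compliance-scaled.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    mix = resolve_regimen(age, params.regimen_policy, params.entry_age)
    drug = 0.0
    admin = 0.0
    for regimen, w in mix.items():
        for name in regimen:
            agent = params.agents[name]
            grams = agent.dose_mg_per_kg_day * weight * agent.annual_dose_days / 1000.0
            cost = grams * agent.unit_price_per_g
            if params.compliance_scales_cost:
                cost *= agent.compliance
            drug += w * cost
        if "DFO" in regimen:
            admin += w * 12.0 * params.agents["DFO"].admin_monthly_cost
    return drug, admin


def annual_transfusion_cost(weight: float, tc: TransfusionCosts) -> float:
    """Annual transfusion cost: volume-driven blood cost plus fixed
    crossmatch and equipment charges per episode."""
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    per_transfusion = (weight * tc.ml_per_kg * tc.per_ml
                       + tc.crossmatch_per_transfusion
                       + tc.equipment_per_transfusion)
    return tc.transfusions_per_year * per_transfusion


def annual_monitoring_cost(age: int, m: MonitoringCosts) -> float:
    """Twelve months of routine surveillance; the older-age schedule applies
    from the cutoff age (>= cutoff) upwards."""
    if age < 0:
        raise ValueError("age must be >= 0")
    monthly = m.monthly_under10 if age < m.age_cutoff else m.monthly_10plus
    return 12.0 * monthly


def annual_iol_cost(strata: Mapping[str, tuple[float, float]],
                    table: Mapping[str, ComplicationCost]) -> float:
    """Expected complication-management cost for one cycle.

    ``strata`` maps each complication to its (year-1, year-2+) prevalence;
    the cost is the prevalence-weighted sum of the onset-year and
    established-year annual costs.
    """
    total = 0.0
    for name, (y1, y2p) in strata.items():
        if not (0.0 <= y1 <= 1.0 and 0.0 <= y2p <= 1.0):
            raise ValueError(f"{name}: prevalence outside [0, 1]")
        cost = table[name]
        total += y1 * cost.year1 + y2p * cost.year2plus
    return total


@dataclass
class LifetimeCostBreakdown:
    """Lifetime components, TC2, TC3 and TC1, with currency metadata."""

    components: dict[str, float]  # TC2 components, keys TC2_COMPONENTS
    tc3: float
    currency: str = "MYR"
    rate: CurrencyRate = field(default_factory=CurrencyRate)

    def __post_init__(self) -> None:
        missing = set(TC2_COMPONENTS) - set(self.components)
        if missing:
            raise ValueError(f"missing TC2 components: {sorted(missing)}")

    @property
    def tc2(self) -> float:
        return sum(self.components[k] for k in TC2_COMPONENTS)

    @property
    def tc1(self) -> float:
        return self.tc2 + self.tc3

    def scaled_component(self, key: str, factor: float) -> "LifetimeCostBreakdown":
        """Copy of the breakdown with one TC2 component scaled."""
        comps = dict(self.components)
        comps[key] = comps[key] * factor
        return LifetimeCostBreakdown(comps, self.tc3, self.currency, self.rate)

    def in_usd(self, value: float) -> float:
        if self.currency == "USD":
            return value
        return self.rate.myr_to_usd(value)

    def in_myr(self, value: float) -> float:
        if self.currency == "MYR":
            return value
        return self.rate.usd_to_myr(value)

    def to_frame(self) -> pd.DataFrame:
        """Report-shaped table: one row per component plus TC3 and TC1,
        in both currencies with percent of total."""
        rows = []
        for key in TC2_COMPONENTS:
            v = self.components[key]
            rows.append((key, self.in_usd(v), self.in_myr(v),
                         100.0 * v / self.tc1))
        rows.append(("tc3", self.in_usd(self.tc3), self.in_myr(self.tc3),
                     100.0 * self.tc3 / self.tc1))
        rows.append(("tc1", self.in_usd(self.tc1), self.in_myr(self.tc1),
                     100.0))
        return pd.DataFrame(rows, columns=["item", "usd", "myr", "pct_of_total"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def decompose_proportions(b: LifetimeCostBreakdown,
                          decimals: int = 1) -> dict[str, float]:
    """Each component (and TC3) as a percentage of TC1, rounded."""
    if b.tc1 <= 0:
        raise ValueError("TC1 must be positive to decompose proportions")
    out = {k: round(100.0 * b.components[k] / b.tc1, decimals)
           for k in TC2_COMPONENTS}
    out["tc3"] = round(100.0 * b.tc3 / b.tc1, decimals)
    return out


def annual_cost_vector(age: int, trace: CohortTrace, weight_model: WeightModel,
                       params: CostParameters) -> AnnualCostVector:
    weight = predict_weight(age, weight_model)
    drug, admin = annual_ict_cost(age, weight, params)
    return AnnualCostVector(
        ict_drug=drug,
        dfo_admin=admin,
        monitoring=annual_monitoring_cost(age, params.monitoring),
        transfusion=annual_transfusion_cost(weight, params.transfusion),
        iol=annual_iol_cost(trace.iol_strata(age), params.complications),
    )


def cost_trace(trace: CohortTrace, weight_model: WeightModel,
               params: CostParameters) -> pd.DataFrame:
    """Per-age annual component costs and their survival-weighted accruals."""
    ages = list(params.ages)
    if weight_model.lo > ages[0] or weight_model.hi < ages[-1]:
        raise ValueError(
            f"weight model [{weight_model.lo}, {weight_model.hi}] does not "
            f"cover model ages [{ages[0]}, {ages[-1]}]")
    rows = []
    for age in ages:
        vec = annual_cost_vector(age, trace, weight_model, params).as_dict()
        alive = trace.alive(age)
        row = {"age": age, "alive": alive}
        row.update(vec)
        row.update({f"accrued_{k}": v * alive for k, v in vec.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("age")


def lifetime_costs(trace: CohortTrace, weight_model: WeightModel,
                   params: CostParameters, mean_monthly_family_cost: float
                   ) -> LifetimeCostBreakdown:
    """Fold annual costs over the cohort trace into the TC1 breakdown.

    ``mean_monthly_family_cost`` must be in the same currency as ``params``
    (MYR for the packaged base case); it is a single population-level mean,
    not age-varying.
    """
    ct = cost_trace(trace, weight_model, params)
    components = {k: float(ct[f"accrued_{k}"].sum()) for k in TC2_COMPONENTS}
    person_years = float(ct["alive"].sum())
    tc3 = mean_monthly_family_cost * 12.0 * person_years
    return LifetimeCostBreakdown(components=components, tc3=tc3,
                                 currency=params.currency,
                                 rate=params.currency_rate)


def breakdown_from_components(components: Mapping[str, float], tc3: float,
                              currency: str = "USD",
                              rate: CurrencyRate | None = None
                              ) -> LifetimeCostBreakdown:
    """Assemble a breakdown from externally supplied lifetime components
    (e.g. a published decomposition) without re-running the model."""
    return LifetimeCostBreakdown(components=dict(components), tc3=tc3,
                                 currency=currency,
                                 rate=rate or CurrencyRate())
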