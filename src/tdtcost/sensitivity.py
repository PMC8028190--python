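"""One-way sensitivity analysis of the lifetime cost model.

Each scenario perturbs a single input — a numeric parameter swept between a
low and a high value, or a wholesale regimen-policy override such as
lifetime DFX — re-runs the cost engine with everything else held at base
case, and reports the percent change of TC1 and TC2.  Results are assembled
into a tornado-style ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .costs import LifetimeCostBreakdown, lifetime_costs
from .markov import LifeTable, TransitionModel, run_cohort
from .params import CostParameters, RegimenPolicy
from .weight import WeightModel


class ScenarioError(ValueError):
    """Raised for an unknown parameter path or malformed scenario."""


@dataclass
class Scenario:
    label: str
    kind: str = "numeric_range"  # or "regimen_override"
    parameter_path: str | None = None
    low_value: float | None = None
    high_value: float | None = None
    regimen_policy: RegimenPolicy | None = None

    def __post_init__(self) -> None:
        if self.kind == "numeric_range":
            if self.parameter_path is None:
                raise ScenarioError(f"{self.label}: numeric scenario needs a "
                                    "parameter_path")
            if (self.low_value is not None and self.high_value is not None
                    and self.low_value > self.high_value):
                raise ScenarioError(f"{self.label}: low > high")
        elif self.kind == "regimen_override":
            if self.regimen_policy is None:
                raise ScenarioError(f"{self.label}: regimen override needs a "
                                    "regimen_policy")
        else:
            raise ScenarioError(f"{self.label}: unknown kind {self.kind!r}")


@dataclass
class SensitivityResult:
    label: str
    base: LifetimeCostBreakdown
    low: LifetimeCostBreakdown | None
    high: LifetimeCostBreakdown | None

    def pct_change(self, endpoint: str = "tc1", side: str = "high") -> float:
        """Percent change of ``tc1`` or ``tc2`` relative to base case."""
        alt = {"low": self.low, "high": self.high}[side]
        if alt is None:
            return 0.0
        b = getattr(self.base, endpoint)
        return 100.0 * (getattr(alt, endpoint) - b) / b

    def max_abs_pct(self, endpoint: str = "tc1") -> float:
        return max(abs(self.pct_change(endpoint, s)) for s in ("low", "high"))


def _set_path(params: CostParameters, path: str, value: Any) -> None:
    parts = path.split(".")
    obj: Any = params
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise ScenarioError(f"unknown parameter path {path!r} "
                                    f"(no key {part!r})")
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ScenarioError(f"unknown parameter path {path!r} "
                                f"(no attribute {part!r})")
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ScenarioError(f"unknown parameter path {path!r}")
        obj[leaf] = value
    elif hasattr(obj, leaf):
        setattr(obj, leaf, value)
    else:
        raise ScenarioError(f"unknown parameter path {path!r}")


def _perturbed(base: CostParameters, scenario: Scenario,
               value: Any) -> CostParameters:
    params = base.copy()
    if scenario.kind == "regimen_override":
        params.regimen_policy = scenario.regimen_policy
    else:
        _set_path(params, scenario.parameter_path, value)
    params.validate()
    return params


def run_scenario(base: CostParameters, scenario: Scenario,
                 life_table: LifeTable, transitions: TransitionModel,
                 weight_model: WeightModel, mean_monthly_family_cost: float,
                 base_result: LifetimeCostBreakdown | None = None
                 ) -> SensitivityResult:
    """Evaluate one scenario against the shared base inputs.

    The cohort trace is re-run per evaluation (transition inputs are shared,
    so only cost parameters differ, but re-running keeps the path uniform
    and cheap).  ``base_result`` may be passed to reuse a precomputed base.
    """
    def evaluate(params: CostParameters) -> LifetimeCostBreakdown:
        trace = run_cohort(params, life_table, transitions)
        return lifetime_costs(trace, weight_model, params,
                              mean_monthly_family_cost)

    if base_result is None:
        base_result = evaluate(base)

    if scenario.kind == "regimen_override":
        high = evaluate(_perturbed(base, scenario, None))
        low = None
    else:
        low = (evaluate(_perturbed(base, scenario, scenario.low_value))
               if scenario.low_value is not None else None)
        high = (evaluate(_perturbed(base, scenario, scenario.high_value))
                if scenario.high_value is not None else None)
    return SensitivityResult(label=scenario.label, base=base_result,
                             low=low, high=high)


def tornado(results: Sequence[SensitivityResult],
            endpoint: str = "tc1") -> pd.DataFrame:
    """Scenarios ordered by descending absolute percent change.

    Ties are broken lexicographically by scenario label so the ordering is
    deterministic under permuted input.
    """
    if not results:
        raise ValueError("need at least one result")
    rows = []
    for r in results:
        rows.append({
            "label": r.label,
            "pct_low": r.pct_change(endpoint, "low"),
            "pct_high": r.pct_change(endpoint, "high"),
            "max_abs_pct": r.max_abs_pct(endpoint),
            f"base_{endpoint}": getattr(r.base, endpoint),
        })
    df = pd.DataFrame(rows)
    return (df.sort_values(["max_abs_pct", "label"],
                           ascending=[False, True])
            .reset_index(drop=True))


def plot_tornado(report: pd.DataFrame, path: str | Path,
                 endpoint: str = "tc1") -> None:
    """Horizontal-bar tornado chart of the report from :func:`tornado`."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.6 * len(report) + 1.5))
    ypos = range(len(report))[::-1]
    ax.barh(list(ypos), report["pct_high"], color="#c44e52", label="high")
    ax.barh(list(ypos), report["pct_low"], color="#4c72b0", label="low")
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(report["label"])
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"% change in {endpoint.upper()} from base case")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def all_dfx_scenario() -> Scenario:
    """Lifetime oral-DFX regimen for every age (the headline scenario)."""
    return Scenario(
        label="all patients on DFX for life",
        kind="regimen_override",
        regimen_policy=RegimenPolicy(
            child_regimen={("DFX",): 1.0},
            adult_regimen={("DFX",): 1.0},
            switch_age=16))


def default_scenarios(base: CostParameters) -> list[Scenario]:
    """The documented default one-way set: lifetime DFX, transfusion volume
    15-20 ml/kg, transfusion frequency 12-17 per year, and each drug price
    +/- 20 percent."""
    scenarios = [
        all_dfx_scenario(),
        Scenario(label="transfusion volume 15-20 ml/kg",
                 parameter_path="transfusion.ml_per_kg",
                 low_value=15.0, high_value=20.0),
        Scenario(label="transfusions per year 12-17",
                 parameter_path="transfusion.transfusions_per_year",
                 low_value=12, high_value=17),
    ]
    for name in ("DFO", "DFX", "DFP"):
        price = base.agents[name].unit_price_per_g
        scenarios.append(Scenario(
            label=f"{name} price +/-20%",
            parameter_path=f"agents.{name}.unit_price_per_g",
            low_value=0.8 * price, high_value=1.2 * price))
    return scenarios


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Read a YAML list of scenarios (numeric ranges or regimen overrides)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    scenarios = []
    for item in raw:
        if "regimen_policy" in item:
            pol = item["regimen_policy"]
            item = dict(item, kind="regimen_override",
                        regimen_policy=RegimenPolicy(
                            child_regimen=pol.get("child", {"DFX": 1.0}),
                            adult_regimen=pol.get("adult", {"DFX": 1.0}),
                            switch_age=pol.get("switch_age", 16)))
        scenarios.append(Scenario(**item))
    return scenarios
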