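"""Base-case model inputs: unit costs, doses, regimen policy, mortality.

All monetary fields of a :class:`CostParameters` are expressed in a single
currency (``MYR`` by default, the native currency of the underlying unit-cost
sources); conversion to USD is a reporting step applied once through
:class:`CurrencyRate`.  Parameter files are YAML (JSON is a subset and is
accepted); the packaged base case lives in ``tdtcost/data/basecase.yaml``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

AGENTS = ("DFO", "DFX", "DFP")
ORAL_AGENTS = ("DFX", "DFP")
COMPLICATIONS = (
    "cardiac",
    "diabetes",
    "hypogonadism",
    "hypoparathyroidism",
    "hypothyroidism",
)
#: complications that do not alter mortality; they enter through costs only
ENDOCRINE_COMPLICATIONS = COMPLICATIONS[1:]

_REQUIRED_KEYS = (
    "agents",
    "regimen_policy",
    "monitoring",
    "transfusion",
    "complications",
    "mortality",
)


class ParameterError(ValueError):
    """A parameter file violated the schema or an invariant.

    The message lists every violation found, each prefixed with the dotted
    key path of the offending entry.
    """


def _check(errors: list[str], ok: bool, path: str, msg: str) -> None:
    if not ok:
        errors.append(f"{path}: {msg}")


@dataclass
class CurrencyRate:
    """MYR per USD exchange rate (single conversion point for reporting)."""

    myr_per_usd: float = 4.07

    def validate(self, path: str = "myr_per_usd") -> list[str]:
        errors: list[str] = []
        _check(errors, math.isfinite(self.myr_per_usd) and self.myr_per_usd > 0,
               path, "exchange rate must be a positive finite number")
        return errors

    def myr_to_usd(self, amount: float) -> float:
        return amount / self.myr_per_usd

    def usd_to_myr(self, amount: float) -> float:
        return amount * self.myr_per_usd


def convert_currency(amount: float, direction: str, rate: CurrencyRate) -> float:
    """Convert ``amount`` between MYR and USD.

    ``direction`` is ``"myr_to_usd"`` or ``"usd_to_myr"``.  The conversion is
    exact and multiplicative, so a round trip returns the input to within
    floating-point representation error.
    """
    if not math.isfinite(amount):
        raise ValueError(f"cannot convert non-finite amount {amount!r}")
    if direction == "myr_to_usd":
        return rate.myr_to_usd(amount)
    if direction == "usd_to_myr":
        return rate.usd_to_myr(amount)
    raise ValueError(f"unknown conversion direction {direction!r}")


@dataclass
class ICTAgent:
    """One iron-chelating agent and its costing inputs.

    ``dose_days_per_week`` reflects the administration schedule: oral agents
    (DFX, DFP) are taken daily, while subcutaneous DFO is infused five nights
    a week, which is also why only DFO carries a monthly administration cost
    (infusion pump consumables supplied by the hospital).
    """

    name: str
    unit_price_per_g: float  # currency per gram of drug
    dose_mg_per_kg_day: float
    compliance: float  # fraction in [0, 1]
    admin_monthly_cost: float = 0.0
    route: str = "oral"
    dose_days_per_week: float = 7.0

    def validate(self, path: str) -> list[str]:
        errors: list[str] = []
        _check(errors, self.name in AGENTS, f"{path}.name",
               f"unknown agent {self.name!r}; expected one of {AGENTS}")
        _check(errors, self.unit_price_per_g >= 0, f"{path}.unit_price_per_g",
               "unit price must be >= 0")
        _check(errors, self.dose_mg_per_kg_day > 0, f"{path}.dose_mg_per_kg_day",
               "prescribed dose must be > 0")
        _check(errors, 0.0 <= self.compliance <= 1.0, f"{path}.compliance",
               f"compliance {self.compliance} outside [0, 1]")
        _check(errors, self.admin_monthly_cost >= 0, f"{path}.admin_monthly_cost",
               "administration cost must be >= 0")
        _check(errors, self.route in ("oral", "subcutaneous"), f"{path}.route",
               f"unknown route {self.route!r}")
        if self.route == "oral":
            _check(errors, self.admin_monthly_cost == 0, f"{path}.admin_monthly_cost",
                   "oral agents carry no administration cost")
        if self.admin_monthly_cost > 0:
            _check(errors, self.name == "DFO", f"{path}.admin_monthly_cost",
                   "only DFO carries an administration cost")
        _check(errors, 0 < self.dose_days_per_week <= 7, f"{path}.dose_days_per_week",
               "dosing days per week must be in (0, 7]")
        return errors

    @property
    def annual_dose_days(self) -> float:
        return 365.0 * self.dose_days_per_week / 7.0


Regimen = tuple[str, ...]  # e.g. ("DFO", "DFP") for combination therapy


def parse_regimen(label: str | Regimen) -> Regimen:
    """Parse ``"DFO+DFP"`` (or an already-split tuple) into a sorted tuple."""
    if isinstance(label, str):
        parts = tuple(p.strip() for p in label.split("+"))
    else:
        parts = tuple(label)
    return tuple(sorted(parts))


def format_regimen(regimen: Regimen) -> str:
    return "+".join(regimen)


@dataclass
class RegimenPolicy:
    """Age-dependent chelation policy.

    Children are initiated on oral DFX; from ``switch_age`` onwards patients
    move to DFO-based regimens (cheaper per kg as body weight rises).  Each
    mapping assigns weights (cohort fractions) to regimens, where a regimen
    is a combination of agent names such as ``DFO+DFP``.
    """

    child_regimen: dict[Regimen, float] = field(
        default_factory=lambda: {("DFX",): 1.0})
    adult_regimen: dict[Regimen, float] = field(
        default_factory=lambda: {("DFO",): 0.5, ("DFO", "DFP"): 0.5})
    switch_age: int = 16

    def __post_init__(self) -> None:
        self.child_regimen = {parse_regimen(k): float(v)
                              for k, v in self.child_regimen.items()}
        self.adult_regimen = {parse_regimen(k): float(v)
                              for k, v in self.adult_regimen.items()}

    def validate(self, path: str, entry_age: int) -> list[str]:
        errors: list[str] = []
        for side, mix in (("child_regimen", self.child_regimen),
                          ("adult_regimen", self.adult_regimen)):
            _check(errors, mix and abs(sum(mix.values()) - 1.0) < 1e-9,
                   f"{path}.{side}", "regimen weights must sum to 1")
            for regimen, w in mix.items():
                _check(errors, w >= 0, f"{path}.{side}[{format_regimen(regimen)}]",
                       "regimen weight must be >= 0")
                for agent in regimen:
                    _check(errors, agent in AGENTS,
                           f"{path}.{side}[{format_regimen(regimen)}]",
                           f"unknown agent {agent!r}")
        _check(errors, self.switch_age >= entry_age, f"{path}.switch_age",
               f"switch age {self.switch_age} below entry age {entry_age}")
        return errors


def resolve_regimen(age: int, policy: RegimenPolicy,
                    entry_age: int = 2) -> dict[Regimen, float]:
    """Weighted regimen mix applying at ``age``.

    The boundary is half-open: ages in ``[entry_age, switch_age)`` use the
    child regimen and ages ``>= switch_age`` the adult regimen, so the switch
    applies in the cycle starting at ``switch_age`` itself.
    """
    if age < entry_age:
        raise ValueError(f"age {age} below cohort entry age {entry_age}")
    if age < policy.switch_age:
        return dict(policy.child_regimen)
    return dict(policy.adult_regimen)


@dataclass
class MonitoringCosts:
    """Routine laboratory and imaging surveillance, monthly, by age group."""

    monthly_under10: float
    monthly_10plus: float
    age_cutoff: int = 10

    def validate(self, path: str) -> list[str]:
        errors: list[str] = []
        _check(errors, self.monthly_under10 >= 0, f"{path}.monthly_under10",
               "cost must be >= 0")
        _check(errors, self.monthly_10plus >= 0, f"{path}.monthly_10plus",
               "cost must be >= 0")
        return errors


@dataclass
class TransfusionCosts:
    """Packed red-cell transfusion inputs: 15 ml/kg monthly by default."""

    per_ml: float
    crossmatch_per_transfusion: float
    equipment_per_transfusion: float
    ml_per_kg: float = 15.0
    transfusions_per_year: int = 12

    def validate(self, path: str) -> list[str]:
        errors: list[str] = []
        for name in ("per_ml", "crossmatch_per_transfusion",
                     "equipment_per_transfusion"):
            _check(errors, getattr(self, name) >= 0, f"{path}.{name}",
                   "cost must be >= 0")
        _check(errors, 0 <= self.ml_per_kg <= 30, f"{path}.ml_per_kg",
               f"transfusion volume {self.ml_per_kg} outside [0, 30] ml/kg")
        _check(errors, self.transfusions_per_year >= 0,
               f"{path}.transfusions_per_year", "must be >= 0")
        return errors


@dataclass
class ComplicationCost:
    """Annual management cost of one complication, split by year of onset."""

    year1: float
    year2plus: float

    def validate(self, path: str) -> list[str]:
        errors: list[str] = []
        _check(errors, self.year1 >= 0, f"{path}.year1", "cost must be >= 0")
        _check(errors, self.year2plus >= 0, f"{path}.year2plus",
               "cost must be >= 0")
        return errors


@dataclass
class MortalityInputs:
    """Excess mortality of the TDT cohort over the general population."""

    relative_risk: float = 3.9
    cardiac_excess_annual_prob: float = 0.0062

    def validate(self, path: str) -> list[str]:
        errors: list[str] = []
        _check(errors, self.relative_risk > 0, f"{path}.relative_risk",
               "relative risk must be > 0")
        _check(errors, 0 <= self.cardiac_excess_annual_prob <= 1,
               f"{path}.cardiac_excess_annual_prob",
               "annual probability outside [0, 1]")
        return errors


@dataclass
class CostParameters:
    """Complete base-case input set for the lifetime cost model."""

    agents: dict[str, ICTAgent]
    regimen_policy: RegimenPolicy
    monitoring: MonitoringCosts
    transfusion: TransfusionCosts
    complications: dict[str, ComplicationCost]
    mortality: MortalityInputs = field(default_factory=MortalityInputs)
    currency_rate: CurrencyRate = field(default_factory=CurrencyRate)
    currency: str = "MYR"
    entry_age: int = 2
    horizon_age: int = 58
    compliance_scales_cost: bool = True

    def validate(self) -> None:
        """Raise :class:`ParameterError` listing every violated invariant."""
        errors: list[str] = []
        for name, agent in self.agents.items():
            _check(errors, name == agent.name, f"agents.{name}.name",
                   f"key {name!r} does not match agent name {agent.name!r}")
            errors.extend(agent.validate(f"agents.{name}"))
        for name in AGENTS:
            _check(errors, name in self.agents, f"agents.{name}",
                   "missing agent entry")
        errors.extend(self.regimen_policy.validate("regimen_policy",
                                                   self.entry_age))
        errors.extend(self.monitoring.validate("monitoring"))
        errors.extend(self.transfusion.validate("transfusion"))
        for name in COMPLICATIONS:
            if name not in self.complications:
                errors.append(f"complications.{name}: missing complication entry")
            else:
                errors.extend(
                    self.complications[name].validate(f"complications.{name}"))
        errors.extend(self.mortality.validate("mortality"))
        errors.extend(self.currency_rate.validate())
        _check(errors, self.currency in ("MYR", "USD"), "currency",
               f"unknown currency {self.currency!r}")
        _check(errors, self.entry_age < self.horizon_age, "entry_age",
               f"entry age {self.entry_age} must precede horizon "
               f"{self.horizon_age}")
        if errors:
            raise ParameterError(
                "invalid parameters:\n  " + "\n  ".join(errors))

    @property
    def ages(self) -> range:
        """Integer model ages, entry through horizon inclusive."""
        return range(self.entry_age, self.horizon_age + 1)

    def copy(self) -> "CostParameters":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "currency": self.currency,
            "myr_per_usd": self.currency_rate.myr_per_usd,
            "entry_age": self.entry_age,
            "horizon_age": self.horizon_age,
            "compliance_scales_cost": self.compliance_scales_cost,
            "agents": {
                name: {
                    "unit_price_per_g": a.unit_price_per_g,
                    "dose_mg_per_kg_day": a.dose_mg_per_kg_day,
                    "compliance": a.compliance,
                    "admin_monthly_cost": a.admin_monthly_cost,
                    "route": a.route,
                    "dose_days_per_week": a.dose_days_per_week,
                }
                for name, a in self.agents.items()
            },
            "regimen_policy": {
                "child": {format_regimen(r): w
                          for r, w in self.regimen_policy.child_regimen.items()},
                "adult": {format_regimen(r): w
                          for r, w in self.regimen_policy.adult_regimen.items()},
                "switch_age": self.regimen_policy.switch_age,
            },
            "monitoring": {
                "monthly_under10": self.monitoring.monthly_under10,
                "monthly_10plus": self.monitoring.monthly_10plus,
                "age_cutoff": self.monitoring.age_cutoff,
            },
            "transfusion": {
                "per_ml": self.transfusion.per_ml,
                "crossmatch_per_transfusion":
                    self.transfusion.crossmatch_per_transfusion,
                "equipment_per_transfusion":
                    self.transfusion.equipment_per_transfusion,
                "ml_per_kg": self.transfusion.ml_per_kg,
                "transfusions_per_year": self.transfusion.transfusions_per_year,
            },
            "complications": {
                name: {"year1": c.year1, "year2plus": c.year2plus}
                for name, c in self.complications.items()
            },
            "mortality": {
                "relative_risk": self.mortality.relative_risk,
                "cardiac_excess_annual_prob":
                    self.mortality.cardiac_excess_annual_prob,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")


def parameters_from_dict(raw: Mapping) -> CostParameters:
    """Build and validate :class:`CostParameters` from a parsed config mapping."""
    if not isinstance(raw, Mapping) or not raw:
        raise ParameterError(
            "empty or malformed config; required keys: "
            + ", ".join(_REQUIRED_KEYS))
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ParameterError(
            "missing required keys: " + ", ".join(missing))

    try:
        agents = {
            name: ICTAgent(name=name, **spec)
            for name, spec in raw["agents"].items()
        }
        pol = raw["regimen_policy"]
        policy = RegimenPolicy(
            child_regimen=dict(pol.get("child", {"DFX": 1.0})),
            adult_regimen=dict(pol.get("adult", {"DFO": 0.5, "DFO+DFP": 0.5})),
            switch_age=int(pol.get("switch_age", 16)),
        )
        monitoring = MonitoringCosts(**raw["monitoring"])
        transfusion = TransfusionCosts(**raw["transfusion"])
        complications = {
            name: ComplicationCost(**spec)
            for name, spec in raw["complications"].items()
        }
        mortality = MortalityInputs(**raw["mortality"])
    except TypeError as exc:  # unknown/missing dataclass field
        raise ParameterError(f"schema error: {exc}") from exc

    params = CostParameters(
        agents=agents,
        regimen_policy=policy,
        monitoring=monitoring,
        transfusion=transfusion,
        complications=complications,
        mortality=mortality,
        currency_rate=CurrencyRate(float(raw.get("myr_per_usd", 4.07))),
        currency=str(raw.get("currency", "MYR")),
        entry_age=int(raw.get("entry_age", 2)),
        horizon_age=int(raw.get("horizon_age", 58)),
        compliance_scales_cost=bool(raw.get("compliance_scales_cost", True)),
    )
    params.validate()
    return params


def load_parameters(path: str | Path) -> CostParameters:
    """Load, validate and default-fill a YAML/JSON parameter file."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if raw is None:
        raise ParameterError(
            "empty config file; required keys: " + ", ".join(_REQUIRED_KEYS))
    return parameters_from_dict(raw)


def default_parameters() -> CostParameters:
    """The packaged MYR base case (2019 prices, MYR 4.07 per USD)."""
    text = (resources.files("tdtcost") / "data" / "basecase.yaml").read_text(
        encoding="utf-8")
    return parameters_from_dict(yaml.safe_load(text))
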