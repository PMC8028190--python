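"""Synthetic generators for every external model input.

The underlying national analysis rests on three inputs that are not public:
the Malaysian general-population life table, the complication-onset
probabilities taken from an earlier disease-progression model, and the
patient-level health-utilization survey.  This module generates stand-ins
with known ground truth — a Gompertz-Makeham life table calibrated to a
target cohort life expectancy, configurable onset curves, and survey
records drawn from the published log-linear expenditure model — so the
whole pipeline is exercisable and testable offline.  Every generator is a
pure function of its spec and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .markov import LifeTable, TransitionModel
from .params import MortalityInputs

# ---------------------------------------------------------------------------
# life table


@dataclass
class LifeTableSpec:
    """Gompertz-Makeham life table, optionally calibrated.

    Hazard mu(x) = makeham + gompertz_level * exp(gompertz_shape * x); the
    annual death probability is q(x) = 1 - exp(-integral of mu over the
    year).  When ``calibration_target`` is set, ``gompertz_level`` is solved
    by bisection so that a TDT cohort (death probability q * relative_risk,
    no cardiac onset) attains that life expectancy on the age scale
    (entry age + expected person-years within the horizon), to within
    ``tolerance`` years.
    """

    family: str = "gompertz_makeham"
    makeham: float = 5e-5
    gompertz_shape: float = 0.11
    gompertz_level: float | None = None  # solved when calibrating
    calibration_target: float | None = 57.7  # attained-age life expectancy
    relative_risk: float = 3.9
    entry_age: int = 2
    horizon_age: int = 58
    tolerance: float = 0.05


def _gm_q(age: np.ndarray, lam: float, alpha: float, beta: float) -> np.ndarray:
    if alpha == 0.0:
        integral = np.full_like(age, lam, dtype=float)
    else:
        integral = lam + alpha / beta * (math.exp(beta) - 1.0) * np.exp(beta * age)
    return 1.0 - np.exp(-integral)


def _attained_le(q: np.ndarray, rr: float, entry_age: int) -> float:
    """Attained-age life expectancy of the zero-onset TDT cohort."""
    p_death = np.minimum(1.0, q * rr)
    alive = 1.0
    total = 0.0
    for p in p_death:
        total += alive
        alive *= 1.0 - p
    total += alive  # start of the final (horizon) cycle
    return entry_age + total


def make_life_table(spec: LifeTableSpec, seed: int = 0) -> LifeTable:
    """Build the life table; deterministic given the spec (seed accepted for
    interface uniformity, the curve itself carries no noise)."""
    if spec.family != "gompertz_makeham":
        raise ValueError(f"unknown life-table family {spec.family!r}")
    ages = np.arange(spec.entry_age, spec.horizon_age + 1)
    transition_ages = ages[:-1].astype(float)

    if spec.calibration_target is None:
        if spec.gompertz_level is None:
            raise ValueError("set gompertz_level or a calibration target")
        level = spec.gompertz_level
    else:
        target = spec.calibration_target

        def le(log10_alpha: float) -> float:
            q = _gm_q(transition_ages, spec.makeham, 10.0 ** log10_alpha,
                      spec.gompertz_shape)
            return _attained_le(q, spec.relative_risk, spec.entry_age)

        lo, hi = -12.0, -2.0  # log10 of the Gompertz level
        if not (le(hi) <= target <= le(lo)):
            raise ValueError(
                f"calibration target {target} outside attainable range "
                f"[{le(hi):.2f}, {le(lo):.2f}] for these parameters")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if le(mid) > target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-13:
                break
        level = 10.0 ** (0.5 * (lo + hi))
        achieved = le(math.log10(level))
        if abs(achieved - target) > spec.tolerance:
            raise ValueError(
                f"calibration infeasible: achieved {achieved:.3f} vs "
                f"target {target}")

    q = _gm_q(ages.astype(float), spec.makeham, level, spec.gompertz_shape)
    return LifeTable(dict(zip(ages.tolist(), q.tolist())))


# ---------------------------------------------------------------------------
# transition probabilities


DEFAULT_ENDOCRINE_LEVELS = {
    # chosen so any-complication prevalence near the survey's mean age (~17)
    # is about 44%, matching the observed complication frequency
    "diabetes": 0.008,
    "hypogonadism": 0.02,
    "hypoparathyroidism": 0.004,
    "hypothyroidism": 0.006,
}
DEFAULT_CARDIAC_ONSET = 0.005


def make_transitions(cardiac_onset_level: float = DEFAULT_CARDIAC_ONSET,
                     endocrine_levels: dict[str, float] | None = None,
                     shape: str = "flat",
                     entry_age: int = 2,
                     horizon_age: int = 58,
                     mortality: MortalityInputs | None = None,
                     seed: int = 0) -> TransitionModel:
    """Annual onset curves, either age-flat or linearly age-ramped.

    A ramp runs from zero at entry age to twice the level at the horizon, so
    the age-averaged probability equals the level.  Deterministic given the
    arguments (the seed is part of the generator contract but the curves
    carry no noise).
    """
    if endocrine_levels is None:
        endocrine_levels = dict(DEFAULT_ENDOCRINE_LEVELS)
    for name, level in [("cardiac", cardiac_onset_level),
                        *endocrine_levels.items()]:
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"{name} onset level {level} outside [0, 1]")

    span = max(1, horizon_age - entry_age)

    def curve(level: float):
        if shape == "flat":
            return {a: level for a in range(entry_age, horizon_age + 1)}
        if shape == "ramp":
            return {a: min(1.0, 2.0 * level * (a - entry_age) / span)
                    for a in range(entry_age, horizon_age + 1)}
        raise ValueError(f"unknown shape {shape!r}")

    return TransitionModel(
        cardiac_onset=curve(cardiac_onset_level),
        endocrine_onset={c: curve(v) for c, v in endocrine_levels.items()},
        mortality=mortality or MortalityInputs(),
    )


# ---------------------------------------------------------------------------
# survey


#: Current-chelation mix observed in the survey (normalized before use).
SURVEY_REGIMEN_WEIGHTS = {
    "DFO": 0.117,
    "DFX": 0.415,
    "DFP": 0.122,
    "DFO+DFP": 0.268,
    "DFO+DFX": 0.056,
    "DFX+DFP": 0.021,
    "DFO+DFP+DFX": 0.002,
}

DEFAULT_REGION_WEIGHTS = {
    "central": 0.279,
    "southern": 0.139,
    "northern": 0.125,
    "east_coast": 0.272,
    "east_malaysia": 0.185,
}


@dataclass
class SurveySpec:
    """Generating model of a TDT health-utilization survey.

    Monthly total expenditure (MYR) is drawn from the published log-linear
    model ln(total) = b0 + b_income*income + b_visits*visits + b_dfo*DFO +
    b_years*years + eps, with the noise SD set so the regression R^2 on
    generated data is near ``target_r2`` (or fixed via ``noise_sd``).  The
    total is split into out-of-pocket / transportation / productivity
    components by fixed shares, and a configurable fraction of
    zero-expenditure respondents is injected.
    """

    n: int = 574
    age_mean: float = 17.3
    age_sd: float = 10.6
    age_min: int = 2
    age_max: int = 60
    weight_mean: float = 36.8
    weight_noise_sd: float = 6.0
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS))
    regimen_weights: dict[str, float] = field(
        default_factory=lambda: dict(SURVEY_REGIMEN_WEIGHTS))
    income_probs: tuple[float, ...] = (0.25, 0.30, 0.20, 0.15, 0.10)
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "const": 6.654,
        "income_category": 0.272,
        "visits_per_month": 0.294,
        "dfo_regimen": 0.262,
        "years_of_transfusion": 0.009,
    })
    target_r2: float = 0.492
    noise_sd: float | None = None  # overrides target_r2 when set
    component_shares: dict[str, float] = field(default_factory=lambda: {
        "cOOP": 0.335, "cTransportation": 0.311, "cProductivity": 0.355})
    zero_fraction: float = 0.10
    seed: int = 0


#: Growth curve underlying synthetic body weights: near-normal growth to 10,
#: slowed pubertal growth to 18, plateau thereafter (before calibration of
#: the overall level to the target mean weight).
_GROWTH_SEGMENTS = ((10, 8.0, 2.4), (18, 8.0 + 2.4 * 10 - 1.6 * 10, 1.6))
_GROWTH_PLATEAU_AGE = 19


def growth_curve(age, plateau: float | None = None) -> np.ndarray:
    """Median body weight (kg) by age for the synthetic cohort."""
    age = np.asarray(age, dtype=float)
    hi1, b1, s1 = _GROWTH_SEGMENTS[0]
    _, b2, s2 = _GROWTH_SEGMENTS[1]
    if plateau is None:
        plateau = b2 + s2 * (_GROWTH_PLATEAU_AGE - 0.5)
    w = np.where(age <= hi1, b1 + s1 * age,
                 np.where(age < _GROWTH_PLATEAU_AGE, b2 + s2 * age, plateau))
    return w


def _age_pmf(spec: SurveySpec) -> tuple[np.ndarray, np.ndarray]:
    """Probability mass of each integer age.

    Ages are a rounded normal truncated to ``[age_min, age_max]``; because
    truncation at the child end pulls the mean upward, the location of the
    underlying normal is solved so the *truncated* distribution has mean
    ``age_mean`` (the moment the survey reports).
    """
    return _age_pmf_cached(spec.age_min, spec.age_max, spec.age_mean,
                           spec.age_sd)


@lru_cache(maxsize=32)
def _age_pmf_cached(age_min: int, age_max: int, age_mean: float,
                    age_sd: float) -> tuple[np.ndarray, np.ndarray]:
    spec = SurveySpec(age_min=age_min, age_max=age_max, age_mean=age_mean,
                      age_sd=age_sd)
    ages = np.arange(spec.age_min, spec.age_max + 1)

    def pmf_for(loc: float) -> np.ndarray:
        a = (spec.age_min - 0.5 - loc) / spec.age_sd
        b = (spec.age_max + 0.5 - loc) / spec.age_sd
        dist = stats.truncnorm(a, b, loc=loc, scale=spec.age_sd)
        pmf = dist.cdf(ages + 0.5) - dist.cdf(ages - 0.5)
        return pmf / pmf.sum()

    lo, hi = spec.age_min - 20.0, spec.age_max + 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(ages @ pmf_for(mid)) < spec.age_mean:
            lo = mid
        else:
            hi = mid
    return ages, pmf_for(0.5 * (lo + hi))


def make_survey(spec: SurveySpec, seed: int | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic survey and return it with its ground truth.

    Returns ``(records, truth)`` where ``truth`` records the generating
    coefficients, the realized noise SD, component shares and seed.
    """
    share_sum = sum(spec.component_shares.values())
    # tolerate print rounding (published shares add to 100.1%)
    if abs(share_sum - 1.0) > 0.01 or min(spec.component_shares.values()) < 0:
        raise ValueError("component shares must be non-negative and sum to 1")
    shares = {k: v / share_sum for k, v in spec.component_shares.items()}
    if spec.n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    ages, pmf = _age_pmf(spec)
    age = rng.choice(ages, size=spec.n, p=pmf)

    # weight: growth curve shifted so the cohort mean matches the target
    shift = spec.weight_mean - float(growth_curve(ages) @ pmf)
    weight = growth_curve(age) + shift + rng.normal(0.0, spec.weight_noise_sd,
                                                    spec.n)
    weight = np.clip(weight, 3.0, None)

    regions = list(spec.region_weights)
    rw = np.array([spec.region_weights[r] for r in regions], dtype=float)
    region = rng.choice(regions, size=spec.n, p=rw / rw.sum())

    regimens = list(spec.regimen_weights)
    gw = np.array([spec.regimen_weights[r] for r in regimens], dtype=float)
    regimen = rng.choice(regimens, size=spec.n, p=gw / gw.sum())
    dfo = np.array(["DFO" in r for r in regimen], dtype=float)

    income = rng.choice(np.arange(1, len(spec.income_probs) + 1),
                        size=spec.n, p=np.asarray(spec.income_probs))

    # patients in East Malaysia revisit for scarce phenotype-matched blood
    east = region == "east_malaysia"
    visits = 1.0 + rng.poisson(np.where(east, 2.0, 0.3))

    age_first = np.minimum(1 + rng.poisson(2.0, size=spec.n), age)
    years = (age - age_first).astype(float)

    hours = rng.normal(np.where(east, 22.1, 11.7), np.where(east, 9.3, 7.1))
    hours = np.clip(hours, 0.0, None)

    beta = spec.coefficients
    xb = (beta["const"] + beta["income_category"] * income
          + beta["visits_per_month"] * visits + beta["dfo_regimen"] * dfo
          + beta["years_of_transfusion"] * years)
    if spec.noise_sd is not None:
        sigma = float(spec.noise_sd)
    else:
        r2 = spec.target_r2
        if not 0 < r2 <= 1:
            raise ValueError("target_r2 must be in (0, 1]")
        sigma = float(np.sqrt(np.var(xb) * (1.0 - r2) / r2))
    total = np.exp(xb + (rng.normal(0.0, sigma, spec.n) if sigma > 0 else 0.0))

    zero = rng.random(spec.n) < spec.zero_fraction
    total = np.where(zero, 0.0, total)

    records = pd.DataFrame({
        "region": region,
        "age": age,
        "weight": weight,
        "regimen": regimen,
        "dfo_regimen": dfo,
        "income_category": income.astype(float),
        "visits_per_month": visits.astype(float),
        "years_of_transfusion": years,
        "hours_in_hospital_per_month": hours,
        "cOOP": total * shares["cOOP"],
        "cTransportation": total * shares["cTransportation"],
        "cProductivity": total * shares["cProductivity"],
        "distance_km": np.nan,
        "transport_cost_missing": False,
    })
    truth = {
        "coefficients": dict(beta),
        "noise_sd": sigma,
        "target_r2": None if spec.noise_sd is not None else spec.target_r2,
        "component_shares": dict(shares),
        "zero_fraction": spec.zero_fraction,
        "n": spec.n,
        "seed": spec.seed if seed is None else seed,
        "weight_curve_shift": shift,
    }
    return records, truth


def save_survey(records: pd.DataFrame, truth: dict,
                csv_path: str | Path,
                truth_path: str | Path | None = None) -> None:
    """Write the survey CSV and its ground-truth JSON sidecar."""
    csv_path = Path(csv_path)
    records.to_csv(csv_path, index=False)
    if truth_path is None:
        truth_path = csv_path.with_suffix(".truth.json")
    Path(truth_path).write_text(json.dumps(truth, indent=2), encoding="utf-8")
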