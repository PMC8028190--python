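"""Yearly-cycle Markov cohort model of survival and complication onset.

States are ``no_cardiac`` (TDT without cardiac disease), ``cardiac`` and the
absorbing ``dead`` state.  The cardiac state is split into year-of-onset
tunnel strata (``cardiac_y1`` for onset this cycle, ``cardiac_y2p``
thereafter) because complication management costs differ between the first
and subsequent years.  Endocrine complications (diabetes, hypogonadism,
hypoparathyroidism, hypothyroidism) do not alter mortality; their onset is
tracked as tunnel prevalences *conditional on being alive*, which evolve
independently of survival because death is independent of endocrine status.

Within a cycle, onset events are evaluated first and death second, so a
patient whose cardiac disease begins this cycle already faces the cardiac
death probability.  Costs downstream accrue on start-of-cycle occupancy;
there is no half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .params import (
    ENDOCRINE_COMPLICATIONS,
    CostParameters,
    MortalityInputs,
)

STATE_COLUMNS = ("no_cardiac", "cardiac_y1", "cardiac_y2p", "dead")


class LifeTable:
    """General-population annual death probabilities q(age)."""

    def __init__(self, q_by_age: Mapping[int, float]):
        self._q = {int(a): float(q) for a, q in q_by_age.items()}
        for age, q in self._q.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"q({age}) = {q} outside [0, 1]")

    def q(self, age: int) -> float:
        try:
            return self._q[age]
        except KeyError:
            raise ValueError(f"age {age} not covered by life table "
                             f"[{self.min_age}, {self.max_age}]") from None

    @property
    def min_age(self) -> int:
        return min(self._q)

    @property
    def max_age(self) -> int:
        return max(self._q)

    def covers(self, ages) -> bool:
        return all(a in self._q for a in ages)

    def to_frame(self) -> pd.DataFrame:
        ages = sorted(self._q)
        return pd.DataFrame({"age": ages, "qx": [self._q[a] for a in ages]})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["age"], df["qx"])))


@dataclass
class TransitionModel:
    """Annual onset probabilities plus mortality inputs.

    ``cardiac_onset`` and each entry of ``endocrine_onset`` map an integer
    age to an annual probability.  Plain mappings or callables are accepted.
    """

    cardiac_onset: Callable[[int], float] | Mapping[int, float]
    endocrine_onset: dict[str, Callable[[int], float] | Mapping[int, float]]
    mortality: MortalityInputs = field(default_factory=MortalityInputs)

    def p_cardiac(self, age: int) -> float:
        return _prob(self.cardiac_onset, age, "cardiac onset")

    def p_endocrine(self, complication: str, age: int) -> float:
        curve = self.endocrine_onset.get(complication)
        if curve is None:
            return 0.0
        return _prob(curve, age, f"{complication} onset")


def _prob(curve, age: int, label: str) -> float:
    p = curve(age) if callable(curve) else curve.get(age, 0.0)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{label} probability {p} at age {age} outside [0, 1]")
    return float(p)


def annual_death_prob(age: int, state: str, life_table: LifeTable,
                      mortality: MortalityInputs) -> float:
    """Annual death probability of a TDT patient at ``age`` in ``state``.

    The general-population probability is scaled by the relative risk and
    capped at 1; in the cardiac state the excess cardiac mortality combines
    with it as independent competing risks (product of survivals).
    """
    base = min(1.0, life_table.q(age) * mortality.relative_risk)
    if state in ("cardiac", "cardiac_y1", "cardiac_y2p"):
        return 1.0 - (1.0 - base) * (1.0 - mortality.cardiac_excess_annual_prob)
    if state == "no_cardiac":
        return base
    raise ValueError(f"unknown alive state {state!r}")


class CohortTrace:
    """Per-age state occupancy of the closed cohort.

    Wraps a DataFrame indexed by age with unconditional occupancies
    ``no_cardiac``, ``cardiac_y1``, ``cardiac_y2p``, ``dead`` (summing to 1)
    plus ``alive``, and per endocrine complication ``<c>_y1`` / ``<c>_y2p``
    prevalences conditional on being alive.  Rows describe the cohort at the
    *start* of each yearly cycle.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @property
    def ages(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def alive(self, age: int) -> float:
        return float(self.frame.loc[age, "alive"])

    @property
    def alive_curve(self) -> pd.Series:
        return self.frame["alive"]

    def iol_strata(self, age: int) -> dict[str, tuple[float, float]]:
        """Year-1 / year-2+ prevalence of each costed complication at ``age``,
        conditional on being alive (cardiac strata are stored unconditionally
        and rescaled here)."""
        row = self.frame.loc[age]
        alive = row["alive"]
        if alive <= 0.0:
            return {c: (0.0, 0.0)
                    for c in ("cardiac", *ENDOCRINE_COMPLICATIONS)}
        strata = {"cardiac": (row["cardiac_y1"] / alive,
                              row["cardiac_y2p"] / alive)}
        for c in ENDOCRINE_COMPLICATIONS:
            strata[c] = (row[f"{c}_y1"], row[f"{c}_y2p"])
        return strata

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="age")


def run_cohort(params: CostParameters, life_table: LifeTable,
               transitions: TransitionModel) -> CohortTrace:
    """Deterministic forward recursion of state occupancies.

    The cohort starts entirely in ``no_cardiac`` at ``params.entry_age`` and
    is propagated one yearly cycle at a time up to ``params.horizon_age``.
    Dead is absorbing; tunnel strata advance each cycle (year-1 flows into
    year-2+).
    """
    ages = list(params.ages)
    if not life_table.covers(ages[:-1]):
        raise ValueError(
            f"life table [{life_table.min_age}, {life_table.max_age}] does "
            f"not cover model ages [{ages[0]}, {ages[-1] - 1}]")
    mort = transitions.mortality

    nc, c1, c2, dead = 1.0, 0.0, 0.0, 0.0
    endo = {c: {"free": 1.0, "y1": 0.0, "y2p": 0.0}
            for c in ENDOCRINE_COMPLICATIONS}

    rows = []
    for age in ages:
        row = {"no_cardiac": nc, "cardiac_y1": c1, "cardiac_y2p": c2,
               "dead": dead, "alive": nc + c1 + c2}
        for c, s in endo.items():
            row[f"{c}_y1"] = s["y1"]
            row[f"{c}_y2p"] = s["y2p"]
        rows.append(row)
        if age == ages[-1]:
            break

        p_on = transitions.p_cardiac(age)
        d_nc = annual_death_prob(age, "no_cardiac", life_table, mort)
        d_c = annual_death_prob(age, "cardiac", life_table, mort)
        if p_on + d_nc * (1.0 - p_on) > 1.0 + 1e-12:
            raise ValueError(f"outgoing probabilities exceed 1 at age {age}")

        onset = nc * p_on
        new_c1 = onset * (1.0 - d_c)
        new_c2 = (c1 + c2) * (1.0 - d_c)
        new_nc = (nc - onset) * (1.0 - d_nc)
        dead += (nc - onset) * d_nc + (onset + c1 + c2) * d_c
        nc, c1, c2 = new_nc, new_c1, new_c2

        for c, s in endo.items():
            p = transitions.p_endocrine(c, age)
            new_y1 = s["free"] * p
            s["y2p"] += s["y1"]
            s["y1"] = new_y1
            s["free"] *= 1.0 - p

    frame = pd.DataFrame(rows, index=pd.Index(ages, name="age"))
    total = frame[list(STATE_COLUMNS)].sum(axis=1)
    if not np.allclose(total, 1.0, atol=1e-12):
        raise AssertionError("state occupancies do not sum to 1")
    return CohortTrace(frame)


def life_expectancy(trace: CohortTrace, as_attained_age: bool = False) -> float:
    """Undiscounted expected person-years lived within the horizon.

    The sum of the alive probability over all cycles.  With
    ``as_attained_age=True`` the result is reported on the age scale
    (entry age + expected years lived).
    """
    years = float(trace.frame["alive"].sum())
    if as_attained_age:
        return float(trace.ages[0]) + years
    return years


def microsimulate(params: CostParameters, life_table: LifeTable,
                  transitions: TransitionModel, n_individuals: int,
                  seed: int) -> CohortTrace:
    """Individual-level Monte Carlo mirror of :func:`run_cohort`.

    Simulates ``n_individuals`` independent patients under identical rules
    (onset first, then death) and returns a trace-shaped estimate whose
    frame additionally carries binomial standard-error columns
    (``se_<column>``).  Reproducible under a fixed seed.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    ages = list(params.ages)
    if not life_table.covers(ages[:-1]):
        raise ValueError("life table does not cover model ages")
    rng = np.random.default_rng(seed)
    mort = transitions.mortality
    n = n_individuals

    # 0 no_cardiac, 1 cardiac year 1, 2 cardiac year 2+, 3 dead
    state = np.zeros(n, dtype=np.int8)
    # per complication: 0 free, 1 onset this cycle, 2 established
    endo = {c: np.zeros(n, dtype=np.int8) for c in ENDOCRINE_COMPLICATIONS}

    rows = []
    for age in ages:
        alive_mask = state < 3
        n_alive = int(alive_mask.sum())
        row = {
            "no_cardiac": float((state == 0).mean()),
            "cardiac_y1": float((state == 1).mean()),
            "cardiac_y2p": float((state == 2).mean()),
            "dead": float((state == 3).mean()),
            "alive": float(alive_mask.mean()),
        }
        for c, flags in endo.items():
            if n_alive:
                row[f"{c}_y1"] = float((alive_mask & (flags == 1)).sum() / n_alive)
                row[f"{c}_y2p"] = float((alive_mask & (flags == 2)).sum() / n_alive)
            else:
                row[f"{c}_y1"] = 0.0
                row[f"{c}_y2p"] = 0.0
        for col in list(row):
            p = row[col]
            denom = n_alive if col.endswith(("_y1", "_y2p")) and col not in (
                "cardiac_y1", "cardiac_y2p") else n
            row[f"se_{col}"] = float(np.sqrt(p * (1 - p) / denom)) if denom else 0.0
        rows.append(row)
        if age == ages[-1]:
            break

        p_on = transitions.p_cardiac(age)
        d_nc = annual_death_prob(age, "no_cardiac", life_table, mort)
        d_c = annual_death_prob(age, "cardiac", life_table, mort)

        new_state = state.copy()
        nc_mask = state == 0
        onset = nc_mask & (rng.random(n) < p_on)
        new_state[onset] = 1
        new_state[state == 1] = 2  # tunnel advance
        u = rng.random(n)
        death_p = np.where(new_state == 0, d_nc, d_c)
        dies = (state < 3) & (u < death_p)
        new_state[dies] = 3
        new_state[state == 3] = 3
        state = new_state

        survivors = state < 3
        for c, flags in endo.items():
            p = transitions.p_endocrine(c, age)
            new_flags = flags.copy()
            new_flags[flags == 1] = 2
            hit = survivors & (flags == 0) & (rng.random(n) < p)
            new_flags[hit] = 1
            endo[c] = new_flags

    frame = pd.DataFrame(rows, index=pd.Index(ages, name="age"))
    return CohortTrace(frame)
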