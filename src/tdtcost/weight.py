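"""Piecewise age-band linear model of body weight.

Growth in transfusion-dependent thalassaemia is near normal in the first
decade, slowed through delayed puberty in the second, and essentially flat
from 19 onwards.  Weight is therefore modelled as independent simple linear
regressions on three age bands; predicted weight drives both the chelation
dose (mg/kg/day) and the transfusion volume (ml/kg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Default band edges: [1, 10], [11, 18], [19, 60].
DEFAULT_BAND_EDGES = (1, 11, 19, 61)


@dataclass
class AgeBand:
    """One fitted band: weight = intercept + slope * age on [lo, hi]."""

    lo: int
    hi: int
    intercept: float
    slope: float
    r_squared: float
    n: int = 0

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age

    def contains(self, age: float) -> bool:
        return self.lo <= age <= self.hi


@dataclass
class WeightModel:
    """Ordered, contiguous age bands covering the model horizon.

    Boundary convention: an age belongs to the band whose inclusive lower
    edge it matches (bands are ``[lo, hi]`` with ``hi = next lo - 1``), so
    assignment is unambiguous for integer ages.
    """

    bands: list[AgeBand]

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: b.lo)
        for a, b in zip(self.bands, self.bands[1:]):
            if b.lo != a.hi + 1:
                raise ValueError(
                    f"bands [{a.lo},{a.hi}] and [{b.lo},{b.hi}] are not "
                    "contiguous")

    @property
    def lo(self) -> int:
        return self.bands[0].lo

    @property
    def hi(self) -> int:
        return self.bands[-1].hi

    def band_for(self, age: float) -> AgeBand:
        for band in self.bands:
            if band.contains(age):
                return band
        raise ValueError(
            f"age {age} outside model coverage [{self.lo}, {self.hi}]")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"bands": [vars(b) for b in self.bands]}, indent=2)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, text: str) -> "WeightModel":
        raw = json.loads(text)
        return cls(bands=[AgeBand(**b) for b in raw["bands"]])


def predict_weight(age: float, model: WeightModel) -> float:
    """Predicted body weight (kg) at ``age`` from the containing band.

    Raises if the age is outside coverage or the containing band predicts a
    non-positive weight (a degenerate fit).
    """
    w = model.band_for(age).predict(age)
    if w <= 0:
        raise ValueError(
            f"degenerate weight fit: predicted {w:.3f} kg at age {age}")
    return w


def fit_weight_model(samples: Iterable[tuple[float, float]] | pd.DataFrame,
                     band_edges: Sequence[int] = DEFAULT_BAND_EDGES,
                     ) -> WeightModel:
    """Fit one OLS line per age band.

    ``samples`` is an iterable of ``(age, weight_kg)`` pairs or a DataFrame
    with ``age`` and ``weight`` columns.  ``band_edges`` gives the lower
    edges of each band plus one final exclusive upper edge; the default
    produces bands 1-10, 11-18 and 19-60.  Each band needs at least two
    distinct ages.
    """
    if isinstance(samples, pd.DataFrame):
        data = samples[["age", "weight"]].to_numpy(dtype=float)
    else:
        data = np.asarray(list(samples), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("samples must be (age, weight) pairs")
    ages, weights = data[:, 0], data[:, 1]

    if len(band_edges) < 2:
        raise ValueError("need at least two band edges")
    bands: list[AgeBand] = []
    for lo, nxt in zip(band_edges[:-1], band_edges[1:]):
        hi = nxt - 1
        mask = (ages >= lo) & (ages <= hi)
        band_ages = ages[mask]
        if np.unique(band_ages).size < 2:
            raise ValueError(
                f"band [{lo},{hi}]: need >= 2 samples with distinct ages, "
                f"got {np.unique(band_ages).size}")
        X = sm.add_constant(band_ages)
        fit = sm.OLS(weights[mask], X).fit()
        r2 = float(fit.rsquared)
        if not np.isfinite(r2):  # constant outcome: slope 0, no variance
            r2 = 0.0
        bands.append(AgeBand(lo=int(lo), hi=int(hi),
                             intercept=float(fit.params[0]),
                             slope=float(fit.params[1]),
                             r_squared=r2, n=int(mask.sum())))
    return WeightModel(bands=bands)


def constant_band(lo: int, hi: int, weight: float) -> AgeBand:
    """Flat band predicting a constant weight — the fallback for the adult
    band, where age explains almost none of the weight variance."""
    return AgeBand(lo=lo, hi=hi, intercept=weight, slope=0.0, r_squared=0.0)


def with_constant_adult_band(model: WeightModel,
                             samples: pd.DataFrame | None = None,
                             mean_weight: float | None = None) -> WeightModel:
    """Replace the last band's line with the band mean weight."""
    last = model.bands[-1]
    if mean_weight is None:
        if samples is None:
            raise ValueError("provide samples or mean_weight")
        mask = (samples["age"] >= last.lo) & (samples["age"] <= last.hi)
        mean_weight = float(samples.loc[mask, "weight"].mean())
    bands = model.bands[:-1] + [constant_band(last.lo, last.hi, mean_weight)]
    return WeightModel(bands=bands)
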