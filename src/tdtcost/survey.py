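"""Patient and family expenditure analysis of TDT health-utilization surveys.

A survey is a DataFrame with one row per respondent (see ``SURVEY_COLUMNS``)
carrying three monthly expenditure components, all in MYR: out-of-pocket
spending (``cOOP``), transportation (``cTransportation``) and productivity
losses of the patient or caregiver (``cProductivity``).  The pipeline
assembles per-respondent totals, the population mean monthly expenditure
(the quantity that scales into the lifetime TC3), regional summaries, and a
stepwise log-linear regression of expenditure determinants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

REGIONS = ("central", "northern", "southern", "east_coast", "east_malaysia")

SURVEY_COLUMNS = (
    "region", "age", "weight", "regimen", "income_category",
    "visits_per_month", "years_of_transfusion",
    "hours_in_hospital_per_month", "cOOP", "cTransportation",
    "cProductivity", "distance_km", "transport_cost_missing",
)

COMPONENT_COLUMNS = ("cOOP", "cTransportation", "cProductivity")

DEFAULT_COVARIATES = ("income_category", "visits_per_month", "dfo_regimen",
                      "years_of_transfusion")


def validate_survey(df: pd.DataFrame) -> None:
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns
               and c not in ("distance_km", "transport_cost_missing")]
    if missing:
        raise ValueError(f"survey missing columns: {missing}")
    bad_regions = set(df["region"]) - set(REGIONS)
    if bad_regions:
        raise ValueError(f"unknown regions: {sorted(bad_regions)}")
    for col in ("cOOP", "cProductivity"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{col} contains negative values")
    if (df["visits_per_month"] < 0).any():
        raise ValueError("visits_per_month contains negative values")


def impute_transport_cost(df: pd.DataFrame,
                          reimbursement_rate_per_km: float) -> pd.DataFrame:
    """Fill missing transportation costs from recorded travel distance.

    A respondent with no reported transport cost but a recorded return-trip
    distance is imputed ``distance_km * rate * visits_per_month``.  Records
    missing both are flagged (``transport_cost_missing``) and excluded from
    transport means downstream, but are not dropped.  Reported costs are
    never touched.
    """
    out = df.copy()
    if "distance_km" not in out.columns:
        out["distance_km"] = np.nan
    cost_missing = out["cTransportation"].isna()
    has_distance = out["distance_km"].notna()
    imput = cost_missing & has_distance
    out.loc[imput, "cTransportation"] = (
        out.loc[imput, "distance_km"] * reimbursement_rate_per_km
        * out.loc[imput, "visits_per_month"])
    out["transport_cost_missing"] = cost_missing & ~has_distance
    return out


def productivity_loss(hours_per_month: float, hourly_wage: float) -> float:
    """Monthly productivity loss: hours spent at the facility times the
    average hourly wage of the patient (adults) or accompanying caregiver."""
    if hours_per_month < 0 or hourly_wage < 0:
        raise ValueError("hours and wage must be >= 0")
    return hours_per_month * hourly_wage


def total_monthly_expenditure(df: pd.DataFrame) -> pd.Series:
    """Per-respondent monthly total; flagged missing transport counts as 0."""
    transport = df["cTransportation"].fillna(0.0)
    return df["cOOP"] + transport + df["cProductivity"]


@dataclass
class ExpenditureSummary:
    n: int
    mean_total_monthly: float
    sd_total_monthly: float
    sd_defined: bool
    component_shares_pct: dict[str, float]
    regional_annual: pd.DataFrame  # per region: annual total and components
    currency: str = "MYR"

    def to_frame(self) -> pd.DataFrame:
        return self.regional_annual


def mean_monthly_expenditure(df: pd.DataFrame) -> ExpenditureSummary:
    """Mean monthly patient/family expenditure and its decomposition.

    The mean is the simple average of per-respondent totals (invariant to
    record order).  Component shares are the share of each component in the
    grand total; transport sums skip records flagged as missing.  Regional
    summaries are annualized (x12).
    """
    if len(df) == 0:
        raise ValueError("empty survey")
    work = df.copy()
    if "transport_cost_missing" not in work.columns:
        work["transport_cost_missing"] = work["cTransportation"].isna()
    work["total"] = total_monthly_expenditure(work)

    n = len(work)
    mean_total = float(work["total"].mean())
    sd_defined = n > 1
    sd_total = float(work["total"].std(ddof=1)) if sd_defined else 0.0

    comp_sums = {
        "cOOP": float(work["cOOP"].sum()),
        "cTransportation": float(
            work.loc[~work["transport_cost_missing"], "cTransportation"].sum()),
        "cProductivity": float(work["cProductivity"].sum()),
    }
    grand = sum(comp_sums.values())
    shares = {k: (100.0 * v / grand if grand > 0 else 0.0)
              for k, v in comp_sums.items()}

    regional = (work.groupby("region")[["total", *COMPONENT_COLUMNS]]
                .mean(numeric_only=True) * 12.0)
    regional = regional.rename(
        columns={c: f"annual_{c}" for c in ("total", *COMPONENT_COLUMNS)})
    regional["n"] = work.groupby("region").size()

    return ExpenditureSummary(
        n=n, mean_total_monthly=mean_total, sd_total_monthly=sd_total,
        sd_defined=sd_defined, component_shares_pct=shares,
        regional_annual=regional)


@dataclass
class RegressionFit:
    """Stepwise OLS fit of log monthly expenditure."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n_used: int
    n_excluded: int
    retained: list[str] = field(default_factory=list)
    warning: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "t_values": self.t_values,
            "p_values": self.p_values,
            "r_squared": self.r_squared,
            "adjusted_r_squared": self.adjusted_r_squared,
            "f_statistic": self.f_statistic,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "retained": self.retained,
            "warning": self.warning,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def _with_dfo_indicator(df: pd.DataFrame) -> pd.DataFrame:
    if "dfo_regimen" in df.columns:
        return df
    out = df.copy()
    out["dfo_regimen"] = out["regimen"].astype(str).str.contains("DFO").astype(float)
    return out


def fit_expenditure_regression(df: pd.DataFrame,
                               candidate_covariates=DEFAULT_COVARIATES,
                               entry_p: float = 0.05,
                               removal_p: float = 0.10) -> RegressionFit:
    """Forward-stepwise OLS of ln(total monthly expenditure, MYR).

    Records with non-positive totals are excluded before the log transform
    (their count is reported).  At each step the candidate with the smallest
    p-value below ``entry_p`` enters; included covariates whose p-value
    drifts above ``removal_p`` are dropped again.  If nothing enters, an
    intercept-only fit is returned with a warning.
    """
    work = _with_dfo_indicator(df)
    total = total_monthly_expenditure(work)
    keep = total > 0
    n_excluded = int((~keep).sum())
    work = work.loc[keep]
    y = np.log(total.loc[keep].to_numpy(dtype=float))
    if len(work) < 10:
        raise ValueError(
            f"need >= 10 records with positive expenditure, got {len(work)}")

    X_all = work[list(candidate_covariates)].astype(float)

    def _fit(cols: list[str]):
        X = sm.add_constant(X_all[cols], has_constant="add")
        return sm.OLS(y, X).fit()

    included: list[str] = []
    while True:
        changed = False
        remaining = [c for c in candidate_covariates if c not in included]
        best_p, best_c = 1.0, None
        for c in remaining:
            p = _fit(included + [c]).pvalues[c]
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < entry_p:
            included.append(best_c)
            changed = True
        if included:
            fit = _fit(included)
            worst = fit.pvalues[included].idxmax()
            if fit.pvalues[worst] > removal_p:
                included.remove(worst)
                changed = True
        if not changed:
            break

    warning = None
    if not included:
        warning = ("no covariate passed the entry threshold; "
                   "intercept-only model returned")
        fit = sm.OLS(y, np.ones((len(y), 1))).fit()
        coefficients = {"const": float(fit.params[0])}
        return RegressionFit(
            coefficients=coefficients,
            standard_errors={"const": float(fit.bse[0])},
            t_values={"const": float(fit.tvalues[0])},
            p_values={"const": float(fit.pvalues[0])},
            r_squared=0.0, adjusted_r_squared=0.0, f_statistic=float("nan"),
            df_model=0, df_resid=int(fit.df_resid), n_used=len(y),
            n_excluded=n_excluded, retained=[], warning=warning)

    fit = _fit(included)
    return RegressionFit(
        coefficients={k: float(v) for k, v in fit.params.items()},
        standard_errors={k: float(v) for k, v in fit.bse.items()},
        t_values={k: float(v) for k, v in fit.tvalues.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n_used=len(y),
        n_excluded=n_excluded,
        retained=list(included),
        warning=warning)
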