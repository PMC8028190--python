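"""Published reference figures for the Malaysian TDT base case (2019 prices).

These are the printed results of the national cost-of-illness analysis this
package models: the lifetime cost decomposition from the societal
perspective, the unit-cost table in both currencies, and the survey headline
figures.  They serve as validation anchors — injected into the cost engine
to check its arithmetic, and cross-checked against the packaged base-case
config — never as substitutes for model output.
"""

from __future__ import annotations

MYR_PER_USD = 4.07

#: Lifetime cost decomposition per patient, USD, societal perspective.
LIFETIME_BREAKDOWN_USD = {
    "ict_drug": 345_251.68,
    "transfusion": 79_407.41,
    "monitoring": 49_984.71,
    "iol": 48_838.38,
    "dfo_admin": 37_725.72,
}
TC3_USD = 45_457.57
TC1_USD = 606_665.46

#: Same decomposition in MYR.
LIFETIME_BREAKDOWN_MYR = {
    "ict_drug": 1_405_174.32,
    "transfusion": 323_188.15,
    "monitoring": 203_437.75,
    "iol": 198_772.20,
    "dfo_admin": 153_543.67,
}
TC3_MYR = 185_012.31
TC1_MYR = 2_469_128.41

#: Published component proportions of TC1, percent.
PROPORTIONS_PCT = {
    "ict_drug": 56.9,
    "transfusion": 13.1,
    "monitoring": 8.2,
    "iol": 8.1,
    "dfo_admin": 6.2,
    "tc3": 7.5,
}

#: Unit-cost rows printed in both currencies: label -> (USD, MYR).
#: USD figures are rounded to 2 d.p.; MYR is the native column.
UNIT_COST_ROWS_USD_MYR = {
    "DFO per gram": (10.81, 44.00),
    "DFX per gram": (36.60, 149.00),
    "DFP per gram": (0.49, 2.00),
    "DFO administration, monthly": (96.80, 393.98),
    "monitoring <10 y, monthly": (55.39, 225.42),
    "monitoring >=10 y, monthly": (106.47, 433.33),
    "blood per ml": (0.16, 0.67),
    "crossmatch per transfusion": (2.71, 11.00),
    "transfusion equipment": (1.14, 4.64),
    "cardiac year 1": (536.36, 2183.00),
    "diabetes year 1": (323.10, 1315.00),
    "hypogonadism year 1": (175.40, 713.88),
    "hypogonadism year 2+": (709.69, 2888.42),
    "hypoparathyroidism year 1": (128.72, 523.88),
    "hypoparathyroidism year 2+": (580.41, 2362.27),
    "hypothyroidism year 1": (40.43, 164.57),
    "hypothyroidism year 2+": (43.59, 177.40),
}

#: Chelation compliance, percent, from the meta-analysis feeding the model.
COMPLIANCE_PCT = {"DFX": 98.1, "DFO": 77.3, "DFP": 90.3}

#: Survey headline: mean monthly patient/family expenditure, USD (SD 283.02).
MEAN_MONTHLY_FAMILY_COST_USD = 65.56

#: Expenditure regression (outcome: ln monthly total, MYR).
EXPENDITURE_MODEL_COEFFICIENTS = {
    "const": 6.654,
    "income_category": 0.272,
    "visits_per_month": 0.294,
    "dfo_regimen": 0.262,
    "years_of_transfusion": 0.009,
}
EXPENDITURE_MODEL_R2 = 0.492

#: Model life expectancy of the TDT cohort, years of age attained.
LIFE_EXPECTANCY_YEARS = 57.7


def currency_cross_check(rate_myr_per_usd: float = MYR_PER_USD,
                         rel_tol: float = 0.005,
                         printed_decimals: int = 2) -> dict[str, dict]:
    """Check that the USD and MYR unit-cost columns agree at the given rate.

    A row passes if the relative difference between the printed USD figure
    and MYR/rate is at most ``rel_tol``, or the absolute difference is within
    half a unit of the last printed decimal place (print rounding).
    Returns per-row diagnostics including a boolean ``ok``.
    """
    half_ulp = 0.5 * 10.0 ** (-printed_decimals)
    out: dict[str, dict] = {}
    for label, (usd, myr) in UNIT_COST_ROWS_USD_MYR.items():
        implied = myr / rate_myr_per_usd
        abs_err = abs(implied - usd)
        rel_err = abs_err / implied if implied else 0.0
        out[label] = {
            "printed_usd": usd,
            "implied_usd": implied,
            "rel_err": rel_err,
            "abs_err": abs_err,
            "ok": rel_err <= rel_tol or abs_err <= half_ulp,
        }
    return out
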