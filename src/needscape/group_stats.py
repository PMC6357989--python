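"""Univariate and multivariate group comparisons on survey records.

Roma vs non-Roma (and rural vs suburban+urban) comparisons of binary
household indicators, each reported as an odds ratio with a Woolf 95%
confidence interval and a pooled-variance two-sample t statistic on the
0/1 indicator.  Odds ratios are oriented toward the ADVERSE state: the
odds of lacking a toilet, suffering diarrhea, inhabiting insecure
housing, ... in group 1 over group 2, so OR > 1 always means group 1 is
worse off.  Counts can also be reconstructed from printed (percentage,
group size) pairs, which lets published tables be re-analysed without
the underlying microdata.

Linear probability models MOD1-MOD4 regress the Roma indicator on
demographic, infrastructure, and aggregate-score predictors by ordinary
least squares with classical standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .survey import SurveyRecord, compute_scores, safe_water

Z975 = 1.959963984540054  # two-sided 95% normal quantile


class DomainError(ValueError):
    """Inputs outside the statistic's domain (e.g. an empty group)."""


@dataclass(slots=True, frozen=True)
class ContingencyTable2x2:
    """a = group-1 adverse, b = group-1 non-adverse, c/d = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("negative cell count")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise DomainError("empty group")


@dataclass(slots=True)
class ComparisonResult:
    """One row of a univariate comparison table."""

    variable: str
    p1_pct: float
    p2_pct: float
    t_stat: float
    t_df: int
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n1: int = 0
    n2: int = 0
    zero_cell_corrected: bool = False
    non_estimable: bool = False
    caveat: str = ""


@dataclass(slots=True)
class LinearModelResult:
    """OLS fit of the Roma indicator on one predictor set (MOD1-MOD4)."""

    model_id: str
    params: pd.Series
    p_values: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    nobs: int
    rsquared: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "p_value": self.p_values,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def summary(self) -> str:
        lines = [f"{self.model_id}: linear probability model, n={self.nobs}, "
                 f"R^2={self.rsquared:.3f}"]
        lines.append(self.table().to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def reconstruct_count(pct: float, n: int) -> int:
    """Invert a printed percentage to the underlying count.

    Nearest integer to ``pct/100 * n``, ties rounded away from zero.
    """
    if not 0.0 <= pct <= 100.0:
        raise DomainError(f"percentage {pct} outside [0, 100]")
    if n < 1:
        raise DomainError("group size must be >= 1")
    return int(math.floor(pct / 100.0 * n + 0.5))


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, float, float, bool]:
    """Odds ratio with Woolf (log-normal) 95% CI.

    Returns ``(OR, ci_low, ci_high, corrected)`` where *corrected* marks
    the Haldane-Anscombe +0.5 continuity correction applied when any
    cell is zero.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = False
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - Z975 * se)
    hi = math.exp(math.log(or_) + Z975 * se)
    return or_, lo, hi, corrected


def pooled_t_binary(
    p1_count: int, n1: int, p2_count: int, n2: int
) -> tuple[float, int, float]:
    """Two-sample pooled-variance t test on a 0/1 indicator.

    Group variances are the Bessel-corrected variances of the indicator,
    ``n_i p_i (1 - p_i) / (n_i - 1)``; df = n1 + n2 - 2; the sign follows
    p1 - p2 and the p-value is two-sided.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("each group needs n >= 2")
    if p1_count > n1 or p2_count > n2:
        raise DomainError("count exceeds group size")
    p1, p2 = p1_count / n1, p2_count / n2
    df = n1 + n2 - 2
    ss1 = n1 * p1 * (1 - p1)  # = (n1-1) * bessel variance
    ss2 = n2 * p2 * (1 - p2)
    sp2 = (ss1 + ss2) / df
    denom = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if denom == 0.0:
        t = 0.0
    else:
        t = (p1 - p2) / denom
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def _compare_counts(
    variable: str, a: int, n1: int, c: int, n2: int, caveat: str = ""
) -> ComparisonResult:
    """Build one table row from adverse counts in each group."""
    table = ContingencyTable2x2(a, n1 - a, c, n2 - c)
    non_estimable = (a in (0, n1)) and (c in (0, n2))
    or_, lo, hi, corrected = odds_ratio(table)
    t, df, p = pooled_t_binary(a, n1, c, n2)
    return ComparisonResult(
        variable=variable,
        p1_pct=100.0 * a / n1,
        p2_pct=100.0 * c / n2,
        t_stat=t,
        t_df=df,
        p_value=p,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        n1=n1,
        n2=n2,
        zero_cell_corrected=corrected,
        non_estimable=non_estimable,
        caveat=caveat,
    )


# adverse-state predicates for the ethnicity comparison table
ETHNICITY_VARIABLES: list[tuple[str, Callable[[SurveyRecord], bool], str]] = [
    ("indoor_toilet_lacking", lambda r: not r.indoor_toilet, ""),
    ("indoor_bathroom_lacking", lambda r: not r.indoor_bathroom, ""),
    ("improved_water_lacking", lambda r: not r.piped_tap, ""),
    ("insecure_housing", lambda r: compute_scores(r).insecure_housing_flag, ""),
    ("safe_water_lacking", lambda r: not safe_water(r), ""),
    ("diarrhea_mod_severe", lambda r: r.diarrhea_mod_severe, ""),
    (
        "not_immunized",
        lambda r: not r.immunized_any,
        "adverse-orientation OR; published values for this item are "
        "internally inconsistent",
    ),
    ("uninsured", lambda r: not r.insured, ""),
    ("no_pcp_access", lambda r: not r.pcp_access, ""),
    ("electricity_lacking", lambda r: not r.electricity, ""),
    ("gas_lacking", lambda r: not r.gas, ""),
    ("severe_poverty", lambda r: not r.spends_over_2usd, ""),
]

GEOGRAPHY_VARIABLES: list[tuple[str, Callable[[SurveyRecord], bool], str]] = [
    ("severe_poverty", lambda r: not r.spends_over_2usd, ""),
    (
        "water_time_over_15min",
        lambda r: r.time_to_water >= 2,
        "time-to-water binarized at >15 minutes",
    ),
]


def univariate_table(
    records: Sequence[SurveyRecord], grouping: str = "ethnicity"
) -> list[ComparisonResult]:
    """Adverse-oriented comparison table over all indicator variables.

    ``grouping='ethnicity'``: group 1 = Roma, group 2 = non-Roma.
    ``grouping='geography'``: group 1 = rural, group 2 = suburban and
    urban communities pooled.
    """
    if grouping == "ethnicity":
        in_g1 = lambda r: r.ethnicity == "roma"
        variables = ETHNICITY_VARIABLES
    elif grouping == "geography":
        in_g1 = lambda r: r.geography_class == "rural"
        variables = GEOGRAPHY_VARIABLES
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    g1 = [r for r in records if in_g1(r)]
    g2 = [r for r in records if not in_g1(r)]
    if not g1 or not g2:
        raise DomainError("both groups must be non-empty")
    out = []
    for name, adverse, caveat in variables:
        a = sum(adverse(r) for r in g1)
        c = sum(adverse(r) for r in g2)
        out.append(_compare_counts(name, a, len(g1), c, len(g2), caveat))
    return out


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy CSV-ready layout of a univariate table."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "group1_pct": [r.p1_pct for r in results],
            "group2_pct": [r.p2_pct for r in results],
            "t": [r.t_stat for r in results],
            "df": [r.t_df for r in results],
            "p_value": [r.p_value for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "zero_cell_corrected": [r.zero_cell_corrected for r in results],
            "caveat": [r.caveat for r in results],
        }
    )


MODEL_PREDICTORS: dict[str, list[str]] = {
    "MOD1": ["property_documents", "education_grade", "household_size", "unemployed"],
    "MOD2": ["piped_tap", "diarrhea_mod_severe", "electricity_lacking", "insecure_housing"],
    "MOD3": ["wash_score", "healthcare_score", "poverty_score"],
    "MOD4": ["wash_safe_score", "healthcare_score", "poverty_score"],
}


def _design_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        b = compute_scores(r)
        rows.append(
            {
                "roma": int(r.ethnicity == "roma"),
                "property_documents": int(r.property_documents),
                "education_grade": r.education_grade,
                "household_size": r.household_size,
                "unemployed": int(r.employment == "unemployed_or_day_labour"),
                "piped_tap": int(r.piped_tap),
                "diarrhea_mod_severe": int(r.diarrhea_mod_severe),
                "electricity_lacking": int(not r.electricity),
                "insecure_housing": int(b.insecure_housing_flag),
                "wash_score": b.wash_score,
                "wash_safe_score": b.wash_safe_score,
                "healthcare_score": b.healthcare_score,
                "poverty_score": b.poverty_score,
            }
        )
    return pd.DataFrame(rows)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on the others (including the constant)."""
    mat = X.to_numpy(dtype=float)
    dependent = []
    for j, col in enumerate(X.columns):
        if col == "const":
            continue
        others = np.delete(mat, j, axis=1)
        resid = mat[:, j] - others @ np.linalg.lstsq(others, mat[:, j], rcond=None)[0]
        scale = np.linalg.norm(mat[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            dependent.append(col)
    return dependent


def fit_linear_models(
    records: Sequence[SurveyRecord],
    models: Sequence[str] = ("MOD1", "MOD2", "MOD3", "MOD4"),
) -> list[LinearModelResult]:
    """Fit the linear probability models of the Roma indicator.

    Each model is an OLS regression of the 0/1 Roma indicator on its
    predictor set with an intercept and classical standard errors.
    """
    frame = _design_frame(records)
    for eth in (0, 1):
        if (frame["roma"] == eth).sum() < 2:
            raise DomainError("need >= 2 records per ethnicity")
    results = []
    for model_id in models:
        predictors = MODEL_PREDICTORS[model_id]
        X = sm.add_constant(frame[predictors].astype(float), has_constant="add")
        bad = _collinear_columns(X)
        if bad:
            raise DomainError(
                f"{model_id}: collinear design, dependent column(s): {', '.join(bad)}"
            )
        fit = sm.OLS(frame["roma"].astype(float), X).fit()
        ci = fit.conf_int(alpha=0.05)
        results.append(
            LinearModelResult(
                model_id=model_id,
                params=fit.params,
                p_values=fit.pvalues,
                ci_low=ci[0],
                ci_high=ci[1],
                nobs=int(fit.nobs),
                rsquared=float(fit.rsquared) if frame["roma"].nunique() > 1 else 0.0,
            )
        )
    return results


_EDUCATION_BANDS = [
    (8, "secondary (8th grade)"),
    (10, "required (10th grade)"),
    (12, "high school (12th grade)"),
    (16, "university / college"),
]


def education_band(grade: int) -> str:
    for top, label in _EDUCATION_BANDS:
        if grade <= top:
            return label
    return _EDUCATION_BANDS[-1][1]


def summarize_demographics(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Per community x ethnicity demographic summary, plus overall rows.

    Columns: n, pct_male, mean_age, mean_household_size, modal education
    band, pct_partnership, pct_full_time, pct_literate.
    """
    if not records:
        raise DomainError("no records")
    df = pd.DataFrame(
        {
            "community_id": [r.community_id for r in records],
            "ethnicity": [r.ethnicity for r in records],
            "male": [r.respondent_sex == "M" for r in records],
            "age": [r.respondent_age for r in records],
            "household_size": [r.household_size for r in records],
            "education_band": [education_band(r.education_grade) for r in records],
            "partnership": [r.marital == "partnership" for r in records],
            "full_time": [r.employment == "full_time" for r in records],
            "literate": [r.literate for r in records],
        }
    )

    def summarize(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "pct_male": 100.0 * g["male"].mean(),
                "mean_age": g["age"].mean(),
                "mean_household_size": g["household_size"].mean(),
                "modal_education": g["education_band"].mode().iloc[0],
                "pct_partnership": 100.0 * g["partnership"].mean(),
                "pct_full_time": 100.0 * g["full_time"].mean(),
                "pct_literate": 100.0 * g["literate"].mean(),
            }
        )

    parts = []
    by = df.groupby(["community_id", "ethnicity"], sort=True)
    for (comm, eth), g in by:
        parts.append(summarize(g).rename((comm, eth)))
    for eth, g in df.groupby("ethnicity", sort=True):
        parts.append(summarize(g).rename(("overall", eth)))
    parts.append(summarize(df).rename(("overall", "all")))
    out = pd.DataFrame(parts)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["community_id", "ethnicity"])
    return out
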