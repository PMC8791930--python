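"""Percentile grouping, Cox proportional-hazards fits and Kaplan-Meier.

The exposure of interest is a two-level label: "high-expression,
small-nuclei" when gene expression exceeds the cohort 75th percentile
AND mean nuclei Size Area is below the 25th percentile (both strict),
otherwise "low-expression, large-nuclei". Cox models use the Efron
partial likelihood (ties) with a likelihood-ratio test: 1 df for the
univariate group model, 5 df when ER status and age-quartile contrasts
are added. Quantiles use the linear-interpolation (type-7) definition
throughout, since boundary membership depends on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

__all__ = [
    "CoxFit", "assign_groups", "dichotomize_age", "cox_fit",
    "kaplan_meier_logrank",
]

logger = logging.getLogger(__name__)

HIGH_SMALL = "high-expr-small-nuclei"
LOW_LARGE = "low-expr-large-nuclei"


@dataclass
class CoxFit:
    hazard_ratio: dict  # per coefficient
    ci95: dict  # per coefficient, (low, high)
    coef: dict
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    converged: bool
    message: str = ""


def assign_groups(expression: np.ndarray, nuclei_size: np.ndarray) -> np.ndarray:
    """Two-level grouping by cohort percentiles (strict inequalities).

    ``HIGH_SMALL`` when expression > its 75th percentile and nuclei size
    < its 25th percentile; everything else is ``LOW_LARGE``.
    """
    expr = np.asarray(expression, float)
    size = np.asarray(nuclei_size, float)
    if expr.shape != size.shape:
        raise ValueError("expression and nuclei_size must align")
    if len(expr) < 8:
        raise ValueError("need at least 8 subjects")
    if np.ptp(expr) == 0 or np.ptp(size) == 0:
        logger.warning("constant input vector: all subjects fall in the "
                       "'otherwise' group")
    e75 = np.quantile(expr, 0.75)  # type-7 linear interpolation
    s25 = np.quantile(size, 0.25)
    high_small = (expr > e75) & (size < s25)
    return np.where(high_small, HIGH_SMALL, LOW_LARGE)


def dichotomize_age(ages: np.ndarray) -> np.ndarray:
    """Quartile labels Q1-Q4 with ties assigned to the lower bin."""
    ages = np.asarray(ages, float)
    if len(np.unique(ages)) < 4:
        raise ValueError("fewer than 4 distinct ages: use fewer bins")
    edges = np.quantile(ages, [0.25, 0.5, 0.75])
    idx = np.searchsorted(edges, ages, side="left")
    return np.array([f"Q{i + 1}" for i in idx])


def _prepare(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    df = table.copy()
    cols = {}
    if "group" in covariates:
        g = df["group"]
        if g.dtype == object or str(g.dtype).startswith("category"):
            cols["group_low_large"] = (g == LOW_LARGE).astype(float)
        else:
            cols["group_low_large"] = g.astype(float)
    if "er" in covariates:
        er = df["er_status"].astype(str)
        keep = er.isin(["positive", "negative"])
        dropped = int((~keep).sum())
        if dropped:
            logger.info("excluding %d subjects with indeterminate ER status",
                        dropped)
        df = df[keep]
        cols = {k: v[keep] for k, v in cols.items()}
        cols["er_positive"] = (df["er_status"].astype(str) == "positive").astype(float)
    if "age" in covariates:
        q = dichotomize_age(df["age"].to_numpy(float))
        for lvl in ("Q2", "Q3", "Q4"):  # Q1 reference
            cols[f"age_{lvl}"] = (q == lvl).astype(float)
    out = pd.DataFrame(cols, index=df.index)
    out["time"] = df["time"].to_numpy(float)
    out["event"] = df["event"].to_numpy(int)
    return out


def cox_fit(table: pd.DataFrame, covariates: list[str] | None = None) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with a likelihood-ratio
    test against the null (no-covariate) partial likelihood.

    ``covariates`` selects from {"group", "er", "age"}; the default is
    the univariate group model (1 df). Adding ER and age quartiles gives
    the 5-df model (group + ER + 3 age contrasts). Subjects with
    indeterminate ER status are excluded from ER-adjusted fits.
    """
    covariates = covariates or ["group"]
    df = _prepare(table, covariates)
    if int(df["event"].sum()) == 0:
        raise ValueError("no events in the survival table")
    if int(df["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone likelihood / separation
        return CoxFit({}, {}, {}, np.nan, len(df.columns) - 2, np.nan,
                      converged=False, message=str(exc))
    lrt = cph.log_likelihood_ratio_test()
    hr = np.exp(cph.params_)
    ci = np.exp(cph.confidence_intervals_)
    return CoxFit(
        hazard_ratio=hr.to_dict(),
        ci95={k: (float(ci.loc[k].iloc[0]), float(ci.loc[k].iloc[1]))
              for k in cph.params_.index},
        coef=cph.params_.to_dict(),
        lrt_stat=float(lrt.test_statistic),
        lrt_df=int(lrt.degrees_freedom),
        lrt_p=float(lrt.p_value),
        converged=True,
    )


def kaplan_meier_logrank(table: pd.DataFrame) -> dict:
    """Product-limit curves per group with medians and the log-rank test.

    Median survival is the first time the survival function drops to
    0.5 or below (NaN when never reached). Requires at least one event
    overall; the two-group log-rank statistic is chi-square with 1 df.
    """
    if int(table["event"].sum()) == 0:
        raise ValueError("no events: log-rank test undefined")
    groups = pd.unique(table["group"])
    curves = {}
    medians = {}
    for g in groups:
        sub = table[table["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        km.fit(sub["time"], event_observed=sub["event"], label=str(g))
        sf = km.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.iloc[:, 0].to_numpy()})
        medians[g] = float(km.median_survival_time_)
    if len(groups) == 2:
        a = table[table["group"] == groups[0]]
        b = table[table["group"] == groups[1]]
        res = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                           event_observed_B=b["event"])
        chi2, p = float(res.test_statistic), float(res.p_value)
    else:
        res = multivariate_logrank_test(table["time"], table["group"],
                                        table["event"])
        chi2 = float(res.test_statistic)
        p = float(stats.chi2.sf(chi2, df=len(groups) - 1))
    return {"curves": curves, "medians": medians, "logrank_stat": chi2,
            "logrank_p": p}
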