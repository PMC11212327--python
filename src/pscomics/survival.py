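"""Survival association of molecular subtypes and mutations.

Kaplan-Meier product-limit curves, the two-group log-rank test, and
Cox proportional-hazards models (Efron tie handling) with Wald
confidence intervals.  Estimation is delegated to ``lifelines``; this
module shapes the pipeline's records in and tidy summaries out, and
converts near-separation failures into diagnostics instead of crashes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

log = logging.getLogger(__name__)

#: Ordinal encoding of pathological stage for covariate adjustment.
STAGE_ORDINAL = {"IA": 1, "IB": 2, "IIA": 3, "IIB": 4, "IIIA": 5,
                 "IIIB": 6, "IV": 7}


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["time"] <= 0).any():
        raise ValueError("all survival times must be > 0")
    if not records["event"].isin((0, 1)).all():
        raise ValueError("event must be 0/1")
    return records


def km_estimate(records: pd.DataFrame
                ) -> Tuple[pd.DataFrame, Optional[float]]:
    """Product-limit survival estimate.

    Returns (curve, median): the curve has columns time, survival,
    at_risk and censored marks; the median is ``None`` while the curve
    stays above 0.5.
    """
    records = _check_records(records)
    km = KaplanMeierFitter()
    km.fit(records["time"], records["event"])
    curve = km.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    tbl = km.event_table
    curve = curve.merge(
        tbl[["at_risk", "censored"]].reset_index().rename(
            columns={"event_at": "time"}),
        on="time", how="left")
    median = km.median_survival_time_
    return curve, (None if np.isinf(median) else float(median))


def logrank_test(records: pd.DataFrame, group_col: str = "group"
                 ) -> Tuple[float, float]:
    """Two-group log-rank test: observed-minus-expected chi-squared
    with hypergeometric variance at each distinct event time; p from
    chi-squared(1)."""
    records = _check_records(records)
    groups = records[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    a = records[records[group_col] == groups[0]]
    b = records[records[group_col] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    if records["event"].sum() == 0:
        raise ValueError("no events observed")
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: hr, ci_lower, ci_upper, p, coef, se
    converged: bool
    diagnostic: str = ""

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(records: pd.DataFrame, covariates: Sequence[str]
            ) -> CoxResult:
    """Cox proportional-hazards fit by partial-likelihood Newton
    iterations with Efron tie handling.

    Returns hazard ratios with 95% Wald intervals
    (``exp(beta +/- 1.96 SE)``) and p-values.  Monotone likelihood
    (complete separation) is reported as a non-converged result with a
    diagnostic rather than raised.
    """
    records = _check_records(records)
    if records["event"].sum() == 0:
        raise ValueError("no events observed")
    df = records[["time", "event", *covariates]].copy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        return CoxResult(summary=pd.DataFrame(), converged=False,
                         diagnostic=f"monotone likelihood / separation: {exc}")
    s = cph.summary
    with np.errstate(over="ignore"):
        out = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "ci_lower": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        "ci_upper": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        "p": s["p"],
    })
    # flag near-separation: absurd standard errors mean the Wald
    # interval is meaningless even though the optimizer stopped
    huge_se = (out["se"] > 10).any()
    return CoxResult(summary=out, converged=not huge_se,
                     diagnostic="near-separation: SE > 10" if huge_se else "")


def survival_summary(records: pd.DataFrame, group_col: str = "group",
                     adjust_for: Sequence[str] = ()) -> pd.DataFrame:
    """Univariate (and optionally covariate-adjusted) association of a
    binary group with survival: log-rank p plus Cox HR per model."""
    records = _check_records(records).copy()
    groups = sorted(records[group_col].unique())
    if len(groups) != 2:
        raise ValueError("binary group required")
    records["_group01"] = (records[group_col] == groups[1]).astype(int)
    chi2, p_lr = logrank_test(records, group_col)
    rows = [{"model": "logrank", "term": group_col, "statistic": chi2,
             "p": p_lr, "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan}]
    for name, covs in (("cox_univariate", ["_group01"]),
                       ("cox_adjusted", ["_group01", *adjust_for])):
        if name == "cox_adjusted" and not adjust_for:
            continue
        res = cox_fit(records, covs)
        if res.converged or not res.summary.empty:
            r = res.summary.loc["_group01"]
            rows.append({"model": name, "term": group_col,
                         "statistic": np.nan, "p": r["p"], "hr": r["hr"],
                         "ci_lower": r["ci_lower"], "ci_upper": r["ci_upper"],
                         "diagnostic": res.diagnostic})
        else:
            rows.append({"model": name, "term": group_col,
                         "statistic": np.nan, "p": np.nan, "hr": np.nan,
                         "ci_lower": np.nan, "ci_upper": np.nan,
                         "diagnostic": res.diagnostic})
    return pd.DataFrame(rows)
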