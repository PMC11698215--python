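"""Sensitivity analyses: E-values, a negative-control outcome, metabolic
testing rates, and the young never-exposed subgroup.

The negative-control analysis reruns the full targeted estimation machinery
with time to first influenza vaccination as the absorbing outcome; because
vaccination should be unaffected by which antipsychotic is taken, a nonzero
vaccination-free RMST difference signals residual confounding or differential
healthcare contact.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    ARIPIPRAZOLE,
    DRUGS,
    EstimatorConfig,
    OLANZAPINE,
    SuperLearnerConfig,
)
from .tmle import ContrastEstimate, RMSTEstimate, estimate_all


@dataclass(frozen=True)
class EValueResult:
    rr: float
    e_point: float
    ci_limit: Optional[float]   # CI limit closest to the null, if supplied
    e_ci: Optional[float]


@dataclass(frozen=True)
class TestingRateResult:
    """Proportion of observed person-months with a metabolic test, per drug."""

    rates: dict[str, float]


@dataclass
class NegativeControlResult:
    rmst: RMSTEstimate          # vaccination-free months, olz minus ari


def _e_from_rr(rr: float) -> float:
    rr_star = rr if rr >= 1.0 else 1.0 / rr
    return rr_star + np.sqrt(rr_star * (rr_star - 1.0))


def e_value(rr: float, ci_lo: Optional[float] = None,
            ci_hi: Optional[float] = None) -> EValueResult:
    """Minimum confounder association (risk-ratio scale) explaining `rr` away.

    Protective ratios are inverted before applying E = RR* + sqrt(RR*(RR*-1)).
    The CI E-value uses the limit closest to the null and is 1 when the
    interval contains 1.
    """
    if rr <= 0:
        raise ValueError("risk ratio must be positive")
    if (ci_lo is None) != (ci_hi is None):
        raise ValueError("supply both CI limits or neither")
    e_point = float(_e_from_rr(rr))
    ci_limit = e_ci = None
    if ci_lo is not None:
        if ci_lo <= 0 or ci_lo > rr or ci_hi < rr:
            raise ValueError("CI must be positive and contain the point estimate")
        if ci_lo <= 1.0 <= ci_hi:
            ci_limit, e_ci = 1.0, 1.0
        else:
            ci_limit = float(ci_hi) if rr < 1.0 else float(ci_lo)
            e_ci = float(_e_from_rr(ci_limit))
    return EValueResult(rr=float(rr), e_point=e_point, ci_limit=ci_limit,
                       e_ci=e_ci)


def evalues_for_contrasts(contrasts: list[ContrastEstimate]) -> pd.DataFrame:
    """Monthly E-values for a sequence of risk-ratio contrasts."""
    rows = []
    for c in contrasts:
        if c.rr is None:
            continue
        if c.rr_lo is not None:
            ev = e_value(c.rr, c.rr_lo, c.rr_hi)
        else:
            ev = e_value(c.rr)
        rows.append({"month": c.month, "rr": c.rr, "e_point": ev.e_point,
                     "e_ci": ev.e_ci})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# negative-control outcome


def vaccination_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Recast the panel with first influenza vaccination as the outcome.

    Person-months stop at the first vaccination; a diabetes event without a
    same-month vaccination ends follow-up as censoring for this outcome.
    """
    df = panel.sort_values(["person_id", "month"], kind="stable").copy()
    first_vacc = df[df["vacc"] == 1].groupby("person_id")["month"].min()
    vm = df["person_id"].map(first_vacc).fillna(np.inf)
    keep = df["month"] <= vm
    df, vm = df[keep].copy(), vm[keep]
    orig_y = df["Y"].copy()
    vacc_now = (df["month"] == vm) & (df["C"] == 0)
    df["Y"] = np.where(df["C"] == 1, np.nan, vacc_now.astype(float))
    # a diabetes event month without vaccination ends observation: censor it
    diab_end = (df["C"] == 0) & (~vacc_now) & (orig_y == 1.0)
    df.loc[diab_end, "C"] = 1
    df.loc[diab_end, "cause"] = "switch"  # label unused downstream
    df.loc[diab_end, "Y"] = np.nan
    return df


def negative_control_analysis(
    panel: pd.DataFrame,
    sl_config: SuperLearnerConfig | None = None,
    est_config: EstimatorConfig | None = None,
) -> NegativeControlResult:
    """Vaccination-free RMST difference under the monotherapy regime."""
    if not (panel["vacc"] == 1).any():
        raise ValueError("no vaccination events present in the panel")
    vp = vaccination_panel(panel)
    res = estimate_all(vp, sl_config, est_config)
    return NegativeControlResult(rmst=res["rmst"])


# ---------------------------------------------------------------------------
# testing rates and the subgroup


def testing_rates(panel: pd.DataFrame) -> TestingRateResult:
    """Per drug group, the share of observed person-months with a metabolic test."""
    rates: dict[str, float] = {}
    for drug in DRUGS:
        sub = panel[panel["drug"] == drug]
        if len(sub) == 0:
            raise ValueError(f"no observed person-months for {drug}")
        rates[drug] = float(sub["tested"].mean())
    return TestingRateResult(rates=rates)


def subgroup_filter(
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    age_min: int = 18,
    age_max: int = 45,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict to ages `age_min`..`age_max` with no previous index-drug exposure."""
    keep_panel = panel[(panel["age"] >= age_min) & (panel["age"] <= age_max)
                       & (panel["pre_rx_days"] == 0)]
    if len(cohort):
        elig = cohort[cohort.get("eligible", 1) == 1]
        keep_ids = set(keep_panel["person_id"])
        keep_cohort = elig[elig["person_id"].isin(keep_ids)]
    else:
        keep_cohort = cohort
    return keep_cohort.reset_index(drop=True), keep_panel.reset_index(drop=True)
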