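"""New-user cohort construction from raw claims.

Implements the active-comparator new-user design: index-episode
identification under the relatively-new-user supply rule, eligibility
filtering with single-reason attrition accounting, outcome ascertainment for
incident type 2 diabetes, the seven-cause censoring hierarchy, and the
monthly continuous-monotherapy exposure panel.

Months are consecutive 30-day windows anchored at the index fill date; all
day windows are half-open ``[start, end)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import (
    ARIPIPRAZOLE,
    CENSORING_CAUSES,
    CohortConfig,
    ELIGIBILITY_REASONS,
    MONOTHERAPY_END_CAUSES,
    OLANZAPINE,
)
from .simulate import PANEL_COLUMNS, RawClaimsBundle

INDEX_CLASSES = {"index_aripiprazole": ARIPIPRAZOLE, "index_olanzapine": OLANZAPINE}
ANTIPSYCHOTIC_CLASSES = set(INDEX_CLASSES) | {"other_antipsychotic"}

OUTCOME_RULES = ("inpatient_primary", "two_outpatient_12mo",
                 "outpatient_plus_oral_antidiabetic", "none")


class DataError(ValueError):
    """Raised on structurally invalid claims input."""


@dataclass(frozen=True)
class IndexEpisode:
    person_id: str
    index_day: int
    drug: str                      # aripiprazole | olanzapine
    pre_period_days_supplied: int  # index-drug supply in the 180 days before


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reason: str  # one of ELIGIBILITY_REASONS; "none" iff eligible

    def __post_init__(self) -> None:
        if self.reason not in ELIGIBILITY_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")
        if self.eligible != (self.reason == "none"):
            raise ValueError("reason must be 'none' exactly when eligible")


@dataclass(frozen=True)
class CensoringOutcome:
    month: int
    cause: str

    def __post_init__(self) -> None:
        if self.cause not in CENSORING_CAUSES:
            raise ValueError(f"unknown censoring cause {self.cause!r}")


@dataclass(frozen=True)
class OutcomeResult:
    event_month: Optional[int]
    rule: str

    def __post_init__(self) -> None:
        if self.rule not in OUTCOME_RULES:
            raise ValueError(f"unknown outcome rule {self.rule!r}")
        if (self.event_month is None) != (self.rule == "none"):
            raise ValueError("rule must be 'none' exactly when no event")


@dataclass(frozen=True)
class CovariateBalance:
    variable: str
    mean_aripiprazole: float
    mean_olanzapine: float
    smd: float          # (olanzapine - aripiprazole) / sd(aripiprazole)
    unbalanced: bool    # |SMD| > 0.10
    undefined: bool = False


@dataclass
class CohortResult:
    cohort: pd.DataFrame
    panel: pd.DataFrame
    attrition: pd.DataFrame
    balance: pd.DataFrame


# ---------------------------------------------------------------------------
# index episode


def _window_supply(days: np.ndarray, supplied: np.ndarray, window: int) -> float:
    """Max total days supplied over any `window`-day span containing the fills."""
    if len(days) == 0:
        return 0.0
    order = np.argsort(days, kind="stable")
    days, supplied = days[order], supplied[order]
    best = 0.0
    j = 0
    for i in range(len(days)):
        if j < i:
            j = i
        while j + 1 < len(days) and days[j + 1] < days[i] + window:
            j += 1
        best = max(best, float(supplied[i:j + 1].sum()))
    return best


def identify_index_episode(
    fills: pd.DataFrame,
    config: CohortConfig | None = None,
    window_start: int | None = None,
) -> tuple[Optional[IndexEpisode], Optional[str]]:
    """First index-drug fill qualifying as a relatively-new-user episode.

    A candidate fill qualifies when (a) no fill of any other antipsychotic —
    including the other study drug — falls in the 180 days before it, and
    (b) no 90-day window inside that pre-period holds more than 30 days
    supplied of the index drug.  When `window_start` is given, fills whose
    180-day pre-period extends before the start of the claims window are not
    evaluable and cannot serve as the index.  Returns ``(episode, None)`` for
    the first qualifying fill, or ``(None, reason)`` with the failure reason
    of the last candidate examined.
    """
    config = config or CohortConfig()
    if (fills["days_supplied"] <= 0).any():
        raise DataError("fill with nonpositive days supplied")
    fills = fills.sort_values("day", kind="stable")
    cand = fills[fills["drug_class"].isin(INDEX_CLASSES)]
    if window_start is not None:
        cand = cand[cand["day"] >= window_start + config.pre_period_days]
    if cand.empty:
        return None, None
    ap = fills[fills["drug_class"].isin(ANTIPSYCHOTIC_CLASSES)]
    last_reason: Optional[str] = None
    for _, f in cand.iterrows():
        day = int(f["day"])
        drug_class = f["drug_class"]
        lo = day - config.pre_period_days
        pre = ap[(ap["day"] >= lo) & (ap["day"] < day)]
        other = pre[pre["drug_class"] != drug_class]
        if not other.empty:
            last_reason = "other_antipsychotic_pre_period"
            continue
        same = pre[pre["drug_class"] == drug_class]
        if _window_supply(same["day"].to_numpy(), same["days_supplied"].to_numpy(),
                          config.new_user_window_days) > config.new_user_max_days_supplied:
            last_reason = "not_new_user"
            continue
        return IndexEpisode(
            person_id=str(f["person_id"]),
            index_day=day,
            drug=INDEX_CLASSES[drug_class],
            pre_period_days_supplied=int(same["days_supplied"].sum()),
        ), None
    return None, last_reason


# ---------------------------------------------------------------------------
# eligibility


def _merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _covered(merged: list[tuple[int, int]], lo: int, hi: int) -> bool:
    """True when [lo, hi) is fully inside one merged enrolment span."""
    return any(s <= lo and e >= hi for s, e in merged)


def apply_eligibility(
    episode: IndexEpisode,
    dx_claims: pd.DataFrame,
    enrolment: pd.DataFrame,
    demographics: pd.Series,
    config: CohortConfig | None = None,
) -> EligibilityResult:
    """Cohort eligibility for one index episode; first failing check wins.

    Checks, in the fixed reporting order: continuous enrolment over the
    pre-period and the six months after index; no pre-period diabetes or
    cardiometabolic diagnosis; no pre-period polycystic ovarian syndrome;
    age 18-64 at index.
    """
    config = config or CohortConfig()
    day = episode.index_day
    merged = _merge_spans(
        zip(enrolment["start_day"].astype(int), enrolment["end_day"].astype(int))
    )
    if not _covered(merged, day - config.pre_period_days,
                    day + config.post_enrolment_days):
        return EligibilityResult(False, "enrolment_gap")
    pre = dx_claims[(dx_claims["day"] >= day - config.pre_period_days)
                    & (dx_claims["day"] < day)]
    if pre["code_group"].isin(["type2_diabetes", "excluded_cardiometabolic"]).any():
        return EligibilityResult(False, "prior_diabetes_or_cardiometabolic")
    if (pre["code_group"] == "pcos").any():
        return EligibilityResult(False, "pcos")
    birth = demographics.get("birth_day")
    if birth is None or (isinstance(birth, float) and np.isnan(birth)):
        raise DataError(f"missing birth date for {episode.person_id}")
    age = (day - int(birth)) // 365
    if not config.age_min <= age <= config.age_max:
        return EligibilityResult(False, "age_out_of_range")
    return EligibilityResult(True, "none")


# ---------------------------------------------------------------------------
# outcome ascertainment


def ascertain_outcome(
    dx_claims: pd.DataFrame,
    fills: pd.DataFrame,
    index_day: int,
    config: CohortConfig | None = None,
) -> OutcomeResult:
    """First qualifying evidence of incident type 2 diabetes after index.

    Qualifying rules: (i) an in-patient claim with a primary diabetes code;
    (ii) two out-patient claims (any position) within a 12-month window,
    dated at the first of the pair; (iii) one out-patient claim with an oral
    antidiabetic fill observed during follow-up.  Insulin fills never
    qualify: insulin-only treatment is taken to indicate type 1 diabetes.
    """
    config = config or CohortConfig()
    dia = dx_claims[(dx_claims["code_group"] == "type2_diabetes")
                    & (dx_claims["day"] >= index_day)]
    candidates: list[tuple[int, str]] = []

    inpat = dia[(dia["setting"] == "inpatient") & (dia["position"] == "primary")]
    if not inpat.empty:
        candidates.append((int(inpat["day"].min()), "inpatient_primary"))

    outpat_days = np.sort(dia.loc[dia["setting"] == "outpatient", "day"].to_numpy())
    for i in range(len(outpat_days) - 1):
        if outpat_days[i + 1] - outpat_days[i] < config.outpatient_pair_window_days:
            candidates.append((int(outpat_days[i]), "two_outpatient_12mo"))
            break

    oral = fills[(fills["drug_class"] == "oral_antidiabetic")
                 & (fills["day"] >= index_day)]
    if len(outpat_days) and not oral.empty:
        candidates.append((int(outpat_days[0]), "outpatient_plus_oral_antidiabetic"))

    if not candidates:
        return OutcomeResult(None, "none")
    rule_rank = {r: i for i, r in enumerate(OUTCOME_RULES)}
    day, rule = min(candidates, key=lambda c: (c[0], rule_rank[c[1]]))
    month = (day - index_day) // config.month_days + 1
    return OutcomeResult(month, rule)


# ---------------------------------------------------------------------------
# censoring


def determine_censoring(
    events: Iterable[tuple[int, str]], horizon: int
) -> CensoringOutcome:
    """Earliest censoring event; same-month ties break by the fixed hierarchy."""
    rank = {c: i for i, c in enumerate(CENSORING_CAUSES)}
    best: Optional[tuple[int, int, str]] = None
    for month, cause in events:
        if cause not in rank:
            raise ValueError(f"unknown censoring cause {cause!r}")
        if month > horizon:
            continue
        key = (month, rank[cause], cause)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return CensoringOutcome(horizon, "study_end")
    return CensoringOutcome(best[0], best[2])


# ---------------------------------------------------------------------------
# exposure / supply analysis


def _monotherapy_end(
    index_day: int,
    drug_class: str,
    fills: pd.DataFrame,
    config: CohortConfig,
) -> Optional[tuple[int, str]]:
    """Month and cause of the end of continuous index-drug monotherapy.

    A month counts as covered when any index-drug supply interval (with
    carryover of unused supply, capped at the stockpile limit) intersects it.
    The first other-antipsychotic fill converts the end into augmentation
    (index supply continues past the fill day) or a switch; otherwise the
    first uncovered month is a discontinuation.
    """
    md = config.month_days
    post = fills[fills["day"] >= index_day].sort_values("day", kind="stable")
    own = post[post["drug_class"] == drug_class]
    supply_end = index_day
    for _, f in own.iterrows():
        d = int(f["day"])
        if d > supply_end + config.grace_days:
            break  # supply gap: once off monotherapy, never back on
        carry = min(max(supply_end - d, 0), config.stockpile_cap_days)
        supply_end = d + carry + int(f["days_supplied"])
    m_cov = (supply_end + config.grace_days - index_day + md - 1) // md + 1

    other = post[post["drug_class"].isin(ANTIPSYCHOTIC_CLASSES)
                 & (post["drug_class"] != drug_class)]
    if not other.empty:
        d_ap = int(other["day"].min())
        m_ap = (d_ap - index_day) // md + 1
        if m_ap <= m_cov:
            cause = "augmentation" if supply_end > d_ap else "switch"
            return m_ap, cause
    return (m_cov, "discontinuation")


# ---------------------------------------------------------------------------
# panel assembly


def _person_panel_rows(
    pid: str,
    episode: IndexEpisode,
    end_month: int,
    event_month: Optional[int],
    censoring: Optional[CensoringOutcome],
    months_flags: dict[str, np.ndarray],
    baseline: dict,
) -> pd.DataFrame:
    months = np.arange(1, end_month + 1)
    censor_here = np.zeros(end_month, dtype=int)
    cause = np.array([""] * end_month, dtype=object)
    y = np.zeros(end_month, dtype=float)
    a = np.ones(end_month, dtype=int)
    if censoring is not None and censoring.month == end_month:
        censor_here[-1] = 1
        cause[-1] = censoring.cause
        y[-1] = np.nan
        if censoring.cause in MONOTHERAPY_END_CAUSES:
            a[-1] = 0
    elif event_month is not None and event_month == end_month:
        y[-1] = 1.0
    df = pd.DataFrame({
        "person_id": pid, "month": months, "drug": episode.drug,
        **baseline,
        "comorb": months_flags["comorb"][:end_month],
        "acute": months_flags["acute"][:end_month],
        "tested": months_flags["tested"][:end_month],
        "vacc": months_flags["vacc"][:end_month],
        "A": a, "C": censor_here, "cause": cause, "Y": y,
    })
    return df


def build_cohort(
    bundle: RawClaimsBundle,
    config: CohortConfig | None = None,
    window_days: int | None = None,
) -> CohortResult:
    """Full cohort construction: eligibility, outcome, censoring and panel.

    `window_days` is the calendar length of the claims window (used for the
    deterministic study-end censoring month); it defaults to the largest day
    observed across the claims streams rounded up to a month boundary.
    """
    config = config or CohortConfig()
    md = config.month_days
    if window_days is None:
        days = [int(df["day"].max()) for df in
                (bundle.fills, bundle.dx_claims, bundle.procedures) if len(df)]
        window_days = ((max(days) // md) + 1) * md if days else config.horizon * md

    fills_by = {k: v for k, v in bundle.fills.groupby("person_id", sort=False)}
    dx_by = {k: v for k, v in bundle.dx_claims.groupby("person_id", sort=False)}
    proc_by = {k: v for k, v in bundle.procedures.groupby("person_id", sort=False)}
    enrol_by = {k: v for k, v in bundle.enrolment.groupby("person_id", sort=False)}
    demo = bundle.demographics.set_index("person_id")

    empty_fills = bundle.fills.iloc[0:0]
    empty_dx = bundle.dx_claims.iloc[0:0]
    empty_proc = bundle.procedures.iloc[0:0]

    cohort_rows: list[dict] = []
    panel_parts: list[pd.DataFrame] = []
    attrition: dict[str, int] = {r: 0 for r in ELIGIBILITY_REASONS if r != "none"}
    attrition["no_index_fill"] = 0
    included = 0

    for pid in demo.index:
        person_fills = fills_by.get(pid, empty_fills)
        person_dx = dx_by.get(pid, empty_dx)
        person_proc = proc_by.get(pid, empty_proc)
        person_demo = demo.loc[pid]
        episode, fail = identify_index_episode(person_fills, config,
                                               window_start=0)
        if episode is None:
            reason = fail if fail is not None else "no_index_fill"
            attrition[reason] += 1
            cohort_rows.append({"person_id": pid, "eligible": 0,
                                "exclusion_reason": reason})
            continue
        elig = apply_eligibility(episode, person_dx,
                                 enrol_by.get(pid, bundle.enrolment.iloc[0:0]),
                                 person_demo, config)
        if not elig.eligible:
            attrition[elig.reason] += 1
            cohort_rows.append({"person_id": pid, "eligible": 0,
                                "exclusion_reason": elig.reason})
            continue
        included += 1
        index_day = episode.index_day
        drug_class = ("index_olanzapine" if episode.drug == OLANZAPINE
                      else "index_aripiprazole")

        events: list[tuple[int, str]] = []
        death_day = person_demo.get("death_day")
        if death_day is not None and not pd.isna(death_day):
            m = (int(death_day) - index_day) // md + 1
            if m >= 1:
                events.append((m, "death"))
        events.append(((window_days - index_day) // md + 1, "study_end"))
        events.append(((int(person_demo["birth_day"]) + 65 * 365 - index_day) // md + 1,
                       "age_65"))
        merged = _merge_spans(zip(
            enrol_by[pid]["start_day"].astype(int),
            enrol_by[pid]["end_day"].astype(int))) if pid in enrol_by else []
        for m in range(1, config.horizon + 1):
            lo = index_day + (m - 1) * md
            if not _covered(merged, lo, lo + md):
                events.append((m, "coverage_loss"))
                break
        events.append(_monotherapy_end(index_day, drug_class, person_fills, config))
        real_events = [(m, c) for m, c in events if m <= config.horizon]
        censoring = (determine_censoring(real_events, config.horizon)
                     if real_events else None)
        c_month = censoring.month if censoring else config.horizon + 1

        outcome = ascertain_outcome(person_dx, person_fills, index_day, config)
        event_month = outcome.event_month
        # within a month, censoring precedes the outcome draw
        if event_month is not None and (event_month > config.horizon
                                        or event_month >= c_month):
            event_month = None
        if event_month is not None:
            end_month = event_month
            censor_flag = None
        elif censoring is not None:
            end_month = c_month
            censor_flag = censoring
        else:
            end_month = config.horizon
            censor_flag = None
        censoring_record = censoring or CensoringOutcome(config.horizon, "study_end")

        # month-level covariate flags derived from the claims streams
        flags = {k: np.zeros(config.horizon, dtype=int)
                 for k in ("comorb", "acute", "tested", "vacc")}
        for day, setting, group in zip(person_dx["day"], person_dx["setting"],
                                       person_dx["code_group"]):
            if group != "other" or day < index_day:
                continue
            m = (int(day) - index_day) // md
            if 0 <= m < config.horizon:
                flags["comorb" if setting == "outpatient" else "acute"][m] = 1
        for day, kind in zip(person_proc["day"], person_proc["kind"]):
            if day < index_day:
                continue
            m = (int(day) - index_day) // md
            if 0 <= m < config.horizon:
                key = "tested" if kind == "metabolic_test" else "vacc"
                flags[key][m] = 1

        age = (index_day - int(person_demo["birth_day"])) // 365
        pre = person_fills[(person_fills["drug_class"] == drug_class)
                           & (person_fills["day"] >= index_day - config.pre_period_days)
                           & (person_fills["day"] < index_day)]
        pre_dx = person_dx[(person_dx["day"] >= index_day - config.pre_period_days)
                           & (person_dx["day"] < index_day)]
        baseline = {
            "dx": person_demo["dx"],
            "age": age,
            "older": int(age > 45),
            "female": int(person_demo["sex"] == "F"),
            "nonwhite": int(person_demo["race_group"] != "white"),
            "state": int(person_demo["state"]),
            "index_year": 2008 + index_day // 365,
            "pre_rx_days": int(pre["days_supplied"].sum()),
            "comorb0": int(((pre_dx["code_group"] == "other")
                            & (pre_dx["setting"] == "outpatient")).any()),
        }
        panel_parts.append(_person_panel_rows(
            pid, episode, end_month, event_month, censor_flag, flags, baseline))
        cohort_rows.append({
            "person_id": pid, "eligible": 1, "exclusion_reason": "none",
            "drug": episode.drug, "index_day": index_day,
            "pre_rx_days": episode.pre_period_days_supplied,
            "event_month": event_month if event_month is not None else 0,
            "censor_month": censoring_record.month,
            "censor_cause": censoring_record.cause,
            **{k: v for k, v in baseline.items() if k != "pre_rx_days"},
        })

    cohort = pd.DataFrame(cohort_rows)
    if panel_parts:
        panel = pd.concat(panel_parts, ignore_index=True)
        panel = panel[PANEL_COLUMNS].sort_values(["person_id", "month"]).reset_index(drop=True)
    else:
        panel = pd.DataFrame(columns=PANEL_COLUMNS)
    att = pd.DataFrame(
        [{"reason": "included", "count": included}]
        + [{"reason": r, "count": c} for r, c in attrition.items()]
    )
    balance = compute_balance_table(cohort)
    return CohortResult(cohort=cohort, panel=panel, attrition=att, balance=balance)


# ---------------------------------------------------------------------------
# covariate balance


def compute_smd(cohort: pd.DataFrame, variable: str) -> CovariateBalance:
    """Standardised mean difference, olanzapine minus aripiprazole.

    The difference is standardised by the aripiprazole-group standard
    deviation; |SMD| > 0.10 flags imbalance.
    """
    elig = cohort[cohort.get("eligible", 1) == 1]
    ari = elig.loc[elig["drug"] == ARIPIPRAZOLE, variable].astype(float)
    olz = elig.loc[elig["drug"] == OLANZAPINE, variable].astype(float)
    if len(ari) == 0 or len(olz) == 0:
        raise ValueError(f"variable {variable!r} unobserved in one drug group")
    sd = float(ari.std(ddof=1))
    m_ari, m_olz = float(ari.mean()), float(olz.mean())
    if sd == 0 or np.isnan(sd):
        return CovariateBalance(variable, m_ari, m_olz, float("nan"),
                                unbalanced=False, undefined=True)
    smd = (m_olz - m_ari) / sd
    return CovariateBalance(variable, m_ari, m_olz, smd, unbalanced=abs(smd) > 0.10)


BALANCE_VARIABLES = ("age", "older", "female", "nonwhite", "pre_rx_days",
                     "comorb0")


def compute_balance_table(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    elig = cohort[cohort.get("eligible", pd.Series(dtype=int)) == 1] if len(cohort) else cohort
    for var in BALANCE_VARIABLES:
        if var not in cohort.columns or len(elig) == 0:
            continue
        try:
            b = compute_smd(cohort, var)
        except ValueError:
            continue
        rows.append({"variable": b.variable, "mean_aripiprazole": b.mean_aripiprazole,
                     "mean_olanzapine": b.mean_olanzapine, "smd": b.smd,
                     "unbalanced": b.unbalanced, "undefined": b.undefined})
    return pd.DataFrame(rows)
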