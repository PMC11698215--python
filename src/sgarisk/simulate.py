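"""Synthetic administrative-claims world with exactly computable ground truth.

The generator emulates the structure a comparative-safety analysis of two
index antipsychotics needs: monthly continuous-monotherapy exposure, a small
finite time-varying covariate state, a seven-cause censoring process and a
rare incident-diabetes outcome.  Because the covariate state space is finite,
the counterfactual risk under the regime "always on monotherapy, never
censored" is computable by exact forward recursion rather than simulation.

Within a month the order of play is: covariates update, then censoring given
the updated covariates, then the outcome among the uncensored.  The analytic
panel records one row per person-month up to (and including) the first event
or censoring month; the censoring-month row carries the updated covariates
and a missing outcome.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit as _scipy_expit

from .config import (
    ARIPIPRAZOLE,
    CENSORING_CAUSES,
    DGPConfig,
    DIAGNOSES,
    DRUGS,
    MONOTHERAPY_END_CAUSES,
    OLANZAPINE,
    ConfigurationError,
)

PANEL_COLUMNS = [
    "person_id", "month", "drug", "dx", "age", "older", "female", "nonwhite",
    "state", "index_year", "pre_rx_days", "comorb0", "comorb", "acute",
    "tested", "vacc", "A", "C", "cause", "Y",
]


def _expit(x: np.ndarray) -> np.ndarray:
    return _scipy_expit(np.asarray(x, dtype=float))


@dataclass
class TruthReport:
    """Exact counterfactual risk curves of the generating configuration.

    Risks are cumulative probabilities of incident diabetes by the end of each
    month under forced continuous monotherapy with no censoring.
    """

    horizon: int
    risks: dict[str, np.ndarray]          # drug -> psi_a(t), t = 1..horizon
    rmst: dict[str, float]                # drug -> sum of survival probs

    @property
    def survival(self) -> dict[str, np.ndarray]:
        return {d: 1.0 - r for d, r in self.risks.items()}

    @property
    def rmst_difference(self) -> float:
        """Olanzapine minus aripiprazole diabetes-free months."""
        return self.rmst[OLANZAPINE] - self.rmst[ARIPIPRAZOLE]

    def risk_difference(self, month: int) -> float:
        return self.risks[OLANZAPINE][month - 1] - self.risks[ARIPIPRAZOLE][month - 1]

    def risk_ratio(self, month: int) -> float:
        denom = self.risks[ARIPIPRAZOLE][month - 1]
        if denom <= 0:
            return float("nan")
        return self.risks[OLANZAPINE][month - 1] / denom

    def to_dict(self) -> dict:
        out = {
            "horizon": self.horizon,
            "risks": {d: list(map(float, r)) for d, r in self.risks.items()},
            "rmst": {d: float(v) for d, v in self.rmst.items()},
            "rmst_difference": float(self.rmst_difference),
            "risk_difference": [self.risk_difference(t) for t in range(1, self.horizon + 1)],
            "risk_ratio": [self.risk_ratio(t) for t in range(1, self.horizon + 1)],
        }
        return out


@dataclass
class SimulationResult:
    panel: pd.DataFrame
    persons: pd.DataFrame
    truth: TruthReport


@dataclass
class RawClaimsBundle:
    """Person-level claims streams consumed by the cohort builder."""

    fills: pd.DataFrame        # person_id, day, drug_class, days_supplied
    dx_claims: pd.DataFrame    # person_id, day, setting, position, code_group
    enrolment: pd.DataFrame    # person_id, start_day, end_day  (half-open)
    procedures: pd.DataFrame   # person_id, day, kind
    demographics: pd.DataFrame  # person_id, birth_day, sex, race_group, state, dx, death_day
    latent_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# linear predictors


def _lp(coeffs: dict[str, float], feats: dict[str, np.ndarray], n: int) -> np.ndarray:
    lp = np.zeros(n)
    for name, beta in coeffs.items():
        if name == "intercept":
            lp += beta
        else:
            lp += beta * feats[name]
    return lp


def _baseline_features(b: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {
        "dx_bipolar": (b["dx"] == "bipolar").astype(float),
        "dx_mdd": (b["dx"] == "severe_mdd").astype(float),
        "older": b["older"].astype(float),
        "female": b["female"].astype(float),
        "nonwhite": b["nonwhite"].astype(float),
        "pre_rx_any": (b["pre_rx_days"] > 0).astype(float),
        "comorb0": b["comorb0"].astype(float),
    }


# ---------------------------------------------------------------------------
# panel simulation


def _draw_baseline(config: DGPConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = config.n_subjects
    spec = config.baseline_covariate_spec
    cal = config.calendar
    dx = rng.choice(DIAGNOSES, size=n,
                    p=[config.diagnosis_mix[d] for d in DIAGNOSES])
    age = rng.integers(spec.age_min, spec.age_max + 1, size=n)
    female = rng.random(n) < spec.p_female
    nonwhite = rng.random(n) < spec.p_nonwhite
    state = rng.integers(0, spec.n_states, size=n)
    pre_any = rng.random(n) < spec.p_pre_rx
    pre_days = np.where(pre_any, rng.integers(1, spec.pre_rx_max_days + 1, size=n), 0)
    index_day = rng.integers(cal.index_day_min, cal.index_day_max + 1, size=n)
    days_since_bday = rng.integers(0, 365, size=n)
    birth_day = index_day - age * 365 - days_since_bday
    older = age > 45
    p_c0 = spec.p_comorb0 + spec.p_comorb0_older_add * older
    comorb0 = rng.random(n) < p_c0
    return {
        "dx": dx, "age": age, "older": older, "female": female,
        "nonwhite": nonwhite, "state": state, "pre_rx_days": pre_days,
        "index_day": index_day, "birth_day": birth_day, "comorb0": comorb0,
        "index_year": cal.start_year + index_day // 365,
    }


def simulate_cohort(config: DGPConfig) -> SimulationResult:
    """Draw the observed longitudinal panel and its exact truth report."""
    n, H = config.n_subjects, config.horizon
    cal = config.calendar
    rng = np.random.default_rng(config.seed)
    b = _draw_baseline(config, rng)
    feats = _baseline_features(b)

    p_olz = _expit(_lp(config.treatment_assignment_coefficients, feats, n))
    olz = rng.random(n) < p_olz
    drug = np.where(olz, OLANZAPINE, ARIPIPRAZOLE)
    ari = (~olz).astype(float)

    # deterministic calendar/age censoring months (inf when beyond horizon)
    first_incomplete = (cal.window_days - b["index_day"]) // cal.month_days + 1
    study_end_month = np.where(first_incomplete <= H, first_incomplete, 10 ** 6)
    turn65 = b["birth_day"] + 65 * 365
    m65 = (turn65 - b["index_day"]) // cal.month_days + 1
    age65_month = np.where(m65 <= H, m65, 10 ** 6)

    cens = config.cause_specific_censoring_rates
    dyn = config.covariate_dynamics
    mix = cens.stop_cause_mix
    mix_cum = np.cumsum([mix[c] for c in MONOTHERAPY_END_CAUSES])

    comorb = b["comorb0"].copy()
    active = np.ones(n, dtype=bool)
    rows: list[pd.DataFrame] = []
    event_month = np.full(n, 10 ** 6)
    censor_month = np.full(n, 10 ** 6)
    censor_cause = np.full(n, "", dtype=object)

    onset_p = dyn.comorb_onset + dyn.comorb_onset_older_add * b["older"]
    for t in range(1, H + 1):
        # --- covariates update (L_t) for everyone entering month t
        comorb = comorb | (rng.random(n) < onset_p)
        acute = rng.random(n) < (dyn.p_acute + dyn.p_acute_comorb_add * comorb)
        tested = rng.random(n) < config.testing_rate
        tv = dict(feats)
        tv.update({
            "comorb": comorb.astype(float), "acute": acute.astype(float),
            "tested": tested.astype(float),
            "month_frac": np.full(n, (t - 1) / H),
            "ari": ari, "olz": 1.0 - ari,
        })
        vacc = rng.random(n) < _expit(_lp(config.vaccination_hazard_coefficients, tv, n))

        # --- censoring given (W, L_t): hierarchy on same-month ties
        death = rng.random(n) < cens.death_rate
        coverage = (rng.random(n) < cens.coverage_loss_rate) & (
            t >= cens.coverage_loss_min_month
        )
        p_stay = _expit(_lp(config.adherence_hazard_coefficients, tv, n))
        # the index fill itself covers month 1, so monotherapy can only end
        # from month 2 onward
        stop = (rng.random(n) >= p_stay) & (t >= 2)
        u = rng.random(n)
        stop_cause = np.select(
            [u < mix_cum[0], u < mix_cum[1]],
            [MONOTHERAPY_END_CAUSES[0], MONOTHERAPY_END_CAUSES[1]],
            default=MONOTHERAPY_END_CAUSES[2],
        )
        fired = {
            "death": death,
            "study_end": study_end_month == t,
            "age_65": age65_month == t,
            "coverage_loss": coverage,
            "discontinuation": stop & (stop_cause == "discontinuation"),
            "augmentation": stop & (stop_cause == "augmentation"),
            "switch": stop & (stop_cause == "switch"),
        }
        cause_t = np.full(n, "", dtype=object)
        for c in reversed(CENSORING_CAUSES):  # earliest-listed cause wins
            cause_t = np.where(fired[c], c, cause_t)
        censored_now = active & (cause_t != "")

        # --- outcome among the at-risk, uncensored
        y_draw = rng.random(n) < _expit(_lp(config.outcome_hazard_coefficients, tv, n))
        event_now = active & ~censored_now & y_draw

        idx = np.where(active)[0]
        mono_end = np.isin(cause_t[idx], MONOTHERAPY_END_CAUSES)
        rows.append(pd.DataFrame({
            "person_id": idx,
            "month": t,
            "drug": drug[idx],
            "comorb": comorb[idx].astype(int),
            "acute": acute[idx].astype(int),
            "tested": tested[idx].astype(int),
            "vacc": vacc[idx].astype(int),
            "A": np.where(censored_now[idx] & mono_end, 0, 1),
            "C": censored_now[idx].astype(int),
            "cause": np.where(censored_now[idx], cause_t[idx], ""),
            "Y": np.where(censored_now[idx], np.nan, y_draw[idx].astype(float)),
        }))
        event_month[event_now] = t
        censor_month[censored_now] = t
        censor_cause[censored_now] = cause_t[censored_now]
        active &= ~censored_now & ~event_now

    panel = pd.concat(rows, ignore_index=True)
    person_ids = np.array([f"p{i:06d}" for i in range(n)])
    base_df = pd.DataFrame({
        "person_id": person_ids,
        "drug": drug,
        "dx": b["dx"],
        "age": b["age"],
        "older": b["older"].astype(int),
        "female": b["female"].astype(int),
        "nonwhite": b["nonwhite"].astype(int),
        "state": b["state"],
        "index_year": b["index_year"],
        "pre_rx_days": b["pre_rx_days"],
        "comorb0": b["comorb0"].astype(int),
        "index_day": b["index_day"],
        "birth_day": b["birth_day"],
        "event_month": np.where(event_month <= H, event_month, 0),
        "censor_month": np.where(censor_month <= H, censor_month, 0),
        "censor_cause": censor_cause,
    })
    panel = panel.merge(
        base_df.drop(columns=["drug", "index_day", "birth_day", "event_month",
                              "censor_month", "censor_cause"]).assign(
            _pid=np.arange(n)).rename(columns={"person_id": "pid_str"}),
        left_on="person_id", right_on="_pid",
    )
    panel["person_id"] = panel["pid_str"]
    panel = panel.drop(columns=["pid_str", "_pid"])
    panel = panel[PANEL_COLUMNS].sort_values(["person_id", "month"]).reset_index(drop=True)
    truth = compute_truth(config)
    return SimulationResult(panel=panel, persons=base_df, truth=truth)


def generate_panel(config: DGPConfig) -> tuple[pd.DataFrame, TruthReport]:
    """The analytic panel plus the exact counterfactual truth of its world."""
    sim = simulate_cohort(config)
    return sim.panel, sim.truth


# ---------------------------------------------------------------------------
# exact counterfactual truth


def _coef(coeffs: dict[str, float], name: str) -> float:
    return coeffs.get(name, 0.0)


def _cell_risk_curve(config: DGPConfig, drug: str, dx: str, older: int,
                     female: int) -> np.ndarray:
    """Exact forward recursion over the (comorb, acute) state for one cell."""
    H = config.horizon
    spec = config.baseline_covariate_spec
    dyn = config.covariate_dynamics
    beta = config.outcome_hazard_coefficients
    base_lp = (
        _coef(beta, "intercept")
        + _coef(beta, "ari") * (drug == ARIPIPRAZOLE)
        + _coef(beta, "olz") * (drug == OLANZAPINE)
        + _coef(beta, "dx_bipolar") * (dx == "bipolar")
        + _coef(beta, "dx_mdd") * (dx == "severe_mdd")
        + _coef(beta, "older") * older
        + _coef(beta, "female") * female
    )
    onset = min(dyn.comorb_onset + dyn.comorb_onset_older_add * older, 1.0)
    p_acute = {c: min(dyn.p_acute + dyn.p_acute_comorb_add * c, 1.0) for c in (0, 1)}
    # expected hazard given comorb state, averaging over the fresh acute draw
    # and the testing indicator (tested enters no default hazard but may be
    # configured, so marginalise over it too)
    p_test = config.testing_rate

    def hbar(c: int, t: int) -> float:
        lp = base_lp + _coef(beta, "comorb") * c + _coef(beta, "month_frac") * (t - 1) / H
        h = 0.0
        for a in (0, 1):
            for s in (0, 1):
                w = (p_acute[c] if a else 1 - p_acute[c]) * (p_test if s else 1 - p_test)
                h += w * float(_expit(lp + _coef(beta, "acute") * a
                                   + _coef(beta, "tested") * s))
        return h

    p_comorb = min(spec.p_comorb0 + spec.p_comorb0_older_add * older, 1.0)
    S, cum = 1.0, 0.0
    risks = np.empty(H)
    for t in range(1, H + 1):
        p_comorb = p_comorb + (1 - p_comorb) * onset
        h1, h0 = hbar(1, t), hbar(0, t)
        m = p_comorb * h1 + (1 - p_comorb) * h0
        cum += S * m
        S *= 1 - m
        risks[t - 1] = cum
        if m < 1.0:
            p_comorb = p_comorb * (1 - h1) / (1 - m)
    return risks


def true_risk_curve(config: DGPConfig, drug: str) -> np.ndarray:
    """psi_a(t) for t = 1..horizon under forced monotherapy, no censoring."""
    if drug not in DRUGS:
        raise ValueError(f"unknown index drug {drug!r}; expected one of {DRUGS}")
    spec = config.baseline_covariate_spec
    ages = np.arange(spec.age_min, spec.age_max + 1)
    p_older = float(np.mean(ages > 45))
    total = np.zeros(config.horizon)
    for dx in DIAGNOSES:
        for older in (0, 1):
            for female in (0, 1):
                w = (config.diagnosis_mix[dx]
                     * (p_older if older else 1 - p_older)
                     * (spec.p_female if female else 1 - spec.p_female))
                if w == 0:
                    continue
                total += w * _cell_risk_curve(config, drug, dx, older, female)
    return total


def true_counterfactual_risk(config: DGPConfig, drug: str, month: int) -> float:
    """Exact cumulative diabetes risk by `month` under the always-treated regime."""
    if not 1 <= month <= config.horizon:
        raise ValueError(f"month must be in 1..{config.horizon}")
    return float(true_risk_curve(config, drug)[month - 1])


def true_rmst(config: DGPConfig, drug: str) -> float:
    """Exact diabetes-free months over the horizon: sum of survival probabilities."""
    return float(np.sum(1.0 - true_risk_curve(config, drug)))


def compute_truth(config: DGPConfig) -> TruthReport:
    risks = {d: true_risk_curve(config, d) for d in DRUGS}
    rmst = {d: float(np.sum(1.0 - risks[d])) for d in DRUGS}
    return TruthReport(horizon=config.horizon, risks=risks, rmst=rmst)


def simulate_intervened(config: DGPConfig, drug: str, n: int,
                        seed: int) -> np.ndarray:
    """Monte-Carlo event months under forced monotherapy with no censoring.

    Returns the event month per replicate (0 when diabetes-free through the
    horizon).  Serves as a simulation check of the exact recursion.
    """
    if drug not in DRUGS:
        raise ValueError(f"unknown index drug {drug!r}")
    H = config.horizon
    spec = config.baseline_covariate_spec
    dyn = config.covariate_dynamics
    beta = config.outcome_hazard_coefficients
    rng = np.random.default_rng(seed)
    dx = rng.choice(DIAGNOSES, size=n, p=[config.diagnosis_mix[d] for d in DIAGNOSES])
    age = rng.integers(spec.age_min, spec.age_max + 1, size=n)
    older = age > 45
    female = rng.random(n) < spec.p_female
    comorb = rng.random(n) < np.minimum(
        spec.p_comorb0 + spec.p_comorb0_older_add * older, 1.0)
    onset_p = dyn.comorb_onset + dyn.comorb_onset_older_add * older
    lp_base = (
        _coef(beta, "intercept")
        + _coef(beta, "ari") * (drug == ARIPIPRAZOLE)
        + _coef(beta, "olz") * (drug == OLANZAPINE)
        + _coef(beta, "dx_bipolar") * (dx == "bipolar")
        + _coef(beta, "dx_mdd") * (dx == "severe_mdd")
        + _coef(beta, "older") * older
        + _coef(beta, "female") * female
    )
    event = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for t in range(1, H + 1):
        comorb = comorb | (rng.random(n) < onset_p)
        acute = rng.random(n) < (dyn.p_acute + dyn.p_acute_comorb_add * comorb)
        tested = rng.random(n) < config.testing_rate
        lp = (lp_base + _coef(beta, "comorb") * comorb
              + _coef(beta, "acute") * acute + _coef(beta, "tested") * tested
              + _coef(beta, "month_frac") * (t - 1) / H)
        y = rng.random(n) < _expit(lp)
        hit = alive & y
        event[hit] = t
        alive &= ~y
    return event


# ---------------------------------------------------------------------------
# claims encoding


def _claims_for_person(pid: str, row: pd.Series, person_panel: pd.DataFrame,
                       cal, rng: np.random.Generator, fills: list, dx_claims: list,
                       procedures: list) -> None:
    """Emit the claims streams that encode one latent person's panel."""
    md = cal.month_days
    index_day = int(row["index_day"])
    drug_class = ("index_olanzapine" if row["drug"] == OLANZAPINE
                  else "index_aripiprazole")
    # pre-period: historic other-antipsychotic exposure plus limited index-drug
    # supply (kept under the relatively-new-user cap)
    if row["pre_rx_days"] > 0:
        fills.append((pid, index_day - 290, "other_antipsychotic", 30))
        fills.append((pid, index_day - 150, drug_class, int(row["pre_rx_days"])))
    if row["comorb0"]:
        dx_claims.append((pid, index_day - 40, "outpatient", "secondary", "other"))

    months = person_panel.sort_values("month")
    end_month = int(months["month"].max())
    last = months.iloc[-1]
    cause = last["cause"]
    if cause in ("discontinuation", "switch"):
        last_fill_month = end_month - 1
    else:
        last_fill_month = end_month

    for _, m in months.iterrows():
        t = int(m["month"])
        m_start = index_day + (t - 1) * md
        if t <= last_fill_month:
            fills.append((pid, m_start, drug_class, md))
        if m["comorb"]:
            dx_claims.append((pid, m_start + 2, "outpatient", "secondary", "other"))
        if m["acute"]:
            dx_claims.append((pid, m_start + 5, "inpatient", "secondary", "other"))
        if m["tested"]:
            procedures.append((pid, m_start + 8, "metabolic_test"))
        if m["vacc"]:
            procedures.append((pid, m_start + 9, "influenza_vaccination"))
        if cause == "augmentation" and t == end_month:
            fills.append((pid, m_start + 5, "other_antipsychotic", md))
        if cause == "switch" and t == end_month:
            fills.append((pid, m_start + 2, "other_antipsychotic", md))
        if m["Y"] == 1.0:
            m_start_e = m_start
            rule = rng.choice(["inpatient_primary", "two_outpatient",
                               "outpatient_plus_oral"], p=[0.4, 0.3, 0.3])
            if rule == "inpatient_primary":
                dx_claims.append((pid, m_start_e + 6, "inpatient", "primary",
                                  "type2_diabetes"))
            elif rule == "two_outpatient":
                dx_claims.append((pid, m_start_e + 3, "outpatient", "primary",
                                  "type2_diabetes"))
                dx_claims.append((pid, m_start_e + 17, "outpatient", "secondary",
                                  "type2_diabetes"))
            else:
                dx_claims.append((pid, m_start_e + 3, "outpatient", "primary",
                                  "type2_diabetes"))
                fills.append((pid, m_start_e + 10, "oral_antidiabetic", md))


def _distractor_person(kind: str, pid: str, cal, rng: np.random.Generator,
                       fills: list, dx_claims: list, demo: list, enrol: list) -> None:
    """One person violating a single eligibility rule (or an insulin decoy)."""
    md = cal.month_days
    index_day = int(rng.integers(cal.index_day_min, cal.index_day_max + 1))
    age = 66 if kind == "age_out_of_range" else int(rng.integers(18, 65))
    birth_day = index_day - age * 365 - int(rng.integers(0, 365))
    female = kind == "pcos" or bool(rng.random() < 0.5)
    demo.append((pid, birth_day, "F" if female else "M",
                 "nonwhite" if rng.random() < 0.33 else "white",
                 int(rng.integers(0, 7)), str(rng.choice(DIAGNOSES)), np.nan))
    enrol_start = index_day - (120 if kind == "enrolment_gap" else 180)
    enrol.append((pid, enrol_start, index_day + 360))
    drug_class = ("index_olanzapine" if rng.random() < 0.5 else "index_aripiprazole")
    if kind == "not_new_user":
        # earlier fill disqualified by a historic antipsychotic; the index-day
        # fill then trips the 30-days-per-90 supply rule
        fills.append((pid, index_day - 240, "other_antipsychotic", 30))
        fills.append((pid, index_day - 60, drug_class, 45))
        fills.append((pid, index_day, drug_class, md))
        return
    if kind == "other_antipsychotic_pre_period":
        fills.append((pid, index_day - 90, "other_antipsychotic", 30))
        fills.append((pid, index_day, drug_class, md))
        return
    for t in range(1, 7):  # six months of uneventful monotherapy
        fills.append((pid, index_day + (t - 1) * md, drug_class, md))
    if kind == "prior_diabetes_or_cardiometabolic":
        dx_claims.append((pid, index_day - 70, "outpatient", "primary",
                          "excluded_cardiometabolic"))
    elif kind == "pcos":
        dx_claims.append((pid, index_day - 70, "outpatient", "secondary", "pcos"))
    elif kind == "insulin_only":
        # eligible decoy: insulin fills plus one out-patient diabetes claim
        # must never be ascertained as incident type 2 diabetes
        for t in (1, 2, 3):
            fills.append((pid, index_day + (t - 1) * md + 10, "insulin", md))
        dx_claims.append((pid, index_day + 2 * md + 4, "outpatient", "secondary",
                          "type2_diabetes"))


def generate_claims(config: DGPConfig) -> RawClaimsBundle:
    """Encode a simulated cohort as raw claims streams.

    The latent panel is retained on the bundle so round-trip tests can compare
    what the cohort builder recovers against what was generated.  Distractor
    persons violating eligibility rules are appended in the configured
    proportions.
    """
    cal = config.calendar
    if cal.index_day_min + config.horizon * cal.month_days > cal.window_days:
        raise ConfigurationError("horizon longer than the simulated calendar window")
    sim = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_777]))
    fills: list = []
    dx_claims: list = []
    procedures: list = []
    demo: list = []
    enrol: list = []

    panel_by_person = dict(tuple(sim.panel.groupby("person_id", sort=True)))
    for _, row in sim.persons.iterrows():
        pid = row["person_id"]
        death_day = np.nan
        pp = panel_by_person[pid]
        end_month = int(pp["month"].max())
        if row["censor_cause"] == "death":
            death_day = row["index_day"] + (end_month - 1) * cal.month_days + 14
        demo.append((pid, int(row["birth_day"]), "F" if row["female"] else "M",
                     "nonwhite" if row["nonwhite"] else "white",
                     int(row["state"]), row["dx"], death_day))
        if row["censor_cause"] == "coverage_loss":
            enrol_end = int(row["index_day"] + (end_month - 1) * cal.month_days)
        else:
            enrol_end = cal.window_days
        enrol.append((pid, int(row["index_day"]) - 180, enrol_end))
        _claims_for_person(pid, row, pp, cal, rng, fills, dx_claims, procedures)

    n = config.n_subjects
    k = 0
    for kind, frac in sorted(config.distractors.items()):
        for _ in range(int(round(frac * n))):
            _distractor_person(kind, f"d{k:06d}", cal, rng, fills, dx_claims,
                               demo, enrol)
            k += 1

    bundle = RawClaimsBundle(
        fills=pd.DataFrame(fills, columns=["person_id", "day", "drug_class",
                                           "days_supplied"]),
        dx_claims=pd.DataFrame(dx_claims, columns=["person_id", "day", "setting",
                                                   "position", "code_group"]),
        enrolment=pd.DataFrame(enrol, columns=["person_id", "start_day", "end_day"]),
        procedures=pd.DataFrame(procedures, columns=["person_id", "day", "kind"]),
        demographics=pd.DataFrame(demo, columns=["person_id", "birth_day", "sex",
                                                 "race_group", "state", "dx",
                                                 "death_day"]),
        latent_truth=sim.panel,
    )
    for df in (bundle.fills, bundle.dx_claims, bundle.procedures):
        df.sort_values(["person_id", "day"], inplace=True, kind="stable")
        df.reset_index(drop=True, inplace=True)
    if (bundle.fills["days_supplied"] <= 0).any():
        raise ValueError("generated fill with nonpositive days supplied")
    return bundle
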