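"""Longitudinal targeted minimum loss-based estimation for discrete-time survival.

Estimates counterfactual monthly diabetes risk under the static regime
"continuous index-drug monotherapy, never censored", by iterated conditional
expectations (sequential regression) with one logistic fluctuation per time
point.  The clever covariate is the regime indicator divided by the cumulative
product of the treatment propensity and the monthly probabilities of remaining
on the regime.  Standard errors come from the estimated efficient influence
function; restricted mean survival time (RMST) is the sum of monthly survival
probabilities, with cross-month influence-function covariance retained.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import (
    ARIPIPRAZOLE,
    DRUGS,
    EstimatorConfig,
    OLANZAPINE,
    SuperLearnerConfig,
)
from .superlearner import fit_super_learner, predict_ensemble

Z95 = 1.959963984540054


class PositivityError(RuntimeError):
    """No at-risk observations (or no support) at some month."""


@dataclass(frozen=True)
class RegimeSpec:
    """Static regime: start on `drug`, stay adherent and uncensored."""

    drug: str

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown index drug {self.drug!r}")


@dataclass
class RiskEstimate:
    month: int
    drug: str
    risk: float
    se: float
    lo: float
    hi: float
    influence: Optional[np.ndarray] = None


@dataclass
class SurvivalCurve:
    drug: str
    months: np.ndarray
    risk: np.ndarray           # isotonised cumulative risk
    survival: np.ndarray       # 1 - risk
    se: np.ndarray
    influence: Optional[np.ndarray] = None  # n x T, per-month contributions


@dataclass
class SingleRMST:
    drug: str
    rmst: float
    se: float
    lo: float
    hi: float


@dataclass
class RMSTEstimate:
    per_drug: dict[str, SingleRMST]
    difference: float          # olanzapine minus aripiprazole
    diff_se: float
    diff_lo: float
    diff_hi: float


@dataclass
class ContrastEstimate:
    month: int
    rd_pp: float               # risk difference in percentage points
    rd_lo: float
    rd_hi: float
    rr: Optional[float]
    rr_lo: Optional[float]
    rr_hi: Optional[float]


@dataclass
class NuisanceEstimates:
    """Propensity and monthly remain-on-regime probabilities.

    ``cumulative`` holds, per person and month, the truncated product
    g_A(W) * prod_{r<=t} g_r; it is defined only where the person has a row.
    """

    drug: str
    g_treatment: np.ndarray            # n
    g_month: list[np.ndarray]          # per month, aligned with rows at t
    cumulative: np.ndarray             # n x T, NaN where undefined
    floor: float


# ---------------------------------------------------------------------------
# panel preparation


@dataclass
class PanelData:
    person_ids: np.ndarray
    n: int
    horizon: int
    drug: np.ndarray                       # per person
    X_base: np.ndarray                     # n x p, month-1 features
    month_rows: list[dict]                 # per month: idx, X, C, Y

    @classmethod
    def from_panel(cls, panel: pd.DataFrame,
                   config: EstimatorConfig | None = None) -> "PanelData":
        config = config or EstimatorConfig()
        df = panel.copy()
        df["dx_bipolar"] = (df["dx"] == "bipolar").astype(float)
        df["dx_mdd"] = (df["dx"] == "severe_mdd").astype(float)
        df["pre_rx_any"] = (df["pre_rx_days"] > 0).astype(float)
        feats = list(config.baseline_features) + list(config.timevarying_features)
        missing = [c for c in feats if c not in df.columns]
        if missing:
            raise ValueError(f"panel lacks feature column(s) {missing}")
        df = df.sort_values(["person_id", "month"], kind="stable")
        first = df[df["month"] == 1]
        person_ids = first["person_id"].to_numpy()
        pindex = {p: i for i, p in enumerate(person_ids)}
        n = len(person_ids)
        horizon = min(int(df["month"].max()), config.horizon)
        month_rows = []
        for t in range(1, horizon + 1):
            sub = df[df["month"] == t]
            idx = np.array([pindex[p] for p in sub["person_id"]])
            month_rows.append({
                "idx": idx,
                "X": sub[feats].to_numpy(dtype=float),
                "C": sub["C"].to_numpy(dtype=int),
                "Y": sub["Y"].to_numpy(dtype=float),
            })
        return cls(
            person_ids=person_ids, n=n, horizon=horizon,
            drug=first["drug"].to_numpy(),
            X_base=first[feats].to_numpy(dtype=float),
            month_rows=month_rows,
        )


def _sl_seed(sl: SuperLearnerConfig, *parts: int) -> int:
    return int(np.random.SeedSequence([sl.seed] + list(parts)).generate_state(1)[0]
               % (2 ** 31))


# ---------------------------------------------------------------------------
# nuisance estimation


def fit_nuisances(
    panel: pd.DataFrame | PanelData,
    regime: RegimeSpec,
    sl_config: SuperLearnerConfig | None = None,
    est_config: EstimatorConfig | None = None,
) -> NuisanceEstimates:
    """Treatment propensity and monthly remain-on-regime probabilities.

    The propensity is fit once on baseline covariates; each month's
    probability of staying adherent and uncensored is fit on that month's
    at-risk rows within the regime arm.  Cumulative products are truncated
    below at the configured floor.
    """
    sl = sl_config or SuperLearnerConfig()
    est = est_config or EstimatorConfig()
    data = panel if isinstance(panel, PanelData) else PanelData.from_panel(panel, est)
    n, T = data.n, data.horizon
    in_arm = data.drug == regime.drug

    tx_fit = fit_super_learner(data.X_base, in_arm.astype(float), sl.library,
                               sl.folds, _sl_seed(sl, 0))
    g_treat = predict_ensemble(tx_fit, data.X_base, sl.clip)

    cumulative = np.full((n, T), np.nan)
    g_month: list[np.ndarray] = []
    running = g_treat.copy()
    for t in range(1, T + 1):
        rows = data.month_rows[t - 1]
        arm_rows = in_arm[rows["idx"]]
        if not np.any(arm_rows):
            raise PositivityError(f"no at-risk rows at month {t} for {regime.drug}")
        uncens = 1.0 - rows["C"][arm_rows]
        if np.all(uncens == uncens[0]):
            g_t = np.full(arm_rows.sum(), max(float(np.mean(uncens)), sl.clip))
        else:
            fit = fit_super_learner(rows["X"][arm_rows], uncens, sl.library,
                                    sl.folds, _sl_seed(sl, t))
            g_t = predict_ensemble(fit, rows["X"][arm_rows], sl.clip)
        g_month.append(g_t)
        idx_arm = rows["idx"][arm_rows]
        running_t = running[idx_arm] * g_t
        running[idx_arm] = running_t
        cumulative[idx_arm, t - 1] = np.maximum(running_t, est.g_floor)
    return NuisanceEstimates(regime.drug, g_treat, g_month, cumulative, est.g_floor)


# ---------------------------------------------------------------------------
# targeting


def _fluctuate(m: np.ndarray, v: np.ndarray, w: np.ndarray) -> float:
    """Weighted intercept-only logistic fluctuation on the logit scale."""
    lo = logit(np.clip(m, 1e-9, 1 - 1e-9))

    def score(eps: float) -> float:
        return float(np.sum(w * (v - expit(lo + eps))))

    s0 = score(0.0)
    if abs(s0) < 1e-12:
        return 0.0
    a, b = -1.0, 1.0
    for _ in range(40):
        if score(a) * score(b) <= 0:
            break
        a *= 2.0
        b *= 2.0
    else:
        return 0.0
    return float(brentq(score, a, b, xtol=1e-12))


def _regress(X: np.ndarray, y: np.ndarray, sl: SuperLearnerConfig, seed: int):
    """Fit one sequential regression; constant targets short-circuit."""
    if np.all(y == y[0]):
        c = float(y[0])
        return ("const", c)
    fit = fit_super_learner(X, y, sl.library, sl.folds, seed)
    return ("fit", fit)


def _predict(model, X: np.ndarray, clip: float) -> np.ndarray:
    kind, obj = model
    if kind == "const":
        return np.full(X.shape[0], np.clip(obj, clip, 1 - clip))
    return predict_ensemble(obj, X, clip)


def tmle_risk(
    panel: pd.DataFrame | PanelData,
    regime: RegimeSpec,
    month: int,
    sl_config: SuperLearnerConfig | None = None,
    est_config: EstimatorConfig | None = None,
    nuisances: NuisanceEstimates | None = None,
) -> RiskEstimate:
    """Targeted estimate of cumulative risk by `month` under the regime.

    Sequential regressions run backward from the target month; each is
    fluctuated with the inverse-probability clever covariate before feeding
    the next step.  The point estimate is the mean of the targeted first-step
    regression over all subjects' baseline information.
    """
    sl = sl_config or SuperLearnerConfig()
    est = est_config or EstimatorConfig()
    data = panel if isinstance(panel, PanelData) else PanelData.from_panel(panel, est)
    if not 1 <= month <= data.horizon:
        raise ValueError(f"month must be within 1..{data.horizon}")
    nuis = nuisances or fit_nuisances(data, regime, sl, est)
    n = data.n
    in_arm = data.drug == regime.drug

    # degenerate world: no events at all by the target month in the regime arm
    any_event = any(
        np.nansum(data.month_rows[t - 1]["Y"][in_arm[data.month_rows[t - 1]["idx"]]]) > 0
        for t in range(1, month + 1)
    )
    if not any_event:
        return RiskEstimate(month, regime.drug, 0.0, 0.0, 0.0, 0.0,
                            influence=np.zeros(n))

    if_sum = np.zeros(n)
    m_next: Optional[np.ndarray] = None  # per-person targeted m_{t+1}
    low_g = 0
    followers_tau = 0
    for t in range(month, 0, -1):
        rows = data.month_rows[t - 1]
        idx, X, C, Y = rows["idx"], rows["X"], rows["C"], rows["Y"]
        arm = in_arm[idx]
        reg = arm & (C == 0)
        if not np.any(reg):
            raise PositivityError(f"no uncensored regime rows at month {t}")
        if t == month:
            v = Y[reg]
            followers_tau = int(reg.sum())
        else:
            carried = np.where(Y[reg] == 1.0, 1.0, m_next[idx[reg]])
            v = carried
        model = _regress(X[reg], v, sl, _sl_seed(sl, month, t))
        m_hat = _predict(model, X[reg], sl.clip)
        G = nuis.cumulative[idx[reg], t - 1]
        if t == month:
            low_g = int(np.sum(G <= nuis.floor + 1e-12))
        w = 1.0 / G
        eps = _fluctuate(m_hat, v, w)
        m_star = expit(logit(np.clip(m_hat, 1e-9, 1 - 1e-9)) + eps)
        if_sum[idx[reg]] += w * (v - m_star)
        # evaluate the targeted regression on every row at month t (the
        # step-(t-1) survivors include persons censored at t)
        m_all = expit(logit(np.clip(_predict(model, X, sl.clip),
                                    1e-9, 1 - 1e-9)) + eps)
        m_next = np.full(n, np.nan)
        m_next[idx] = m_all
        if t == 1:
            m1 = m_all  # month-1 rows exist for every person
            psi = float(np.mean(m1))
            influence = if_sum + m1 - psi
    if followers_tau and low_g / max(followers_tau, 1) > 0.05:
        warnings.warn(
            f"cumulative g truncated at the floor for more than 5% of "
            f"regime-followers at month {month}", RuntimeWarning)
    se = float(np.std(influence, ddof=1) / np.sqrt(n))
    lo = min(max(psi - Z95 * se, 0.0), 1.0)
    hi = min(max(psi + Z95 * se, 0.0), 1.0)
    return RiskEstimate(month, regime.drug, psi, se, lo, hi, influence=influence)


# ---------------------------------------------------------------------------
# curves, RMST, contrasts


def estimate_risk_curve(
    panel: pd.DataFrame | PanelData,
    drug: str,
    sl_config: SuperLearnerConfig | None = None,
    est_config: EstimatorConfig | None = None,
    months: Optional[Sequence[int]] = None,
) -> list[RiskEstimate]:
    """Monthly targeted risks for one drug, sharing a single nuisance fit."""
    sl = sl_config or SuperLearnerConfig()
    est = est_config or EstimatorConfig()
    data = panel if isinstance(panel, PanelData) else PanelData.from_panel(panel, est)
    regime = RegimeSpec(drug)
    nuis = fit_nuisances(data, regime, sl, est)
    months = list(months) if months is not None else list(range(1, data.horizon + 1))
    return [tmle_risk(data, regime, t, sl, est, nuis) for t in months]


def survival_curve(risks: list[RiskEstimate]) -> SurvivalCurve:
    """Survival from monthly risks with an isotonic (PAVA) projection.

    The projection enforces a nondecreasing cumulative risk; monotone input
    passes through unchanged.
    """
    if not risks:
        raise ValueError("no risk estimates supplied")
    risks = sorted(risks, key=lambda r: r.month)
    months = np.array([r.month for r in risks])
    if list(months) != list(range(int(months[0]), int(months[-1]) + 1)):
        raise ValueError("risk estimates must cover consecutive months")
    raw = np.array([r.risk for r in risks])
    iso = _pava_nondecreasing(raw)
    se = np.array([r.se for r in risks])
    influ = None
    if all(r.influence is not None for r in risks):
        influ = np.column_stack([r.influence for r in risks])
    return SurvivalCurve(
        drug=risks[0].drug, months=months, risk=iso, survival=1.0 - iso,
        se=se, influence=influ,
    )


def _pava_nondecreasing(y: np.ndarray) -> np.ndarray:
    """Pooled adjacent violators for a nondecreasing sequence (unit weights)."""
    vals: list[float] = []
    wts: list[float] = []
    for v in y:
        vals.append(float(v))
        wts.append(1.0)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2 = vals.pop(), wts.pop()
            v1, w1 = vals.pop(), wts.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
    out = np.empty(len(y))
    i = 0
    for v, w in zip(vals, wts):
        out[i:i + int(w)] = v
        i += int(w)
    return out


def rmst(curve: SurvivalCurve, horizon: int = 24) -> SingleRMST:
    """Diabetes-free months over the horizon: the sum of monthly survival."""
    if len(curve.months) != horizon or curve.months[0] != 1:
        raise ValueError(
            f"curve covers months {curve.months[0]}..{curve.months[-1]}, "
            f"expected 1..{horizon}")
    value = float(np.sum(curve.survival))
    if curve.influence is not None:
        per_person = -curve.influence.sum(axis=1)
        se = float(np.std(per_person, ddof=1) / np.sqrt(len(per_person)))
    else:
        se = float(np.sqrt(np.sum(curve.se ** 2)))
    return SingleRMST(curve.drug, value, se, value - Z95 * se, value + Z95 * se)


def rmst_difference(curve_olz: SurvivalCurve, curve_ari: SurvivalCurve,
                    horizon: int = 24) -> RMSTEstimate:
    """RMST per drug and the olanzapine-minus-aripiprazole difference."""
    r_olz = rmst(curve_olz, horizon)
    r_ari = rmst(curve_ari, horizon)
    diff = r_olz.rmst - r_ari.rmst
    if curve_olz.influence is not None and curve_ari.influence is not None:
        per = (-curve_olz.influence.sum(axis=1)) - (-curve_ari.influence.sum(axis=1))
        se = float(np.std(per, ddof=1) / np.sqrt(len(per)))
    else:
        se = float(np.sqrt(r_olz.se ** 2 + r_ari.se ** 2))
    return RMSTEstimate(
        per_drug={OLANZAPINE: r_olz, ARIPIPRAZOLE: r_ari},
        difference=diff, diff_se=se,
        diff_lo=diff - Z95 * se, diff_hi=diff + Z95 * se,
    )


def contrast(risk_olz: RiskEstimate, risk_ari: RiskEstimate) -> ContrastEstimate:
    """Risk difference (percentage points) and risk ratio with 95% CIs.

    CIs use the per-arm influence functions when available (delta method on
    the log scale for the ratio); otherwise the arm standard errors are
    combined as if independent.
    """
    if risk_olz.month != risk_ari.month:
        raise ValueError("contrast requires the same month in both arms")
    po, pa = risk_olz.risk, risk_ari.risk
    rd = po - pa
    have_if = risk_olz.influence is not None and risk_ari.influence is not None
    if have_if:
        d = risk_olz.influence - risk_ari.influence
        rd_se = float(np.std(d, ddof=1) / np.sqrt(len(d)))
    else:
        rd_se = float(np.sqrt(risk_olz.se ** 2 + risk_ari.se ** 2))
    rd_lo, rd_hi = rd - Z95 * rd_se, rd + Z95 * rd_se

    rr = rr_lo = rr_hi = None
    if pa > 0:
        rr = po / pa
        if po > 0:
            if have_if:
                dlog = risk_olz.influence / po - risk_ari.influence / pa
                se_log = float(np.std(dlog, ddof=1) / np.sqrt(len(dlog)))
            else:
                se_log = float(np.sqrt((risk_olz.se / po) ** 2
                                       + (risk_ari.se / pa) ** 2))
            rr_lo = rr * np.exp(-Z95 * se_log)
            rr_hi = rr * np.exp(Z95 * se_log)
    return ContrastEstimate(
        month=risk_olz.month,
        rd_pp=100.0 * rd, rd_lo=100.0 * rd_lo, rd_hi=100.0 * rd_hi,
        rr=rr, rr_lo=rr_lo, rr_hi=rr_hi,
    )


def estimate_all(
    panel: pd.DataFrame,
    sl_config: SuperLearnerConfig | None = None,
    est_config: EstimatorConfig | None = None,
) -> dict:
    """Both arms end to end: risk curves, RMST summary and monthly contrasts."""
    est = est_config or EstimatorConfig()
    data = PanelData.from_panel(panel, est)
    risks = {d: estimate_risk_curve(data, d, sl_config, est) for d in DRUGS}
    curves = {d: survival_curve(risks[d]) for d in DRUGS}
    rm = rmst_difference(curves[OLANZAPINE], curves[ARIPIPRAZOLE], data.horizon)
    contrasts = [contrast(o, a) for o, a in
                 zip(risks[OLANZAPINE], risks[ARIPIPRAZOLE])]
    return {"risks": risks, "curves": curves, "rmst": rm, "contrasts": contrasts}
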