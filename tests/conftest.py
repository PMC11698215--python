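"""Shared fixtures: small configurations, hand-built panels and an
independent two-period g-computation oracle used to check the targeted
estimator on fully enumerable worlds."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sgarisk import DGPConfig, EstimatorConfig, SuperLearnerConfig
from sgarisk.simulate import PANEL_COLUMNS


@pytest.fixture
def small_dgp() -> DGPConfig:
    return DGPConfig(n_subjects=300, seed=3)


@pytest.fixture
def logistic_sl() -> SuperLearnerConfig:
    return SuperLearnerConfig(library=["logistic"], seed=5)


def make_panel(rows: list[dict]) -> pd.DataFrame:
    """Panel frame from sparse row dicts, filling uninteresting columns."""
    defaults = {
        "drug": "aripiprazole", "dx": "schizophrenia", "age": 40, "older": 0,
        "female": 0, "nonwhite": 0, "state": 0, "index_year": 2010,
        "pre_rx_days": 0, "comorb0": 0, "comorb": 0, "acute": 0, "tested": 0,
        "vacc": 0, "A": 1, "C": 0, "cause": "", "Y": 0.0,
    }
    out = [{**defaults, **r} for r in rows]
    return pd.DataFrame(out)[PANEL_COLUMNS]


# ---------------------------------------------------------------------------
# two-period binary-confounder world with saturated-stratum oracle


TWO_PERIOD_PARAMS = {
    # P(W=1), P(A=olz | W), censoring and outcome probabilities by stratum
    "p_w": 0.45,
    "p_olz": {0: 0.35, 1: 0.65},
    "p_c1": {(0, "aripiprazole"): 0.10, (1, "aripiprazole"): 0.20,
             (0, "olanzapine"): 0.15, (1, "olanzapine"): 0.10},
    "q1": {(0, "aripiprazole"): 0.12, (1, "aripiprazole"): 0.30,
           (0, "olanzapine"): 0.08, (1, "olanzapine"): 0.22},
    "p_l2": {(0, "aripiprazole"): 0.30, (1, "aripiprazole"): 0.60,
             (0, "olanzapine"): 0.25, (1, "olanzapine"): 0.55},
    "p_c2": {0: 0.10, 1: 0.25},          # depends on L2
    "q2": {(0, 0): 0.10, (0, 1): 0.25, (1, 0): 0.20, (1, 1): 0.40},  # (W, L2)
}


def simulate_two_period(n: int, seed: int) -> pd.DataFrame:
    """Observed data from the two-period world, in panel layout.

    W is carried in the `comorb0` column and the time-varying confounder in
    `comorb` (equal to W at month 1, to L2 at month 2).
    """
    p = TWO_PERIOD_PARAMS
    rng = np.random.default_rng(seed)
    w = (rng.random(n) < p["p_w"]).astype(int)
    olz = rng.random(n) < np.vectorize(p["p_olz"].get)(w)
    drug = np.where(olz, "olanzapine", "aripiprazole")
    c1 = rng.random(n) < np.array([p["p_c1"][(wi, d)] for wi, d in zip(w, drug)])
    y1 = rng.random(n) < np.array([p["q1"][(wi, d)] for wi, d in zip(w, drug)])
    l2 = rng.random(n) < np.array([p["p_l2"][(wi, d)] for wi, d in zip(w, drug)])
    c2 = rng.random(n) < np.vectorize(p["p_c2"].get)(l2.astype(int))
    y2 = rng.random(n) < np.array([p["q2"][(wi, li)]
                                   for wi, li in zip(w, l2.astype(int))])
    rows = []
    for i in range(n):
        pid = f"t{i:05d}"
        base = {"person_id": pid, "drug": drug[i], "comorb0": int(w[i])}
        rows.append({**base, "month": 1, "comorb": int(w[i]),
                     "C": int(c1[i]),
                     "cause": "coverage_loss" if c1[i] else "",
                     "Y": np.nan if c1[i] else float(y1[i])})
        if not c1[i] and not y1[i]:
            rows.append({**base, "month": 2, "comorb": int(l2[i]),
                         "C": int(c2[i]),
                         "cause": "coverage_loss" if c2[i] else "",
                         "Y": np.nan if c2[i] else float(y2[i])})
    return make_panel(rows)


def g_formula_two_period(panel: pd.DataFrame, drug: str) -> float:
    """Empirical iterated-expectation g-formula by exhaustive stratification.

    Independent of the estimator: plain stratum means over (W, L2), averaged
    over the empirical baseline distribution.
    """
    df = panel.copy()
    m1_rows = df[df["month"] == 1].set_index("person_id")
    m2_rows = df[df["month"] == 2].set_index("person_id")

    # step 2: E[Y2 | W, L2] among arm, uncensored at both months, no event
    m2 = {}
    sel2 = m2_rows[(m2_rows["drug"] == drug) & (m2_rows["C"] == 0)]
    for (wv, lv), grp in sel2.groupby([m1_rows.loc[sel2.index, "comorb0"],
                                       sel2["comorb"]]):
        m2[(wv, lv)] = grp["Y"].mean()

    # step 1: E[Y1 + (1-Y1) m2(W, L2) | W] among arm, uncensored at month 1
    sel1 = m1_rows[(m1_rows["drug"] == drug) & (m1_rows["C"] == 0)]
    m1 = {}
    for wv, grp in sel1.groupby("comorb0"):
        vals = []
        for pid, row in grp.iterrows():
            if row["Y"] == 1.0:
                vals.append(1.0)
            else:
                l2v = int(m2_rows.loc[pid, "comorb"])
                vals.append(m2[(wv, l2v)])
        m1[wv] = float(np.mean(vals))

    w_all = m1_rows["comorb0"].to_numpy()
    return float(np.mean([m1[wv] for wv in w_all]))


@pytest.fixture
def two_period_estimator_config() -> EstimatorConfig:
    return EstimatorConfig(horizon=2, baseline_features=["comorb0"],
                           timevarying_features=["comorb"], g_floor=1e-4)
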