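"""Targeted estimator: plug-in identities, the enumerable-world oracle,
survival/RMST summaries and contrasts."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sgarisk import (
    ARIPIPRAZOLE,
    DGPConfig,
    DRUGS,
    OLANZAPINE,
    EstimatorConfig,
    PositivityError,
    RegimeSpec,
    RiskEstimate,
    SuperLearnerConfig,
    contrast,
    fit_nuisances,
    generate_panel,
    rmst,
    rmst_difference,
    survival_curve,
    tmle_risk,
)
from sgarisk.simulate import compute_truth
from sgarisk.tmle import SurvivalCurve, _pava_nondecreasing

from conftest import (
    g_formula_two_period,
    make_panel,
    simulate_two_period,
)

SAT = SuperLearnerConfig(library=["saturated"])


class TestNuisances:
    def test_single_month_mean_learner_recovers_empirical_adherence(self):
        rows = []
        for i in range(40):
            drug = ARIPIPRAZOLE if i % 2 else OLANZAPINE
            c = 1 if (drug == ARIPIPRAZOLE and i % 5 == 0) else 0
            rows.append({"person_id": f"p{i:03d}", "month": 1, "drug": drug,
                         "C": c, "Y": np.nan if c else 0.0})
        panel = make_panel(rows)
        nuis = fit_nuisances(panel, RegimeSpec(ARIPIPRAZOLE),
                             SuperLearnerConfig(library=["mean"]))
        # 4 of 20 aripiprazole rows censored
        assert np.allclose(nuis.g_month[0], 16 / 20)

    def test_fully_followed_panel_gives_cumulative_g_equal_to_propensity(self):
        rows = []
        for i in range(30):
            drug = ARIPIPRAZOLE if i < 18 else OLANZAPINE
            for t in (1, 2, 3):
                rows.append({"person_id": f"p{i:03d}", "month": t,
                             "drug": drug, "Y": 0.0})
        panel = make_panel(rows)
        nuis = fit_nuisances(panel, RegimeSpec(ARIPIPRAZOLE),
                             SuperLearnerConfig(library=["mean"]))
        idx = np.arange(18)
        for t in range(3):
            assert np.allclose(nuis.cumulative[idx, t], 18 / 30)

    def test_missing_month_raises_positivity_error(self):
        rows = [{"person_id": "p1", "month": 1, "drug": ARIPIPRAZOLE, "Y": 0.0},
                {"person_id": "p1", "month": 2, "drug": ARIPIPRAZOLE, "Y": 0.0},
                {"person_id": "p2", "month": 1, "drug": OLANZAPINE, "Y": 0.0},
                {"person_id": "p2", "month": 2, "drug": OLANZAPINE, "Y": 0.0}]
        panel = make_panel(rows)
        with pytest.raises(PositivityError, match="month 2"):
            fit_nuisances(panel.drop(panel.index[1]), RegimeSpec(ARIPIPRAZOLE),
                          SuperLearnerConfig(library=["mean"]))


class TestTargetedRisk:
    def test_plug_in_identity_without_confounding(self):
        # one month, homogeneous covariates, no censoring: the estimate is the
        # empirical event proportion in the regime arm, to numerical precision
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            drug = ARIPIPRAZOLE if i < 120 else OLANZAPINE
            y = float(rng.random() < (0.25 if drug == ARIPIPRAZOLE else 0.10))
            rows.append({"person_id": f"p{i:03d}", "month": 1, "drug": drug,
                         "Y": y})
        panel = make_panel(rows)
        est = tmle_risk(panel, RegimeSpec(ARIPIPRAZOLE), 1, SAT)
        ari = panel[panel["drug"] == ARIPIPRAZOLE]
        assert est.risk == pytest.approx(float(ari["Y"].mean()), abs=1e-10)

    def test_zero_events_give_zero_risk_with_degenerate_se(self):
        rows = [{"person_id": f"p{i}", "month": t, "drug": ARIPIPRAZOLE,
                 "Y": 0.0} for i in range(25) for t in (1, 2)]
        panel = make_panel(rows)
        est = tmle_risk(panel, RegimeSpec(ARIPIPRAZOLE), 2, SAT)
        assert est.risk == 0.0 and est.se == 0.0

    @pytest.mark.parametrize("drug", DRUGS)
    def test_saturated_tmle_equals_g_formula_in_two_period_world(
            self, drug, two_period_estimator_config):
        panel = simulate_two_period(n=900, seed=4)
        est = tmle_risk(panel, RegimeSpec(drug), 2, SAT,
                        two_period_estimator_config)
        oracle = g_formula_two_period(panel, drug)
        assert est.risk == pytest.approx(oracle, abs=1e-6)

    def test_double_robustness_to_misspecified_outcome_regressions(self):
        # mean-only outcome regressions with correctly specified adherence and
        # treatment models still give nearly unbiased month-24 risk
        truth = compute_truth(DGPConfig(n_subjects=10))
        errors = {d: [] for d in DRUGS}
        for seed in (21, 22):
            cfg = DGPConfig(n_subjects=5000, seed=seed)
            panel, _ = generate_panel(cfg)
            from sgarisk.tmle import PanelData
            data = PanelData.from_panel(panel, EstimatorConfig())
            for d in DRUGS:
                nuis = fit_nuisances(data, RegimeSpec(d),
                                     SuperLearnerConfig(library=["logistic"]))
                est = tmle_risk(data, RegimeSpec(d), 24,
                                SuperLearnerConfig(library=["mean"]),
                                nuisances=nuis)
                errors[d].append(est.risk - truth.risks[d][-1])
        for d in DRUGS:
            assert abs(float(np.mean(errors[d]))) < 0.015


class TestCurvesAndSummaries:
    def _curve(self, drug, risks, ses=None):
        risks = np.asarray(risks, dtype=float)
        ses = np.zeros_like(risks) if ses is None else np.asarray(ses)
        ests = [RiskEstimate(t + 1, drug, r, s, r, r)
                for t, (r, s) in enumerate(zip(risks, ses))]
        return survival_curve(ests)

    def test_zero_risk_curve_has_unit_survival_and_rmst_24(self):
        c = self._curve(ARIPIPRAZOLE, np.zeros(24))
        assert np.all(c.survival == 1.0)
        assert rmst(c, 24).rmst == pytest.approx(24.0)

    def test_half_survival_gives_rmst_12(self):
        c = self._curve(ARIPIPRAZOLE, np.full(24, 0.5))
        assert rmst(c, 24).rmst == pytest.approx(12.0)

    def test_pava_pools_adjacent_violators(self):
        # risks (0.02, 0.01) pool to 0.015 at both months
        out = _pava_nondecreasing(np.array([0.02, 0.01]))
        assert np.allclose(out, [0.015, 0.015])

    def test_monotone_input_is_unchanged(self):
        risks = np.linspace(0.001, 0.06, 24)
        c = self._curve(OLANZAPINE, risks)
        assert np.allclose(c.risk, risks)

    def test_missing_months_raise(self):
        ests = [RiskEstimate(1, ARIPIPRAZOLE, 0.01, 0.0, 0.01, 0.01),
                RiskEstimate(3, ARIPIPRAZOLE, 0.02, 0.0, 0.02, 0.02)]
        with pytest.raises(ValueError):
            survival_curve(ests)

    def test_rmst_difference_equals_difference_of_rmsts_exactly(self):
        co = self._curve(OLANZAPINE, np.linspace(0.002, 0.05, 24))
        ca = self._curve(ARIPIPRAZOLE, np.linspace(0.003, 0.065, 24))
        rm = rmst_difference(co, ca, 24)
        assert rm.difference == rm.per_drug[OLANZAPINE].rmst - \
            rm.per_drug[ARIPIPRAZOLE].rmst

    def test_horizon_mismatch_raises(self):
        c = self._curve(ARIPIPRAZOLE, np.zeros(12))
        with pytest.raises(ValueError):
            rmst(c, 24)


class TestContrast:
    def test_worked_example_four_versus_two_percent(self):
        o = RiskEstimate(6, OLANZAPINE, 0.04, 0.0, 0.04, 0.04)
        a = RiskEstimate(6, ARIPIPRAZOLE, 0.02, 0.0, 0.02, 0.02)
        c = contrast(o, a)
        assert c.rd_pp == pytest.approx(2.0, abs=1e-12)
        assert c.rr == pytest.approx(2.0, abs=1e-12)

    def test_equal_risks_are_null(self):
        o = RiskEstimate(3, OLANZAPINE, 0.05, 0.0, 0.05, 0.05)
        a = RiskEstimate(3, ARIPIPRAZOLE, 0.05, 0.0, 0.05, 0.05)
        c = contrast(o, a)
        assert c.rd_pp == 0.0 and c.rr == 1.0

    def test_zero_reference_risk_leaves_rr_undefined(self):
        o = RiskEstimate(3, OLANZAPINE, 0.05, 0.0, 0.05, 0.05)
        a = RiskEstimate(3, ARIPIPRAZOLE, 0.0, 0.0, 0.0, 0.0)
        c = contrast(o, a)
        assert c.rr is None and c.rd_pp == pytest.approx(5.0)

    def test_month_mismatch_raises(self):
        o = RiskEstimate(3, OLANZAPINE, 0.05, 0.0, 0.05, 0.05)
        a = RiskEstimate(4, ARIPIPRAZOLE, 0.02, 0.0, 0.02, 0.02)
        with pytest.raises(ValueError):
            contrast(o, a)

    def test_consistency_with_input_risks(self):
        rng = np.random.default_rng(1)
        ifo, ifa = rng.normal(size=300), rng.normal(size=300)
        o = RiskEstimate(9, OLANZAPINE, 0.061, 0.004, 0.05, 0.07, influence=ifo)
        a = RiskEstimate(9, ARIPIPRAZOLE, 0.043, 0.004, 0.03, 0.05, influence=ifa)
        c = contrast(o, a)
        assert c.rd_pp == pytest.approx(100 * (o.risk - a.risk), abs=1e-10)
        assert c.rr == pytest.approx(o.risk / a.risk, abs=1e-10)

    def test_delta_method_ci_agrees_with_bootstrap(self):
        # resampling the influence-function contributions is an independent
        # route to the same sampling distribution
        rng = np.random.default_rng(2)
        n = 400
        ifo = rng.normal(scale=0.8, size=n)
        ifa = rng.normal(scale=0.6, size=n)
        o = RiskEstimate(24, OLANZAPINE, 0.055, 0.0, 0, 0, influence=ifo)
        a = RiskEstimate(24, ARIPIPRAZOLE, 0.065, 0.0, 0, 0, influence=ifa)
        c = contrast(o, a)
        width_delta = c.rd_hi - c.rd_lo
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            boots.append((o.risk - a.risk) + np.mean(ifo[idx] - ifa[idx]))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        width_boot = 100 * (hi - lo)
        assert width_delta == pytest.approx(width_boot, rel=0.10)
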