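"""Targeted estimation of counterfactual monthly diabetes risk.

Simulates a cohort, runs the longitudinal TMLE for both drugs and prints the
month-24 risks, the risk difference/ratio and the RMST summary next to the
generator's exact truth.
"""
from sgarisk import (
    DGPConfig,
    DRUGS,
    SuperLearnerConfig,
    estimate_all,
    generate_panel,
)

config = DGPConfig(n_subjects=2000, seed=11)
panel, truth = generate_panel(config)
sl = SuperLearnerConfig(library=["mean", "logistic"])
result = estimate_all(panel, sl)

for drug in DRUGS:
    est = result["risks"][drug][-1]
    print(f"{drug:>13}: psi(24) = {100 * est.risk:.2f}% "
          f"(95% CI {100 * est.lo:.2f}, {100 * est.hi:.2f}) | "
          f"truth {100 * truth.risks[drug][-1]:.2f}%")
c = result["contrasts"][-1]
print(f"month-24 risk difference: {c.rd_pp:+.2f} pp "
      f"(95% CI {c.rd_lo:+.2f}, {c.rd_hi:+.2f})")
print(f"month-24 risk ratio:      {c.rr:.2f} "
      f"(95% CI {c.rr_lo:.2f}, {c.rr_hi:.2f})")
rm = result["rmst"]
print(f"RMST difference: {rm.difference:+.3f} months "
      f"(95% CI {rm.diff_lo:+.3f}, {rm.diff_hi:+.3f}) | "
      f"truth {truth.rmst_difference:+.3f}")
print("An interval excluding 0 (or 1 for the ratio) indicates a detected "
      "difference in diabetes risk between the two drugs.")
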