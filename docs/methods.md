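# Methods

## The estimand and the design

The package estimates, per index drug *a* ∈ {aripiprazole, olanzapine} and
study month *t* = 1…24, the counterfactual cumulative incidence of type 2
diabetes ψ_a(t) had every cohort member initiated drug *a* and remained on
continuous monotherapy, uncensored, through month *t*. Months are
consecutive 30-day windows anchored at the index fill; all day windows are
half-open `[start, end)`. Summaries are the survival curve S_a(t) = 1 −
ψ_a(t), the restricted mean survival time RMST_a = Σ_{t≤24} S_a(t)
(diabetes-free months), and monthly contrasts RD_t (percentage points,
olanzapine minus aripiprazole) and RR_t.

The cohort follows an active-comparator new-user design. An index episode
is the first index-drug fill with (a) no other antipsychotic fill in the 180
days before it and (b) at most 30 days supplied of the index drug in any
90-day window inside that pre-period. A fill whose 180-day pre-period
extends before the start of the claims window is not evaluable and cannot
index: this is what lets a cohort member carry limited *pre-period
index-drug exposure* (their earlier use sits behind an unobservable or
disqualified stretch) while still counting as a relatively new user. When
no fill qualifies, the exclusion reason recorded is the failure of the last
candidate examined, which keeps one reason per excluded person.

Eligibility then requires, in fixed order: continuous enrolment over
[−180, +180) days around index; no pre-period diabetes/cardiometabolic
diagnosis; no pre-period polycystic ovarian syndrome; age 18–64 at index.
Follow-up ends at the earliest of seven censoring causes with same-month
ties broken by the hierarchy death ≻ study end ≻ turning 65 ≻ coverage loss
≻ discontinuation ≻ augmentation ≻ switch, or at the diabetes event.
Within a month, censoring precedes the outcome: an event ascertained in the
censoring month is not counted.

Exposure is medication availability: a month is covered when any index-drug
supply interval intersects it, with carryover of unused supply capped at a
30-day stockpile and a configurable grace period (default 0). The first
other-antipsychotic fill ends monotherapy in its month — as augmentation
when index supply continues past the fill day, otherwise as a switch; a
supply gap without another antipsychotic is a discontinuation. Because the
index fill itself covers month 1, monotherapy can end no earlier than
month 2.

## The estimator

Risks are estimated by longitudinal targeted minimum loss-based estimation
in its iterated-conditional-expectation (sequential-regression) form, one
target month at a time within a single nuisance fit. Nodes are ordered
(W, A₀) then, per month, (L_t, C_t, Y_t): covariates update, censoring is
decided given the updated covariates, the outcome follows among the
uncensored. The panel therefore records the censoring-month row with its
covariates and a missing outcome, which makes every sequential regression's
target observable for everyone in its regression set and keeps coarsening
at random aligned with the fitted models.

For target month τ, regressions run backward s = τ…1 on at-risk, uncensored
regime rows: the step-s target is Y_s for events and the (already targeted)
step-(s+1) prediction otherwise. Each step is fluctuated by a weighted
intercept-only logistic submodel with weights 1/Ĝ_s, where Ĝ_s is the
product of the treatment propensity ĝ_A(W) and the monthly probabilities
ĝ_r of remaining adherent and uncensored, truncated below at 0.005
(configurable). ψ̂_a(τ) is the mean of the targeted first-step regression
over all subjects. Standard errors come from the estimated efficient
influence function; RMST and contrast intervals retain the full cross-month
and cross-arm influence-function covariance. Month-1 risk is estimated with
the same machinery from baseline information so the RMST genuinely spans
months 1–24, although reports emphasise months 2–24 where confounding
adjustment is nontrivial. Monthly risk curves are projected to monotone by
pooled adjacent violators before survival and RMST are formed; the raw
estimates and their intervals are kept alongside.

Numerical choices: the fluctuation solves a one-dimensional monotone score
equation by bracketed root finding (tolerance 1e−12, expanding bracket); a
regression whose targets are constant short-circuits to that constant; a
panel with zero events by the target month returns risk 0 with a degenerate
standard error; predictions are clipped to [1e−6, 1−1e−6]; when more than
5% of regime-followers at the target month sit at the truncation floor a
positivity warning names the month.

## The Super Learner

All nuisance regressions go through a cross-validated convex ensemble over
a fixed library — mean, ordinary least squares, logistic (IRLS with a 1e−8
ridge), CART (minimum leaf 20), random forest (500 trees) and a one-hidden-
layer 8-unit neural network — plus a saturated stratum-mean learner used
for exact-oracle testing. Learners are regressions onto [0, 1] because
iterated-expectation targets are fractional; the loss is the negative
Bernoulli (quasi-binomial) log-likelihood. Weights minimise cross-validated
loss over the probability simplex via SLSQP started at the best single
learner, so the ensemble can never be worse than the best library member
(the simplex contains its vertices); 2-fold cross-validation is the
default. A learner that fails to fit is weighted zero with a logged
warning. Because the simplex optimum is located numerically, reordering the
library reproduces predictions to about 1e−6 rather than machine precision.
The pipeline's default nuisance library is {mean, logistic}; replicate
studies in the test suite use {logistic} alone. Both choices keep the
desk-scale studies (hundreds of sequential regressions per replicate)
tractable while remaining correctly specified for the synthetic world,
whose hazards are logistic in the same features; the full six-learner
library is supported and exercised in the ensemble tests.

## The synthetic world and its truth

The generator emulates the statistical structure the analysis assumes, not
real billing data: symbolic code groups instead of ICD-9/NDC vocabularies,
a six-year calendar of 30-day months, and a small finite time-varying state
— an absorbing chronic-comorbidity flag (monthly onset ≈0.4%, doubled past
age 45), an episodic acute-care flag (6%, +10 points with comorbidity) and
a metabolic-testing indicator (7% per month). Baseline covariates (diagnosis
mix 52/24/24% schizophrenia/bipolar/severe depression, age 18–64, sex,
race group, state, pre-period index-drug days in 76% of subjects) drive
treatment assignment; the monthly diabetes hazard is logistic in drug,
month, diagnosis, age group, sex and the time-varying flags. Censoring
mixes stochastic causes (death 0.15%/month, coverage loss 0.6%/month from
month 7, when post-index enrolment is no longer guaranteed; a
covariate-dependent monotherapy-stop model ≈4–5%/month split 70/15/15 into
discontinuation/augmentation/switch) with two deterministic ones — study
end from the index date and the calendar boundary, turning 65 from the birth
date — because those causes are calendar/age driven in reality and must be
re-derivable by the cohort builder from demographics and enrolment alone.
Under the default configuration roughly a quarter of subjects complete 24
months.

Outcome-hazard coefficients were calibrated once so the 24-month
counterfactual risks fall in the published 5–9% range for this comparison
(olanzapine ≈5.5/6.4/8.5% across the three diagnosis strata, aripiprazole
≈0.2 log-odds higher, RMST difference ≈ +0.14 months); the within-period
hazard shape (a mild upward trend) is the package's own choice. The default
effect direction favours olanzapine, and `DGPConfig.null_effect()` gives the
sharp-null world used for coverage testing. The vaccination
(negative-control) hazard is drug-independent by default — a clean null —
and configurable for misspecification studies.

Because the state space is finite, ψ_a(t) is computed exactly by a forward
recursion over (baseline cell) × (comorbidity state), marginalising the
episodic flags each month and tilting the survivor distribution; `TruthReport`
carries these exact curves, the RMSTs and their contrasts. The claims
encoder writes fills, diagnosis claims, enrolment spans, procedures and
demographics that the cohort builder provably inverts: the round trip is
exact on distractor-free configurations and ≥99% of person-months with
distractors present. Two artificialities are accepted for that
invertibility: covariate-marker claims are also emitted in the censoring
month (even for coverage loss), and monotherapy-stop causes are drawn from
a single adherence model rather than three free per-cause hazards.

## What passing tests do and do not show

Tests validate the estimator against worlds whose truth is known exactly:
bias of ψ̂(24) below one percentage point and 88–99% interval coverage at
n = 2 000 over 100 replicates, null preservation, double robustness to
mean-only outcome regressions, and exact agreement with a brute-force
g-formula on an enumerable two-period world. They do not show that real
claims data satisfy the assumptions the synthetic world builds in by
construction — no unmeasured confounding given the recorded covariates,
coarsening at random for all seven censoring causes, correct code-group
mappings, and hazards that are smooth in a handful of flags. The
replicate-study sample size (n = 2 000) is an order of magnitude below the
published cohort it mimics, so real-data confidence intervals would be
correspondingly narrower.

## Open design choices taken

- Outcome rule "one out-patient code plus an oral antidiabetic fill"
  accepts a fill anywhere post-index and dates the event at the out-patient
  claim; the two-out-patient rule dates at the first of the pair.
- Monthly per-arm targeting within one nuisance fit (rather than one joint
  longitudinal fluctuation across all months).
- RMST intervals use the full influence-function covariance across months;
  ignoring it would understate the variance.
- E-values are computed on monthly risk ratios only; RMST-scale E-values
  are not supported.
- The negative-control reanalysis treats a diabetes event month without
  vaccination as censoring for the vaccination outcome (diabetes ends
  observation in the source panel); with ≈6% cumulative incidence this
  affects few person-months.
- Subgroup re-estimation (ages 18–45, no pre-period index-drug supply)
  reruns the full estimator on the restricted panel; nothing is pooled.
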