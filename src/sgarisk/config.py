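"""Configuration models for the synthetic claims world and the analysis pipeline.

All knobs are plain pydantic models so that YAML round-trips are exact and any
misspelled key is rejected at load time.
"""
from __future__ import annotations

from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

ARIPIPRAZOLE = "aripiprazole"
OLANZAPINE = "olanzapine"
DRUGS = (ARIPIPRAZOLE, OLANZAPINE)

DIAGNOSES = ("schizophrenia", "bipolar", "severe_mdd")

#: Censoring causes in the precedence order used when several coincide.
CENSORING_CAUSES = (
    "death",
    "study_end",
    "age_65",
    "coverage_loss",
    "discontinuation",
    "augmentation",
    "switch",
)

#: Causes that end continuous monotherapy (drawn from the adherence model).
MONOTHERAPY_END_CAUSES = ("discontinuation", "augmentation", "switch")

#: Feature names that coefficient mappings may refer to.  Baseline features are
#: fixed at the index month; the rest vary month to month.
BASELINE_FEATURES = (
    "intercept",
    "dx_bipolar",
    "dx_mdd",
    "older",
    "female",
    "nonwhite",
    "pre_rx_any",
    "comorb0",
)
TIMEVARYING_FEATURES = ("comorb", "acute", "tested", "month_frac", "ari", "olz")
ALL_FEATURES = BASELINE_FEATURES + TIMEVARYING_FEATURES

ELIGIBILITY_REASONS = (
    "other_antipsychotic_pre_period",
    "not_new_user",
    "enrolment_gap",
    "prior_diabetes_or_cardiometabolic",
    "pcos",
    "age_out_of_range",
    "none",
)


class ConfigurationError(ValueError):
    """Raised when a configuration block is structurally invalid."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except ConfigurationError:
            raise
        except ValueError as exc:  # unwrap pydantic's ValidationError
            raise ConfigurationError(str(exc)) from exc


def _check_coefficients(name: str, coeffs: Mapping[str, float]) -> None:
    unknown = set(coeffs) - set(ALL_FEATURES)
    if unknown:
        raise ConfigurationError(
            f"{name}: unknown feature(s) {sorted(unknown)}; "
            f"allowed: {sorted(ALL_FEATURES)}"
        )


class BaselineSpec(_Strict):
    """Distributions of baseline (index-month) characteristics."""

    p_female: float = 0.50
    p_nonwhite: float = 0.33
    n_states: int = 7
    age_min: int = 18
    age_max: int = 64
    p_pre_rx: float = 0.76          # share with some pre-period index-drug supply
    pre_rx_max_days: int = 30       # capped by the relatively-new-user rule
    p_comorb0: float = 0.10         # chronic comorbidity flag at baseline
    p_comorb0_older_add: float = 0.10

    @field_validator("p_female", "p_nonwhite", "p_pre_rx", "p_comorb0",
                     "p_comorb0_older_add")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"probability out of [0, 1]: {v}")
        return v


class CovariateDynamics(_Strict):
    """Markov dynamics of the (small, finite) time-varying covariate state."""

    comorb_onset: float = 0.004           # monthly onset of the chronic flag
    comorb_onset_older_add: float = 0.004
    p_acute: float = 0.06                 # acute-care use, redrawn monthly
    p_acute_comorb_add: float = 0.10

    @field_validator("comorb_onset", "comorb_onset_older_add", "p_acute",
                     "p_acute_comorb_add")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"probability out of [0, 1]: {v}")
        return v


class CensoringSpec(_Strict):
    """Stochastic censoring-process parameters.

    Turning 65 and reaching the end of the study window are deterministic given
    birth date and index date, so only the genuinely random causes carry rates.
    The three monotherapy-ending causes share the adherence hazard model; the
    ``stop_cause_mix`` splits a monotherapy stop into its recorded cause.
    """

    death_rate: float = 0.0015
    coverage_loss_rate: float = 0.006
    coverage_loss_min_month: int = 7  # post-index enrolment is guaranteed 6 months
    stop_cause_mix: dict[str, float] = Field(
        default_factory=lambda: {"discontinuation": 0.70,
                                 "augmentation": 0.15,
                                 "switch": 0.15}
    )

    @field_validator("death_rate", "coverage_loss_rate")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"hazard out of [0, 1]: {v}")
        return v

    @model_validator(mode="after")
    def _mix(self) -> "CensoringSpec":
        if set(self.stop_cause_mix) != set(MONOTHERAPY_END_CAUSES):
            raise ConfigurationError(
                "stop_cause_mix must have exactly the keys "
                f"{MONOTHERAPY_END_CAUSES}"
            )
        total = sum(self.stop_cause_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"stop_cause_mix sums to {total}, not 1")
        return self


class CalendarSpec(_Strict):
    """The simulated calendar: a six-year claims window of 30-day months."""

    window_days: int = 2190
    start_year: int = 2008
    month_days: int = 30
    pre_period_days: int = 180

    @property
    def index_day_min(self) -> int:
        # leave room for the pre-period plus any historic antipsychotic fills
        return self.pre_period_days + 150

    @property
    def index_day_max(self) -> int:
        return self.window_days - self.pre_period_days

    def horizon_fits(self, horizon: int) -> bool:
        """Some index date must allow a complete `horizon`-month follow-up."""
        return self.index_day_min + horizon * self.month_days <= self.window_days


class DGPConfig(_Strict):
    """Generative parameters of the synthetic claims world.

    Coefficient mappings are log-odds weights keyed by feature name; any key
    outside the fixed vocabulary raises :class:`ConfigurationError` naming the
    offending field.
    """

    n_subjects: int = 2000
    horizon: int = 24
    seed: int = 0
    diagnosis_mix: dict[str, float] = Field(
        default_factory=lambda: {"schizophrenia": 0.52,
                                 "bipolar": 0.24,
                                 "severe_mdd": 0.24}
    )
    baseline_covariate_spec: BaselineSpec = Field(default_factory=BaselineSpec)
    covariate_dynamics: CovariateDynamics = Field(default_factory=CovariateDynamics)
    treatment_assignment_coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "intercept": -0.20, "dx_bipolar": 0.10, "dx_mdd": 0.15,
            "older": 0.25, "female": -0.20, "nonwhite": 0.10,
            "pre_rx_any": 0.30, "comorb0": -0.80,
        }
    )
    adherence_hazard_coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "intercept": 3.10, "ari": -0.15, "comorb": -0.50,
            "acute": -0.40, "month_frac": 0.50,
        }
    )
    cause_specific_censoring_rates: CensoringSpec = Field(
        default_factory=CensoringSpec
    )
    outcome_hazard_coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "intercept": -6.55, "ari": 0.18, "month_frac": 0.35,
            "dx_bipolar": 0.15, "dx_mdd": 0.45, "older": 0.35,
            "female": -0.10, "comorb": 0.70, "acute": 0.30,
        }
    )
    vaccination_hazard_coefficients: dict[str, float] = Field(
        default_factory=lambda: {"intercept": -3.90, "olz": 0.0}
    )
    testing_rate: float = 0.07
    calendar: CalendarSpec = Field(default_factory=CalendarSpec)
    #: fraction of extra persons per eligibility-violating distractor type
    distractors: dict[str, float] = Field(default_factory=dict)

    @field_validator("testing_rate")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"testing_rate out of [0, 1]: {v}")
        return v

    @model_validator(mode="after")
    def _validate(self) -> "DGPConfig":
        if self.horizon < 2:
            raise ConfigurationError("horizon must be at least 2 months")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if set(self.diagnosis_mix) != set(DIAGNOSES):
            raise ConfigurationError(
                f"diagnosis_mix must have exactly the keys {DIAGNOSES}"
            )
        for p in self.diagnosis_mix.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("diagnosis_mix probabilities must be in [0, 1]")
        if abs(sum(self.diagnosis_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("diagnosis_mix must sum to 1")
        allowed_distractors = set(ELIGIBILITY_REASONS) - {"none"} | {"insulin_only"}
        unknown = set(self.distractors) - allowed_distractors
        if unknown:
            raise ConfigurationError(
                f"distractors: unknown type(s) {sorted(unknown)}"
            )
        for name in ("treatment_assignment_coefficients",
                     "adherence_hazard_coefficients",
                     "outcome_hazard_coefficients",
                     "vaccination_hazard_coefficients"):
            _check_coefficients(name, getattr(self, name))
        if self.calendar.horizon_fits(self.horizon) is False:
            raise ConfigurationError(
                "horizon longer than the simulated calendar window"
            )
        return self

    def null_effect(self) -> "DGPConfig":
        """A copy with no drug effect on the outcome hazard (sharp null)."""
        cfg = self.model_copy(deep=True)
        cfg.outcome_hazard_coefficients["ari"] = 0.0
        return cfg


class CohortConfig(_Strict):
    """Cohort-construction rules applied by the builder."""

    horizon: int = 24
    month_days: int = 30
    pre_period_days: int = 180
    post_enrolment_days: int = 180
    age_min: int = 18
    age_max: int = 64
    new_user_window_days: int = 90
    new_user_max_days_supplied: int = 30
    grace_days: int = 0          # extra supply slack before discontinuation
    stockpile_cap_days: int = 30  # carryover of unused days supplied
    outpatient_pair_window_days: int = 365


class SuperLearnerConfig(_Strict):
    """Library and cross-validation settings for all nuisance regressions."""

    library: list[str] = Field(default_factory=lambda: ["mean", "logistic"])
    folds: int = 2
    seed: int = 0
    clip: float = 1e-6


class EstimatorConfig(_Strict):
    horizon: int = 24
    g_floor: float = 0.005      # positivity truncation of cumulative probabilities
    baseline_features: list[str] = Field(
        default_factory=lambda: ["dx_bipolar", "dx_mdd", "older", "female",
                                 "nonwhite", "pre_rx_any", "comorb0"]
    )
    timevarying_features: list[str] = Field(
        default_factory=lambda: ["comorb", "acute"]
    )


class SensitivityConfig(_Strict):
    evalues: bool = True
    negative_control: bool = True
    testing_rates: bool = True
    subgroup: bool = True
    subgroup_age_max: int = 45


class RunConfig(_Strict):
    """Everything one end-to-end run needs, fanned out from a master seed."""

    seed: int = 1
    strata: list[str] = Field(default_factory=lambda: list(DIAGNOSES))
    dgp: DGPConfig = Field(default_factory=DGPConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    superlearner: SuperLearnerConfig = Field(default_factory=SuperLearnerConfig)
    estimator: EstimatorConfig = Field(default_factory=EstimatorConfig)
    sensitivity: SensitivityConfig = Field(default_factory=SensitivityConfig)

    @model_validator(mode="after")
    def _strata(self) -> "RunConfig":
        unknown = set(self.strata) - set(DIAGNOSES)
        if unknown:
            raise ConfigurationError(f"unknown strata {sorted(unknown)}")
        return self


def load_run_config(path: str) -> RunConfig:
    """Load a :class:`RunConfig` from YAML, rejecting unknown keys."""
    with open(path) as fh:
        raw: Any = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ConfigurationError:
        raise
    except Exception as exc:  # pydantic ValidationError -> uniform error type
        raise ConfigurationError(str(exc)) from exc


def dump_run_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
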