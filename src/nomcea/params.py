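"""Typed, validated parameter containers for the rectal-cancer cost model.

Every number the model consumes lives in one declarative configuration
document (YAML).  The published point estimates ship as the immutable
default profile (``data/default_params.yaml``); assumed values (visit
schedules, absence durations, co-payment unit counts) are kept in a
separate ``assumptions`` block so that they are auditable.

All containers are pydantic models with ``extra="forbid"``: unknown keys
are rejected, probabilities are range-checked and cumulative risk maps are
checked for monotonicity at load time.
"""

from __future__ import annotations

import enum
from importlib import resources
from typing import Dict, List

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class HealthState(enum.Enum):
    """The six Markov health states; ``DEATH`` is the unique absorbing state."""

    STABLE = "A"
    STABLE_POST_SALVAGE = "B"
    LOCAL_RECURRENCE = "C"
    DISTANT_RECURRENCE = "D"
    LOCAL_AND_DISTANT = "E"
    DEATH = "F"


#: Canonical state ordering used for all vectors and matrices.
STATES: tuple[HealthState, ...] = tuple(HealthState)
STATE_INDEX: Dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}


class Strategy(str, enum.Enum):
    NOM = "NOM"
    RESECTION = "RESECTION"


class Scenario(str, enum.Enum):
    EMPLOYED = "EMPLOYED"
    RETIRED = "RETIRED"
    MIXED = "MIXED"


Probability = Field(ge=0.0, le=1.0)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


def _check_cumulative(name: str, cum: Dict[int, float]) -> Dict[int, float]:
    years = sorted(cum)
    if any(y <= 0 for y in years):
        raise ValueError(f"{name}: horizon years must be positive, got {years}")
    last = -1.0
    for y in years:
        p = cum[y]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}: probability {p} at {y}y outside [0, 1]")
        if p < last:
            raise ValueError(
                f"{name}: cumulative probabilities must be non-decreasing in "
                f"years, got {cum}"
            )
        last = p
    return {int(y): float(cum[y]) for y in years}


class ArmTransitions(_Model):
    """Transition-probability inputs for one treatment arm.

    Cumulative maps carry their time frames as keys (years); single
    probabilities are per event or per cycle as named.
    """

    overall_g3g4_toxicity: float = Probability
    perioperative_death: float = Probability
    local_recurrence_cum: Dict[int, float]
    distant_recurrence_cum: Dict[int, float]
    overall_survival: Dict[int, float]
    distant_given_local: float = Probability
    local_given_distant: float = Probability
    local_recurrence_after_salvage_5y: float = Probability
    distant_after_local_3y: float = Probability
    salvage_local: float = Probability
    salvage_distant: float = Probability
    mort_local_salvaged_5y: float = Probability
    mort_local_unsalvaged_5y: float = Probability
    mort_distant_5y: float = Probability
    mort_local_and_distant_5y: float = Probability
    other_cause_mortality_annual: float = Probability

    @field_validator("local_recurrence_cum", "distant_recurrence_cum", mode="after")
    @classmethod
    def _monotone(cls, v, info):
        return _check_cumulative(info.field_name, v)

    @field_validator("overall_survival", mode="after")
    @classmethod
    def _survival_monotone(cls, v, info):
        # a survival curve is non-increasing in years
        years = sorted(v)
        probs = [v[y] for y in years]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"{info.field_name}: probability outside [0, 1]")
        if any(b > a for a, b in zip(probs, probs[1:])):
            raise ValueError(
                f"{info.field_name}: survival must be non-increasing in years"
            )
        return {int(y): float(v[y]) for y in years}


class TransitionParams(_Model):
    nom: ArmTransitions
    resection: ArmTransitions

    def for_strategy(self, strategy: Strategy) -> ArmTransitions:
        return self.nom if strategy is Strategy.NOM else self.resection


class ArmUtilities(_Model):
    """Annual QALY weights per health state for one arm (0 = death, 1 = perfect)."""

    initial_state: float = Probability
    long_term_stable: float = Probability
    salvage_surgery: float = Probability
    local_recurrence: float = Probability
    distant_recurrence: float = Probability
    local_and_distant: float = Probability
    death: float = Probability

    @model_validator(mode="after")
    def _death_zero(self):
        if self.death != 0.0:
            raise ValueError("death utility must be exactly 0")
        return self

    def state_weights(self, cycle_year: int) -> Dict[HealthState, float]:
        """Per-state weights for a given cycle; the initial-state weight
        applies to the stable state in cycle 1 only."""
        stable = self.initial_state if cycle_year == 1 else self.long_term_stable
        return {
            HealthState.STABLE: stable,
            HealthState.STABLE_POST_SALVAGE: self.salvage_surgery,
            HealthState.LOCAL_RECURRENCE: self.local_recurrence,
            HealthState.DISTANT_RECURRENCE: self.distant_recurrence,
            HealthState.LOCAL_AND_DISTANT: self.local_and_distant,
            HealthState.DEATH: self.death,
        }


class UtilityParams(_Model):
    nom: ArmUtilities
    resection: ArmUtilities

    def for_strategy(self, strategy: Strategy) -> ArmUtilities:
        return self.nom if strategy is Strategy.NOM else self.resection


NonNegative = Field(ge=0.0)


class EconomicParams(_Model):
    """Income, pension, co-payment, driving and sick-pay rules (German SHI)."""

    wtp_per_qaly: float = Field(gt=0.0)
    discount_rate_annual: float = Field(ge=0.0, le=1.0)
    gross_income_monthly: float = NonNegative
    net_household_income_monthly: float = NonNegative
    net_household_income_general_monthly: float = NonNegative
    pension_monthly: float = NonNegative
    reduced_earning_capacity_pension_monthly: float = NonNegative
    tax_allowance_annual: float = NonNegative
    pension_taxable_fraction: float = Probability
    personal_allowance_per_person: float = NonNegative
    household_size: int = Field(ge=1)
    copay_rate_general: float = Probability
    copay_rate_chronic: float = Probability
    copay_per_unit: float = NonNegative
    inpatient_copay_cap_annual: float = NonNegative
    driving_distance_km: float = NonNegative
    driving_rate_per_km: float = NonNegative
    taxi_copay_per_covered_series: float = NonNegative
    supplement_monthly: float = NonNegative
    sick_pay_fraction: float = Probability
    full_pay_weeks: int = Field(ge=0)
    sick_pay_max_weeks: int = Field(ge=0)
    employment_rate_mixed: float = Probability

    @property
    def gross_income_weekly(self) -> float:
        return self.gross_income_monthly * 12.0 / 52.0


class VisitSeries(_Model):
    n_drives: int = Field(ge=0)
    covered: bool


class StrategySpec(_Model):
    """Treatment pathway structure for one arm: visit schedules, inpatient
    nights, ostomy status and return-to-work timing."""

    name: Strategy
    treatment_visit_series: List[VisitSeries]
    followup_visits_per_year: Dict[int, int]
    ostomy: bool
    inpatient_nights_primary: int = Field(ge=0)
    inpatient_nights_metastasectomy: int = Field(ge=0)
    return_to_work_months: int = Field(ge=0)
    employment_scenario: Scenario = Scenario.MIXED

    @model_validator(mode="after")
    def _structure(self):
        if self.name is Strategy.NOM:
            if self.ostomy:
                raise ValueError("NOM must not carry a definitive ostomy")
            if self.inpatient_nights_primary != 0:
                raise ValueError("NOM has no primary inpatient stay")
        else:
            if not self.ostomy:
                raise ValueError("RESECTION implies a definitive ostomy")
        bad = [y for y, n in self.followup_visits_per_year.items() if n < 0 or y < 1]
        if bad:
            raise ValueError(f"invalid follow-up schedule entries for years {bad}")
        return self


class CostAssumptions(_Model):
    """Assumed, calibrated cost-model inputs not stated by the sources."""

    round_trip_factor: float = Field(ge=1.0)
    toxicity_inpatient_nights: int = Field(ge=0)
    inpatient_nights_salvage: int = Field(ge=0)
    copay_units_treatment_year: int = Field(ge=0)
    copay_units_followup_nom: int = Field(ge=0)
    copay_units_followup_resection: int = Field(ge=0)
    copay_units_recurrence_year: int = Field(ge=0)
    absence_weeks_primary_nom: float = NonNegative
    absence_weeks_primary_resection: float = NonNegative
    absence_weeks_salvage: float = NonNegative
    absence_weeks_distant: float = NonNegative
    net_conversion_factor: float = Field(gt=0.0, le=1.0)
    half_cycle_correction: bool = False
    perioperative_death_at_salvage: str = Field(pattern="^(nom_only|both)$")


class AgeStratum(_Model):
    label: str
    cases: int = Field(ge=0)
    employment_rate: float = Probability
    gross_income_monthly: float = NonNegative


class AgeQuantiles(_Model):
    median: float
    q25: float
    q75: float
    min: float
    max: float

    @model_validator(mode="after")
    def _ordered(self):
        if not self.min <= self.q25 <= self.median <= self.q75 <= self.max:
            raise ValueError("age quantiles must be ordered min<=q25<=median<=q75<=max")
        return self


class CohortMarginals(_Model):
    """Published marginal counts of the survey reference cohort."""

    n_total: int = Field(ge=1)
    n_shi: int = Field(ge=0)
    age: AgeQuantiles
    gender: Dict[str, int]
    employment: Dict[str, int]
    income_bracket: Dict[str, int]
    income_loss_bracket: Dict[str, int]
    extra_expense_bracket: Dict[str, int]
    expense_cause_mentions: Dict[str, int]
    financial_difficulty: Dict[str, int]

    @field_validator(
        "gender", "employment", "income_bracket", "income_loss_bracket",
        "extra_expense_bracket", "expense_cause_mentions", "financial_difficulty",
        mode="after",
    )
    @classmethod
    def _nonneg(cls, v, info):
        if any(c < 0 for c in v.values()):
            raise ValueError(f"{info.field_name}: negative count")
        return v


class ModelConfig(_Model):
    """Root of the declarative configuration document."""

    schema_version: int = Field(ge=1)
    transitions: TransitionParams
    utilities: UtilityParams
    economics: EconomicParams
    strategies: Dict[str, StrategySpec]
    assumptions: CostAssumptions
    age_strata: List[AgeStratum]
    cohort_marginals: CohortMarginals

    @model_validator(mode="after")
    def _strategies_complete(self):
        keys = set(self.strategies)
        if keys != {"nom", "resection"}:
            raise ValueError(f"strategies must be exactly nom/resection, got {keys}")
        if self.strategies["nom"].name is not Strategy.NOM:
            raise ValueError("strategies.nom must have name NOM")
        if self.strategies["resection"].name is not Strategy.RESECTION:
            raise ValueError("strategies.resection must have name RESECTION")
        nom = self.strategies["nom"].followup_visits_per_year
        res = self.strategies["resection"].followup_visits_per_year
        for year in sorted(set(nom) | set(res)):
            if nom.get(year, 0) <= res.get(year, 0):
                raise ValueError(
                    "watch-and-wait surveillance must be strictly more frequent "
                    f"than post-resection follow-up in every year (year {year})"
                )
        return self

    def strategy_spec(self, strategy: Strategy) -> StrategySpec:
        return self.strategies["nom" if strategy is Strategy.NOM else "resection"]

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)

    def to_json_dict(self) -> dict:
        return self.model_dump(mode="json")


def load_params(text: str) -> ModelConfig:
    """Parse and validate a YAML configuration document.

    Raises ``pydantic.ValidationError`` (naming the offending key) on schema
    violations, out-of-range probabilities, negative monetary values or
    decreasing cumulative-risk maps.
    """
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("configuration document must be a mapping")
    return ModelConfig.model_validate(raw)


def default_config_text() -> str:
    """The bundled default profile as YAML text."""
    return (
        resources.files("nomcea").joinpath("data/default_params.yaml").read_text()
    )


def default_config() -> ModelConfig:
    """Load the bundled default parameter profile."""
    return load_params(default_config_text())
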