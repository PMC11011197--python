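"""Annual patient-borne costs per health state, strategy and employment scenario.

Four cost components are modelled, following the German statutory
health-insurance (SHI) rules:

* **co-payments** — 10 EUR per unit (prescription, remedy, ostomy product),
  inpatient nights at 10 EUR/night capped at 280 EUR/year, all capped by
  the annual exemption limit (2 % of adjusted gross household income, 1 %
  for chronic disease);
* **driving** — insurer-covered treatment series (chemoradiation,
  chemotherapy) cost the patient only the 5 EUR taxi co-payment for the
  first and last drive; follow-up visits are not reimbursed and are paid
  at 0.2 EUR/km for the round trip of the average 26.3 km centre distance;
* **supplements** — 10 EUR/month for non-prescription medication and
  ostomy-care products (ostomy carriers only);
* **loss of income** — employer continuation pays the first six weeks of
  absence in full; statutory sick pay then replaces 70 % of gross income
  for at most 72 weeks, so the patient loses 30 % of gross income for
  absence beyond six weeks; permanent disability replaces personal net
  income by the reduced-earning-capacity pension.  Retired patients lose
  nothing; the mixed scenario weights the employed loss by the cohort
  employment rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import pandas as pd

from .demographics import copay_exemption_limit
from .params import (
    CostAssumptions,
    EconomicParams,
    HealthState,
    Scenario,
    Strategy,
    StrategySpec,
)

COMPONENTS = ("copay", "driving", "supplement", "income_loss")


def driving_cost(
    n_visits: int,
    covered: bool,
    distance_km: float,
    rate_per_km: float,
    taxi_copay: float,
    round_trip_factor: float = 2.0,
) -> float:
    """Patient-borne driving cost of one visit series.

    A covered series (long-term therapy by taxi/ambulance service) costs the
    patient only the first-and-last-drive taxi co-payments regardless of its
    length; uncovered visits cost the full round-trip mileage each.
    """
    if n_visits < 0:
        raise ValueError("visit count must be non-negative")
    if n_visits == 0:
        return 0.0
    if covered:
        return taxi_copay
    return n_visits * round_trip_factor * distance_km * rate_per_km


def copay_cost(
    units: float,
    inpatient_nights: float,
    exemption_limit: float,
    copay_per_unit: float = 10.0,
    inpatient_cap: float = 280.0,
) -> float:
    """Annual co-payment: units plus capped inpatient nights, jointly capped
    by the applicable exemption limit.

    Counts may be fractional (expectations over a cohort).
    """
    if units < 0 or inpatient_nights < 0:
        raise ValueError("counts must be non-negative")
    raw = units * copay_per_unit + min(inpatient_nights * copay_per_unit, inpatient_cap)
    return min(raw, exemption_limit)


def income_loss(
    scenario: Scenario,
    absence_weeks: float,
    permanent_disability: bool,
    econ: EconomicParams,
    net_conversion_factor: float = 0.65,
    months: float = 12.0,
) -> float:
    """Annual loss of income for one cycle year.

    Temporary absence: the first ``full_pay_weeks`` are fully paid; beyond
    that, sick pay covers ``sick_pay_fraction`` of gross income for at most
    ``sick_pay_max_weeks``, so the patient loses the complement.  Permanent
    disability: the monthly gap between personal net income (gross times an
    assumed net-conversion factor) and the reduced-earning-capacity pension,
    over ``months`` of the cycle.
    """
    if absence_weeks < 0:
        raise ValueError("absence weeks must be non-negative")
    if scenario is Scenario.RETIRED:
        return 0.0
    if scenario is Scenario.MIXED:
        employed = income_loss(
            Scenario.EMPLOYED, absence_weeks, permanent_disability, econ,
            net_conversion_factor, months,
        )
        return econ.employment_rate_mixed * employed
    if permanent_disability:
        personal_net = net_conversion_factor * econ.gross_income_monthly
        gap = max(0.0, personal_net - econ.reduced_earning_capacity_pension_monthly)
        return gap * months
    sick_weeks = min(
        max(0.0, absence_weeks - econ.full_pay_weeks), float(econ.sick_pay_max_weeks)
    )
    lost_fraction = 1.0 - econ.sick_pay_fraction
    return sick_weeks * lost_fraction * econ.gross_income_weekly


@dataclass(frozen=True)
class StateCostProfile:
    """Per state and cycle-year cost components for one strategy/scenario.

    ``table`` is indexed by ``(state, cycle_year)`` with one column per
    component plus ``total``; ``assumptions`` records the assumed defaults
    in force so every report is auditable.
    """

    strategy: Strategy
    scenario: Scenario
    table: pd.DataFrame
    assumptions: Dict[str, object] = field(default_factory=dict)

    def cost(self, state: HealthState, cycle_year: int) -> float:
        return float(self.table.loc[(state.value, cycle_year), "total"])

    def component(self, state: HealthState, cycle_year: int, name: str) -> float:
        return float(self.table.loc[(state.value, cycle_year), name])

    def cost_vector(self, cycle_year: int) -> "pd.Series":
        """Total cost per state for one cycle year, in canonical state order."""
        return self.table.xs(cycle_year, level="cycle_year")["total"]


def build_state_costs(
    spec: StrategySpec,
    econ: EconomicParams,
    assumptions: CostAssumptions,
    scenario: Scenario,
    n_cycles: int = 5,
    toxicity_probability: float = 0.0,
) -> StateCostProfile:
    """Compose the per-state, per-cycle-year annual cost table.

    Conventions: costs accrue at the state occupied during the cycle;
    primary-treatment costs (covered therapy series, primary inpatient stay,
    initial absence from work) attach to the stable state in cycle 1.  The
    general 2 % exemption limit applies to the primary-treatment year, the
    chronic 1 % limit to follow-up years and to all recurrence states.
    """
    a = assumptions
    limit_general = copay_exemption_limit(
        econ.gross_income_monthly, econ.household_size,
        econ.personal_allowance_per_person, econ.copay_rate_general,
    )
    limit_chronic = copay_exemption_limit(
        econ.gross_income_monthly, econ.household_size,
        econ.personal_allowance_per_person, econ.copay_rate_chronic,
    )

    def drive_followup(n_visits: int) -> float:
        return driving_cost(
            n_visits, False, econ.driving_distance_km, econ.driving_rate_per_km,
            econ.taxi_copay_per_covered_series, a.round_trip_factor,
        )

    covered_series_cost = sum(
        driving_cost(
            s.n_drives, s.covered, econ.driving_distance_km,
            econ.driving_rate_per_km, econ.taxi_copay_per_covered_series,
            a.round_trip_factor,
        )
        for s in spec.treatment_visit_series
    )
    supplement_year = 12.0 * econ.supplement_monthly
    is_nom = spec.name is Strategy.NOM
    units_followup = (
        a.copay_units_followup_nom if is_nom else a.copay_units_followup_resection
    )
    absence_primary = (
        a.absence_weeks_primary_nom if is_nom else a.absence_weeks_primary_resection
    )
    # supportive inpatient nights from grade 3/4 toxicity enter the
    # primary-treatment co-payment as an expectation over the cohort
    toxicity_nights = toxicity_probability * a.toxicity_inpatient_nights
    rows = []
    for year in range(1, n_cycles + 1):
        followup_visits = spec.followup_visits_per_year.get(year, 0)
        followup_driving = drive_followup(followup_visits)

        # --- stable disease (A) ------------------------------------------
        if year == 1:
            copay = copay_cost(
                a.copay_units_treatment_year,
                spec.inpatient_nights_primary + toxicity_nights,
                limit_general, econ.copay_per_unit, econ.inpatient_copay_cap_annual,
            )
            driving = covered_series_cost + followup_driving
            loss = income_loss(
                scenario, absence_primary, False, econ, a.net_conversion_factor
            )
        else:
            copay = copay_cost(
                units_followup, 0, limit_chronic,
                econ.copay_per_unit, econ.inpatient_copay_cap_annual,
            )
            driving = followup_driving
            loss = 0.0
        supplement = supplement_year if spec.ostomy else 0.0
        rows.append((HealthState.STABLE, year, copay, driving, supplement, loss))

        # --- stable after successful salvage (B) -------------------------
        # post-surgical follow-up at the post-resection frequency; salvage
        # abdominoperineal resection leaves an ostomy in either arm
        copay_b = copay_cost(
            a.copay_units_followup_resection, 0, limit_chronic,
            econ.copay_per_unit, econ.inpatient_copay_cap_annual,
        )
        # post-salvage surveillance relaxes to the post-surgical frequency
        b_visits = max(1, followup_visits // 2) if is_nom else followup_visits
        driving_b = drive_followup(b_visits)
        rows.append(
            (HealthState.STABLE_POST_SALVAGE, year, copay_b, driving_b,
             supplement_year, 0.0)
        )

        # --- local recurrence (C): salvage resection year ----------------
        copay_c = copay_cost(
            a.copay_units_recurrence_year, a.inpatient_nights_salvage,
            limit_chronic, econ.copay_per_unit, econ.inpatient_copay_cap_annual,
        )
        driving_c = econ.taxi_copay_per_covered_series + followup_driving
        loss_c = income_loss(
            scenario, a.absence_weeks_salvage, False, econ, a.net_conversion_factor
        )
        rows.append(
            (HealthState.LOCAL_RECURRENCE, year, copay_c, driving_c,
             supplement_year, loss_c)
        )

        # --- distant recurrence (D): metastasectomy + chemotherapy -------
        copay_d = copay_cost(
            a.copay_units_recurrence_year, spec.inpatient_nights_metastasectomy,
            limit_chronic, econ.copay_per_unit, econ.inpatient_copay_cap_annual,
        )
        driving_d = econ.taxi_copay_per_covered_series + followup_driving
        loss_d = income_loss(
            scenario, a.absence_weeks_distant, False, econ, a.net_conversion_factor
        )
        supplement_d = supplement_year if spec.ostomy else 0.0
        rows.append(
            (HealthState.DISTANT_RECURRENCE, year, copay_d, driving_d,
             supplement_d, loss_d)
        )

        # --- local + distant recurrence (E): continuous therapy ----------
        # frequent co-payment needs: costs set at the chronic exemption limit
        copay_e = limit_chronic
        driving_e = econ.taxi_copay_per_covered_series
        loss_e = income_loss(scenario, 0.0, True, econ, a.net_conversion_factor)
        rows.append(
            (HealthState.LOCAL_AND_DISTANT, year, copay_e, driving_e,
             supplement_year, loss_e)
        )

        # --- death (F) ---------------------------------------------------
        rows.append((HealthState.DEATH, year, 0.0, 0.0, 0.0, 0.0))

    table = pd.DataFrame(
        rows, columns=["state", "cycle_year", *COMPONENTS]
    )
    table["state"] = [s.value for s in table["state"]]
    table["total"] = table[list(COMPONENTS)].sum(axis=1)
    table = table.set_index(["state", "cycle_year"]).sort_index()
    return StateCostProfile(
        strategy=spec.name,
        scenario=scenario,
        table=table,
        assumptions={
            "followup_visits_per_year": dict(spec.followup_visits_per_year),
            **a.model_dump(),
        },
    )
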