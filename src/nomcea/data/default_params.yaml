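# Default parameter profile for the rectal-cancer patient-cost model.
#
# Values under `transitions`, `utilities`, `economics`, `age_strata` and
# `cohort_marginals` are published point estimates (trial reports, German
# federal statistics, and the FinTox survey reference cohort).  Values under
# `assumptions` and the visit schedules in `strategies` are ASSUMED,
# CALIBRATED defaults: visit counts, absence durations and co-payment unit
# counts that the source material does not state; they are echoed in every
# cost report so the assumption set in force is always auditable.
schema_version: 1

transitions:
  nom:
    overall_g3g4_toxicity: 0.32
    perioperative_death: 0.04          # applies at salvage resection only
    local_recurrence_cum: {2: 0.21, 5: 0.24}
    distant_recurrence_cum: {3: 0.04, 5: 0.08}
    overall_survival: {3: 0.95, 5: 0.85}
    distant_given_local: 0.18
    local_given_distant: 0.54
    local_recurrence_after_salvage_5y: 0.13
    distant_after_local_3y: 0.11
    salvage_local: 0.94
    salvage_distant: 0.57
    mort_local_salvaged_5y: 0.5
    mort_local_unsalvaged_5y: 0.7
    mort_distant_5y: 0.8
    mort_local_and_distant_5y: 0.8
    other_cause_mortality_annual: 0.02
  resection:
    overall_g3g4_toxicity: 0.23
    perioperative_death: 0.04          # applies at entry (primary resection)
    local_recurrence_cum: {3: 0.03, 5: 0.05}
    distant_recurrence_cum: {3: 0.19, 5: 0.21}
    overall_survival: {3: 0.89, 5: 0.79}
    distant_given_local: 0.17
    local_given_distant: 0.36
    local_recurrence_after_salvage_5y: 0.13
    distant_after_local_3y: 0.11
    salvage_local: 0.59
    salvage_distant: 0.57
    mort_local_salvaged_5y: 0.5
    mort_local_unsalvaged_5y: 0.7
    mort_distant_5y: 0.8
    mort_local_and_distant_5y: 0.8
    other_cause_mortality_annual: 0.02

utilities:
  nom:
    initial_state: 0.80
    long_term_stable: 0.80
    salvage_surgery: 0.70
    local_recurrence: 0.67
    distant_recurrence: 0.70
    local_and_distant: 0.48
    death: 0.0
  resection:
    initial_state: 0.61
    long_term_stable: 0.70
    salvage_surgery: 0.70
    local_recurrence: 0.67
    distant_recurrence: 0.70
    local_and_distant: 0.48
    death: 0.0

economics:
  wtp_per_qaly: 6000.0
  discount_rate_annual: 0.035
  gross_income_monthly: 4409.0
  net_household_income_monthly: 2580.0
  net_household_income_general_monthly: 3813.0
  pension_monthly: 1048.0
  reduced_earning_capacity_pension_monthly: 925.0
  tax_allowance_annual: 10347.0
  pension_taxable_fraction: 0.80
  personal_allowance_per_person: 5922.0
  household_size: 2
  copay_rate_general: 0.02
  copay_rate_chronic: 0.01
  copay_per_unit: 10.0
  inpatient_copay_cap_annual: 280.0
  driving_distance_km: 26.3
  driving_rate_per_km: 0.2
  taxi_copay_per_covered_series: 10.0   # 5 EUR first + 5 EUR last drive
  supplement_monthly: 10.0
  sick_pay_fraction: 0.70
  full_pay_weeks: 6
  sick_pay_max_weeks: 72
  employment_rate_mixed: 0.282

strategies:
  nom:
    name: NOM
    # long-course chemoradiation (daily drives) + consolidation chemotherapy,
    # both insurer-covered series
    treatment_visit_series:
      - {n_drives: 28, covered: true}
      - {n_drives: 8, covered: true}
    # intensified surveillance under watch-and-wait: contact every ~3 months
    # incl. endoscopy and imaging appointments in years 1-2, half that
    # thereafter (assumed, calibrated)
    followup_visits_per_year: {1: 8, 2: 8, 3: 4, 4: 4, 5: 4}
    ostomy: false
    inpatient_nights_primary: 0
    inpatient_nights_metastasectomy: 5
    return_to_work_months: 2
    employment_scenario: MIXED
  resection:
    name: RESECTION
    treatment_visit_series:
      - {n_drives: 28, covered: true}
      - {n_drives: 8, covered: true}
    # conventional follow-up after resection (assumed, calibrated)
    followup_visits_per_year: {1: 2, 2: 2, 3: 1, 4: 1, 5: 1}
    ostomy: true
    inpatient_nights_primary: 16
    inpatient_nights_metastasectomy: 5
    return_to_work_months: 4
    employment_scenario: MIXED

assumptions:
  round_trip_factor: 2              # a visit implies return travel
  toxicity_inpatient_nights: 7      # supportive stay if grade 3/4 toxicity
  inpatient_nights_salvage: 16      # salvage resection, same stay as primary
  copay_units_treatment_year: 5
  copay_units_followup_nom: 1
  copay_units_followup_resection: 6
  copay_units_recurrence_year: 10
  absence_weeks_primary_nom: 8
  absence_weeks_primary_resection: 16
  absence_weeks_salvage: 26
  absence_weeks_distant: 26
  net_conversion_factor: 0.65       # personal net income from gross
  half_cycle_correction: false
  perioperative_death_at_salvage: nom_only

# Newly diagnosed rectal-cancer cases in Germany (2019) with general-population
# employment rates and mean gross monthly income (2022) per age band.
age_strata:
  - {label: "<25",    cases: 14,    employment_rate: 0.382, gross_income_monthly: 2913.0}
  - {label: "25-<45", cases: 460,   employment_rate: 0.780, gross_income_monthly: 3881.0}
  - {label: "45-<65", cases: 5807,  employment_rate: 0.737, gross_income_monthly: 4155.0}
  - {label: ">=65",   cases: 11614, employment_rate: 0.034, gross_income_monthly: 4557.0}

# FinTox reference-cohort marginals (survey of rectal-cancer patients;
# N = 44 overall, N = 38 insured with a statutory health insurance).
cohort_marginals:
  n_total: 44
  n_shi: 38
  age: {median: 67.0, q25: 58.0, q75: 75.0, min: 30.0, max: 90.0}
  gender: {female: 19, male: 25}
  employment: {employed: 12, not_employed: 4, retired: 18, not_reported: 4}
  income_bracket:
    "<1300": 8
    "1300-1700": 4
    "1701-2600": 8
    "2601-3600": 6
    "3601-5000": 5
    ">5000": 0
    "not_reported": 7
  income_loss_bracket:
    none: 25
    "<100": 2
    "100-500": 4
    "500-1500": 4
    not_reported: 3
  extra_expense_bracket:
    none: 16
    "<100": 3
    "100-500": 12
    "500-1500": 1
    not_reported: 6
  expense_cause_mentions:
    co-payments: 17
    driving: 10
    medication_health_care_products: 10
    other: 1
  financial_difficulty:
    none: 24
    little: 5
    moderate: 4
    great: 2
    not_reported: 3
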