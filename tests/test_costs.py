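"""Patient-borne cost components and the per-state cost table."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomcea.costs import (
    COMPONENTS,
    build_state_costs,
    copay_cost,
    driving_cost,
    income_loss,
)
from nomcea.params import HealthState, Scenario, Strategy


class TestDrivingCost:
    def test_covered_series_costs_only_taxi_copays(self):
        # 28 chemoradiation drives by taxi: 5 EUR first + 5 EUR last
        assert driving_cost(28, True, 26.3, 0.2, 10.0) == 10.0

    def test_uncovered_visit_is_round_trip_mileage(self):
        assert driving_cost(1, False, 26.3, 0.2, 10.0) == pytest.approx(10.52)

    def test_zero_visits_cost_nothing(self):
        assert driving_cost(0, True, 26.3, 0.2, 10.0) == 0.0
        assert driving_cost(0, False, 26.3, 0.2, 10.0) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            driving_cost(-1, False, 26.3, 0.2, 10.0)


class TestCopayCost:
    def test_inpatient_cap(self):
        # 40 nights would be 400 EUR but the annual inpatient cap is 280
        assert copay_cost(0, 40, exemption_limit=821.28) == 280.0

    def test_exemption_limit_caps_total(self):
        assert copay_cost(100, 40, exemption_limit=410.64) == 410.64

    def test_zero_is_zero(self):
        assert copay_cost(0, 0, exemption_limit=821.28) == 0.0

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(units=st.integers(0, 200), nights=st.integers(0, 60))
    def test_never_exceeds_exemption_limit(self, units, nights):
        limit = 821.28
        value = copay_cost(units, nights, exemption_limit=limit)
        assert 0.0 <= value <= limit


class TestIncomeLoss:
    def test_retired_lose_nothing(self, econ):
        assert income_loss(Scenario.RETIRED, 52, True, econ) == 0.0
        assert income_loss(Scenario.RETIRED, 10, False, econ) == 0.0

    def test_first_six_weeks_fully_paid(self, econ):
        assert income_loss(Scenario.EMPLOYED, 6, False, econ) == 0.0

    def test_sick_pay_gap_after_six_weeks(self, econ):
        # 10 weeks absent: 4 weeks at the 30 % sick-pay gap
        expected = 4 * 0.30 * (4409 * 12 / 52)
        assert income_loss(Scenario.EMPLOYED, 10, False, econ) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(1220.95, abs=0.01)

    def test_sick_pay_duration_cap(self, econ):
        capped = income_loss(Scenario.EMPLOYED, 6 + 72, False, econ)
        assert income_loss(Scenario.EMPLOYED, 200, False, econ) == capped

    def test_mixed_is_employment_weighted(self, econ):
        full = income_loss(Scenario.EMPLOYED, 20, False, econ)
        mixed = income_loss(Scenario.MIXED, 20, False, econ)
        assert mixed == pytest.approx(econ.employment_rate_mixed * full)

    def test_permanent_disability_gap_to_pension(self, econ):
        loss = income_loss(Scenario.EMPLOYED, 0, True, econ, 0.65)
        gap = 0.65 * econ.gross_income_monthly - 925
        assert loss == pytest.approx(12 * gap)


@pytest.fixture(scope="module")
def profiles(config):
    out = {}
    for strategy in Strategy:
        spec = config.strategy_spec(strategy)
        tox = config.transitions.for_strategy(strategy).overall_g3g4_toxicity
        for scenario in Scenario:
            out[strategy, scenario] = build_state_costs(
                spec, config.economics, config.assumptions, scenario,
                toxicity_probability=tox,
            )
    return out


class TestStateCostTable:
    def test_total_is_sum_of_components_and_non_negative(self, profiles):
        for profile in profiles.values():
            t = profile.table
            assert (t[list(COMPONENTS)] >= 0).all().all()
            assert t["total"].equals(t[list(COMPONENTS)].sum(axis=1))

    def test_death_state_costs_nothing(self, profiles):
        for profile in profiles.values():
            assert (profile.table.loc["F"]["total"] == 0).all()

    def test_nom_retired_stable_year3_is_followup_driving_only(
        self, profiles, config
    ):
        profile = profiles[Strategy.NOM, Scenario.RETIRED]
        visits = config.strategy_spec(Strategy.NOM).followup_visits_per_year[3]
        assert profile.component(HealthState.STABLE, 3, "driving") == pytest.approx(
            visits * 10.52
        )
        assert profile.component(HealthState.STABLE, 3, "income_loss") == 0.0

    def test_resection_stable_supplement_is_120_per_year(self, profiles):
        profile = profiles[Strategy.RESECTION, Scenario.MIXED]
        for year in range(1, 6):
            assert profile.component(HealthState.STABLE, year, "supplement") == 120.0

    def test_combined_recurrence_copay_pinned_to_chronic_limit(self, profiles):
        profile = profiles[Strategy.NOM, Scenario.RETIRED]
        for year in range(1, 6):
            assert profile.component(
                HealthState.LOCAL_AND_DISTANT, year, "copay"
            ) == pytest.approx(410.64)

    def test_copay_never_exceeds_exemption_limit(self, profiles):
        # general limit applies in the primary-treatment year, chronic after
        for profile in profiles.values():
            assert (profile.table["copay"] <= 821.28 + 1e-9).all()

    def test_resection_supplement_dominates_nom_statewise(self, profiles):
        for scenario in Scenario:
            nom = profiles[Strategy.NOM, scenario].table["supplement"]
            res = profiles[Strategy.RESECTION, scenario].table["supplement"]
            assert (res >= nom).all()

    def test_nom_surveillance_driving_dominates_resection(self, profiles):
        for scenario in Scenario:
            nom = profiles[Strategy.NOM, scenario].table.loc["A", "driving"]
            res = profiles[Strategy.RESECTION, scenario].table.loc["A", "driving"]
            assert (nom >= res).all()

    def test_employed_totals_dominate_retired_statewise(self, profiles):
        for strategy in Strategy:
            employed = profiles[strategy, Scenario.EMPLOYED].table["total"]
            retired = profiles[strategy, Scenario.RETIRED].table["total"]
            assert (employed >= retired).all()

    def test_assumptions_are_echoed_in_profile(self, profiles):
        profile = profiles[Strategy.NOM, Scenario.MIXED]
        assert "followup_visits_per_year" in profile.assumptions
        assert "absence_weeks_salvage" in profile.assumptions
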