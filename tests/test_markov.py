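"""Markov engine: annualization, matrix structure, cohort vs microsimulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomcea.markov import (
    TransitionMatrix,
    annualize,
    build_matrices,
    piecewise_annual,
    run_cohort,
    run_microsim,
)
from nomcea.params import STATES, HealthState, Strategy

DEATH = list(STATES).index(HealthState.DEATH)


class TestAnnualize:
    def test_zero_risk_stays_zero(self):
        assert annualize(0.0, 5) == 0.0

    def test_identity_at_one_year(self):
        assert annualize(0.37, 1) == pytest.approx(0.37)

    def test_five_year_survival_anchor(self):
        # 5-year overall survival 0.85 -> annual all-cause death ~3.2 %
        assert annualize(1 - 0.85, 5) == pytest.approx(0.03198, abs=1e-5)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            annualize(1.0, 5)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(p=st.floats(0, 0.99), h=st.floats(0.5, 10))
    def test_cumulative_recovery(self, p, h):
        a = annualize(p, h)
        assert 1 - (1 - a) ** h == pytest.approx(p, abs=1e-9)


class TestPiecewiseAnnual:
    def test_first_interval_hazard(self):
        # 2-year cumulative 0.21 -> annual 1 - 0.79^(1/2) ~= 0.1112
        assert piecewise_annual({2: 0.21, 5: 0.24}, 1) == pytest.approx(
            1 - 0.79 ** 0.5
        )

    def test_second_interval_uses_incremental_risk(self):
        expected = 1 - ((1 - 0.24) / (1 - 0.21)) ** (1 / 3)
        assert piecewise_annual({2: 0.21, 5: 0.24}, 4) == pytest.approx(expected)

    def test_carried_forward_beyond_last_anchor(self):
        assert piecewise_annual({2: 0.21, 5: 0.24}, 9) == piecewise_annual(
            {2: 0.21, 5: 0.24}, 5
        )


@pytest.fixture(scope="module", params=[Strategy.NOM, Strategy.RESECTION])
def arm_and_matrices(request, config):
    arm = config.transitions.for_strategy(request.param)
    return request.param, arm, build_matrices(request.param, arm)


class TestMatrices:
    def test_rows_are_stochastic(self, arm_and_matrices):
        _, _, mats = arm_and_matrices
        for m in mats:
            np.testing.assert_allclose(m.entries.sum(axis=1), 1.0, atol=1e-9)
            assert (m.entries >= 0).all()

    def test_death_is_absorbing(self, arm_and_matrices):
        _, _, mats = arm_and_matrices
        for m in mats:
            expected = np.zeros(len(STATES))
            expected[DEATH] = 1.0
            np.testing.assert_array_equal(m.entries[DEATH], expected)

    def test_forbidden_moves_are_zero(self, arm_and_matrices):
        # no resurrection, no direct return from recurrence to initial stable
        _, _, mats = arm_and_matrices
        for m in mats:
            assert m.entries[DEATH, :DEATH].sum() == 0.0
            assert m.entries[2, 0] == 0.0 and m.entries[3, 0] == 0.0

    def test_resection_uses_three_year_local_anchor(self, config):
        arm = config.transitions.resection
        mats = build_matrices(Strategy.RESECTION, arm)
        h = piecewise_annual({3: 0.03, 5: 0.05}, 1)
        # A -> C entry is the local hazard split off the combined-event share
        assert mats[0].entries[0, 2] == pytest.approx(
            h * (1 - arm.distant_given_local)
        )

    def test_invalid_matrix_rejected(self):
        bad = np.eye(len(STATES))
        bad[0, 0] = 0.5
        with pytest.raises(ValueError):
            TransitionMatrix(cycle_year=1, entries=bad)


def identity_matrices(n=5):
    return [
        TransitionMatrix(cycle_year=t, entries=np.eye(len(STATES)))
        for t in range(1, n + 1)
    ]


class TestRunCohort:
    def test_zero_discount_equals_undiscounted(self, config):
        arm = config.transitions.nom
        mats = build_matrices(Strategy.NOM, arm)
        r = run_cohort(
            Strategy.NOM, arm, mats, config.utilities.nom, discount_rate=0.0
        )
        assert r.discounted_qaly_total == pytest.approx(r.undiscounted_qaly_total)

    def test_geometric_sum_with_unit_utilities(self, config):
        arm = config.transitions.nom
        perfect = config.utilities.nom.model_copy(
            update={"initial_state": 1.0, "long_term_stable": 1.0}
        )
        r = run_cohort(
            Strategy.NOM, arm, identity_matrices(), perfect, discount_rate=0.035
        )
        expected = sum(1.035 ** -t for t in range(1, 6))
        assert r.discounted_qaly_total == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(4.515, abs=5e-4)

    def test_stable_cohort_accrues_stable_utility(self, config):
        arm = config.transitions.nom
        r = run_cohort(
            Strategy.NOM, arm, identity_matrices(), config.utilities.nom,
            discount_rate=0.035,
        )
        expected = 0.80 * sum(1.035 ** -t for t in range(1, 6))
        assert r.discounted_qaly_total == pytest.approx(expected, abs=1e-9)

    def test_occupancy_vectors_sum_to_one(self, arm_and_matrices, config):
        strategy, arm, mats = arm_and_matrices
        r = run_cohort(strategy, arm, mats, config.utilities.for_strategy(strategy))
        for v in r.occupancy.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_death_occupancy_monotone(self, arm_and_matrices, config):
        strategy, arm, mats = arm_and_matrices
        r = run_cohort(strategy, arm, mats, config.utilities.for_strategy(strategy))
        deaths = [r.occupancy[t][DEATH] for t in sorted(r.occupancy)]
        assert all(b >= a for a, b in zip(deaths, deaths[1:]))

    def test_discounting_strictly_decreases_totals(self, config):
        arm = config.transitions.nom
        mats = build_matrices(Strategy.NOM, arm)
        totals = [
            run_cohort(
                Strategy.NOM, arm, mats, config.utilities.nom, discount_rate=r
            ).discounted_qaly_total
            for r in (0.0, 0.035, 0.10)
        ]
        assert totals[0] > totals[1] > totals[2]

    def test_resection_applies_perioperative_death_at_entry(self, config):
        arm = config.transitions.resection
        mats = build_matrices(Strategy.RESECTION, arm)
        r = run_cohort(Strategy.RESECTION, arm, mats, config.utilities.resection)
        assert r.occupancy[0][DEATH] == pytest.approx(arm.perioperative_death)


class TestMicrosim:
    def test_seed_determinism(self, config):
        arm = config.transitions.nom
        mats = build_matrices(Strategy.NOM, arm)
        a = run_microsim(
            Strategy.NOM, arm, mats, config.utilities.nom, n=2000, seed=7
        )
        b = run_microsim(
            Strategy.NOM, arm, mats, config.utilities.nom, n=2000, seed=7
        )
        for t in a.occupancy:
            np.testing.assert_array_equal(a.occupancy[t], b.occupancy[t])
        assert a.discounted_qaly_total == b.discounted_qaly_total
        assert a.discounted_cost_total == b.discounted_cost_total

    def test_single_patient_occupancy_is_indicator(self, config):
        arm = config.transitions.nom
        mats = build_matrices(Strategy.NOM, arm)
        r = run_microsim(
            Strategy.NOM, arm, mats, config.utilities.nom, n=1, seed=3
        )
        for v in r.occupancy.values():
            assert sorted(v) == [0, 0, 0, 0, 0, 1]

    def test_converges_to_cohort_expectation(self, arm_and_matrices, config):
        strategy, arm, mats = arm_and_matrices
        utilities = config.utilities.for_strategy(strategy)
        n = 50_000
        det = run_cohort(strategy, arm, mats, utilities)
        sim = run_microsim(strategy, arm, mats, utilities, n=n, seed=11)
        for t in det.occupancy:
            for i in range(len(STATES)):
                p = det.occupancy[t][i]
                sigma = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(sim.occupancy[t][i] - p) <= max(3 * sigma, 2 / n)

    def test_n_must_be_positive(self, config):
        arm = config.transitions.nom
        mats = build_matrices(Strategy.NOM, arm)
        with pytest.raises(ValueError):
            run_microsim(Strategy.NOM, arm, mats, config.utilities.nom, n=0)
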