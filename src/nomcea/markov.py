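"""Six-state Markov engine: matrix construction, deterministic cohort
evaluation and individual-level microsimulation.

States (canonical order): stable disease (A), stable after successful
salvage (B), local recurrence (C), distant recurrence (D), local + distant
recurrence (E), death (F, absorbing).  Cycle length is one year; the base
case runs five cycles.

The published inputs are cumulative risks at 2/3/5-year anchors; they are
converted to per-cycle probabilities under a piecewise-constant-hazard
assumption (``annualize``).  Competing exits from a state are composed
additively from the branch probabilities and the row is renormalized if the
exits exceed 1; the residual probability is "remain in state".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .costs import StateCostProfile
from .params import (
    STATES,
    STATE_INDEX,
    ArmTransitions,
    ArmUtilities,
    HealthState,
    Strategy,
)

logger = logging.getLogger(__name__)

N_STATES = len(STATES)
_A = STATE_INDEX[HealthState.STABLE]
_B = STATE_INDEX[HealthState.STABLE_POST_SALVAGE]
_C = STATE_INDEX[HealthState.LOCAL_RECURRENCE]
_D = STATE_INDEX[HealthState.DISTANT_RECURRENCE]
_E = STATE_INDEX[HealthState.LOCAL_AND_DISTANT]
_F = STATE_INDEX[HealthState.DEATH]


def annualize(p_cum: float, horizon_years: float) -> float:
    """Convert a cumulative probability over ``horizon_years`` to a per-year
    probability under a constant hazard: ``1 - (1 - p)**(1/h)``."""
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1), got {p_cum}")
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    return 1.0 - (1.0 - p_cum) ** (1.0 / horizon_years)


def piecewise_annual(cum: Dict[int, float], cycle_year: int) -> float:
    """Per-cycle probability for ``cycle_year`` from a map of cumulative
    anchors ``{years: cumulative probability}``.

    Within each inter-anchor interval the hazard is constant; beyond the
    last anchor the final interval's hazard is carried forward.
    """
    years = sorted(cum)
    if not years:
        return 0.0
    prev_y, prev_p = 0, 0.0
    for y in years:
        p = cum[y]
        if cycle_year <= y or y == years[-1]:
            surv_ratio = (1.0 - p) / (1.0 - prev_p) if prev_p < 1.0 else 0.0
            if surv_ratio <= 0.0:
                return 1.0
            return 1.0 - surv_ratio ** (1.0 / (y - prev_y))
        prev_y, prev_p = y, p
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class TransitionMatrix:
    """One cycle's 6x6 row-stochastic transition matrix."""

    cycle_year: int
    entries: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValueError(f"matrix must be {N_STATES}x{N_STATES}")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("entries must be probabilities")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")
        death = np.zeros(N_STATES)
        death[_F] = 1.0
        if not np.allclose(m[_F], death):
            raise ValueError("death must be absorbing")


def _compose_row(exits: Dict[int, float], self_idx: int, name: str) -> np.ndarray:
    row = np.zeros(N_STATES)
    total = 0.0
    for idx, p in exits.items():
        row[idx] += p
        total += p
    if total > 1.0:
        if total > 1.25:
            logger.warning(
                "row %s: composed exit probability %.3f exceeds 1 by more than "
                "0.25 before renormalization (parameter tension)", name, total
            )
        row /= total
    else:
        row[self_idx] = 1.0 - total
    return row


def _or(p: float, q: float) -> float:
    """Combine two competing exit risks multiplicatively: 1-(1-p)(1-q)."""
    return 1.0 - (1.0 - p) * (1.0 - q)


def build_matrices(
    strategy: Strategy,
    arm: ArmTransitions,
    n_cycles: int = 5,
    perioperative_death_at_salvage: str = "nom_only",
) -> List[TransitionMatrix]:
    """Per-cycle transition matrices for one arm from its published anchors.

    Arrow set (minimal set consistent with the inputs): A->C/D/E/F,
    C->B/E/F, D->B/E/F, B->C/F, E->F, self-loops everywhere, F absorbing.
    Local and distant events from the stable state are split to the
    combined-recurrence state E by the conditional co-occurrence
    probabilities.  Salvage routes recurrence back to stable-after-salvage
    (B); perioperative mortality applies at salvage resection (in the
    watch-and-wait arm by default; configurable to both arms).
    """
    m = arm.other_cause_mortality_annual
    salvage_periop = arm.perioperative_death if (
        perioperative_death_at_salvage == "both" or strategy is Strategy.NOM
    ) else 0.0

    p_b_relapse = annualize(arm.local_recurrence_after_salvage_5y, 5)
    p_mort_salvaged = annualize(arm.mort_local_salvaged_5y, 5)
    p_mort_unsalvaged = annualize(arm.mort_local_unsalvaged_5y, 5)
    p_mort_distant = annualize(arm.mort_distant_5y, 5)
    p_mort_combined = annualize(arm.mort_local_and_distant_5y, 5)

    matrices = []
    for year in range(1, n_cycles + 1):
        h_local = piecewise_annual(arm.local_recurrence_cum, year)
        h_distant = piecewise_annual(arm.distant_recurrence_cum, year)

        rows = np.zeros((N_STATES, N_STATES))

        # A: stable disease
        rows[_A] = _compose_row(
            {
                _C: h_local * (1.0 - arm.distant_given_local),
                _D: h_distant * (1.0 - arm.local_given_distant),
                _E: h_local * arm.distant_given_local
                    + h_distant * arm.local_given_distant,
                _F: m,
            },
            _A, f"{strategy.value}/A/y{year}",
        )

        # B: stable after salvage; background mortality + re-recurrence risk
        # (the excess mortality of salvaged local recurrence is charged at
        # the recurrence state itself, see C below)
        rows[_B] = _compose_row(
            {_C: p_b_relapse, _F: m},
            _B, f"{strategy.value}/B/y{year}",
        )

        # C: local recurrence — salvage attempt, distant progression, death;
        # the 5-year mortalities after salvaged/unsalvaged local recurrence
        # both act here, weighted by the salvage probability (the row is
        # renormalized, which spreads the excess over the competing exits)
        s = arm.salvage_local
        rows[_C] = _compose_row(
            {
                _B: s * (1.0 - salvage_periop),
                _E: (1.0 - s) * arm.distant_given_local,
                _F: _or(
                    s * salvage_periop
                    + s * p_mort_salvaged
                    + (1.0 - s) * p_mort_unsalvaged,
                    m,
                ),
            },
            _C, f"{strategy.value}/C/y{year}",
        )

        # D: distant recurrence — metastasectomy salvage, local progression
        sd = arm.salvage_distant
        rows[_D] = _compose_row(
            {
                _B: sd,
                _E: (1.0 - sd) * arm.local_given_distant,
                _F: _or((1.0 - sd) * p_mort_distant, m),
            },
            _D, f"{strategy.value}/D/y{year}",
        )

        # E: combined recurrence — continuous therapy until death
        rows[_E] = _compose_row(
            {_F: _or(p_mort_combined, m)}, _E, f"{strategy.value}/E/y{year}"
        )

        # F: absorbing
        rows[_F, _F] = 1.0

        matrices.append(TransitionMatrix(cycle_year=year, entries=rows))
    return matrices


@dataclass(frozen=True)
class CohortResult:
    """Occupancy trajectory plus discounted/undiscounted cost and QALY totals."""

    strategy: Strategy
    scenario: str
    occupancy: Dict[int, np.ndarray]
    discounted_cost_total: float
    discounted_qaly_total: float
    undiscounted_cost_total: float
    undiscounted_qaly_total: float
    n_simulated: Optional[int] = None
    seed: Optional[int] = None

    def occupancy_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, fraction) trajectory."""
        rows = [
            {"cycle": t, "state": s.value, "fraction": float(v[i])}
            for t, v in sorted(self.occupancy.items())
            for i, s in enumerate(STATES)
        ]
        return pd.DataFrame(rows)

    def death_fraction(self, cycle: Optional[int] = None) -> float:
        t = max(self.occupancy) if cycle is None else cycle
        return float(self.occupancy[t][_F])


def _initial_occupancy(strategy: Strategy, arm: ArmTransitions) -> np.ndarray:
    """Everyone starts stable; the resection arm applies perioperative
    mortality of the primary resection at entry."""
    occ = np.zeros(N_STATES)
    if strategy is Strategy.RESECTION:
        occ[_A] = 1.0 - arm.perioperative_death
        occ[_F] = arm.perioperative_death
    else:
        occ[_A] = 1.0
    return occ


def _accounting_vectors(
    utilities: ArmUtilities,
    costs: Optional[StateCostProfile],
    n_cycles: int,
) -> tuple[List[np.ndarray], List[np.ndarray]]:
    u_vecs, c_vecs = [], []
    for year in range(1, n_cycles + 1):
        w = utilities.state_weights(year)
        u_vecs.append(np.array([w[s] for s in STATES]))
        if costs is None:
            c_vecs.append(np.zeros(N_STATES))
        else:
            series = costs.cost_vector(year)
            c_vecs.append(np.array([series[s.value] for s in STATES]))
    return u_vecs, c_vecs


def run_cohort(
    strategy: Strategy,
    arm: ArmTransitions,
    matrices: Sequence[TransitionMatrix],
    utilities: ArmUtilities,
    costs: Optional[StateCostProfile] = None,
    discount_rate: float = 0.035,
) -> CohortResult:
    """Deterministic cohort expectation over the cycle horizon.

    ``occupancy(t) = occupancy(t-1) @ M(t)``; cycle accruals use the
    end-of-cycle occupancy and are discounted by ``(1+r)^-t``.
    """
    n_cycles = len(matrices)
    u_vecs, c_vecs = _accounting_vectors(utilities, costs, n_cycles)
    occ = _initial_occupancy(strategy, arm)
    occupancy = {0: occ.copy()}
    qaly_d = cost_d = qaly_u = cost_u = 0.0
    for t, mat in enumerate(matrices, start=1):
        occ = occ @ mat.entries
        occupancy[t] = occ.copy()
        disc = (1.0 + discount_rate) ** (-t)
        q = float(occ @ u_vecs[t - 1])
        c = float(occ @ c_vecs[t - 1])
        qaly_u += q
        cost_u += c
        qaly_d += q * disc
        cost_d += c * disc
    return CohortResult(
        strategy=strategy,
        scenario=costs.scenario.value if costs is not None else "NONE",
        occupancy=occupancy,
        discounted_cost_total=cost_d,
        discounted_qaly_total=qaly_d,
        undiscounted_cost_total=cost_u,
        undiscounted_qaly_total=qaly_u,
    )


def run_microsim(
    strategy: Strategy,
    arm: ArmTransitions,
    matrices: Sequence[TransitionMatrix],
    utilities: ArmUtilities,
    costs: Optional[StateCostProfile] = None,
    n: int = 100_000,
    seed: int = 0,
    discount_rate: float = 0.035,
) -> CohortResult:
    """Individual-level microsimulation: ``n`` independent trajectories
    sampled from the per-cycle matrix rows, with accounting identical to
    :func:`run_cohort`.  Bit-reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_cycles = len(matrices)
    u_vecs, c_vecs = _accounting_vectors(utilities, costs, n_cycles)

    init = _initial_occupancy(strategy, arm)
    states = rng.choice(N_STATES, size=n, p=init)
    occupancy = {0: np.bincount(states, minlength=N_STATES) / n}
    qaly_d = cost_d = qaly_u = cost_u = 0.0
    for t, mat in enumerate(matrices, start=1):
        cum = np.cumsum(mat.entries, axis=1)
        u = rng.random(n)
        # vectorized per-row inverse-CDF sampling
        states = (u[:, None] > cum[states]).sum(axis=1)
        frac = np.bincount(states, minlength=N_STATES) / n
        occupancy[t] = frac
        disc = (1.0 + discount_rate) ** (-t)
        q = float(frac @ u_vecs[t - 1])
        c = float(frac @ c_vecs[t - 1])
        qaly_u += q
        cost_u += c
        qaly_d += q * disc
        cost_d += c * disc
    return CohortResult(
        strategy=strategy,
        scenario=costs.scenario.value if costs is not None else "NONE",
        occupancy=occupancy,
        discounted_cost_total=cost_d,
        discounted_qaly_total=qaly_d,
        undiscounted_cost_total=cost_u,
        undiscounted_qaly_total=qaly_u,
        n_simulated=n,
        seed=seed,
    )
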