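"""One-way threshold sensitivity analysis on costs and utilities.

The net monetary benefit is affine in both cost and effectiveness, so the
equivalence points where the two strategies' NMBs cross are available in
closed form:

* cost threshold:  ``C* = WTP * E_self - NMB_other``
* QALY threshold:  ``E* = (C_self + NMB_other) / WTP``

A negative cost threshold or a QALY threshold above the horizon maximum
(5 QALYs in 5 years) means no feasible parameter value makes the
comparator competitive; such points are reported with ``feasible=False``
rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

MAX_QALY_5Y = 5.0


def cost_threshold(wtp: float, eff_self: float, nmb_other: float) -> float:
    """Own cost at which the own NMB equals the comparator's NMB."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return wtp * eff_self - nmb_other


def qaly_threshold(wtp: float, cost_self: float, nmb_other: float) -> float:
    """Own effectiveness at which the own NMB equals the comparator's NMB."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return (cost_self + nmb_other) / wtp


@dataclass(frozen=True)
class ThresholdResult:
    strategy: str
    scenario: str
    base_qaly: float
    qaly_equiv: float
    base_cost: float
    cost_equiv: float

    @property
    def cost_feasible(self) -> bool:
        return self.cost_equiv >= 0.0

    @property
    def qaly_feasible(self) -> bool:
        return self.qaly_equiv <= MAX_QALY_5Y

    @property
    def feasible(self) -> bool:
        return self.cost_feasible and self.qaly_feasible


def threshold_row(
    strategy: str,
    scenario: str,
    wtp: float,
    base_qaly: float,
    base_cost: float,
    nmb_other: float,
) -> ThresholdResult:
    """Equivalence points for one strategy/scenario against a fixed
    comparator NMB."""
    return ThresholdResult(
        strategy=strategy,
        scenario=scenario,
        base_qaly=base_qaly,
        qaly_equiv=qaly_threshold(wtp, base_cost, nmb_other),
        base_cost=base_cost,
        cost_equiv=cost_threshold(wtp, base_qaly, nmb_other),
    )


def threshold_table(rows: Sequence[ThresholdResult]) -> pd.DataFrame:
    """Threshold table with 2-decimal QALY rendering alongside full precision."""
    return pd.DataFrame(
        [
            {
                "strategy": r.strategy,
                "scenario": r.scenario,
                "base_qaly": r.base_qaly,
                "qaly_equiv": r.qaly_equiv,
                "qaly_equiv_2dp": round(r.qaly_equiv, 2),
                "base_cost": r.base_cost,
                "cost_equiv": r.cost_equiv,
                "cost_feasible": r.cost_feasible,
                "qaly_feasible": r.qaly_feasible,
            }
            for r in rows
        ]
    )


def nmb_sweep(
    cost_grid: Sequence[float],
    wtp: float,
    eff_self: float,
    comparator_nmb: Optional[float] = None,
) -> pd.DataFrame:
    """NMB-vs-cost sweep curve: ``nmb = wtp * eff_self - cost`` over the
    grid, with per-point dominance against a fixed comparator NMB and the
    crossover cost annotated when a comparator is given."""
    if len(cost_grid) == 0:
        raise ValueError("cost grid must be non-empty")
    rows = []
    crossover = (
        cost_threshold(wtp, eff_self, comparator_nmb)
        if comparator_nmb is not None
        else None
    )
    for cost in cost_grid:
        value = wtp * eff_self - cost
        rows.append(
            {
                "cost": float(cost),
                "nmb": value,
                "dominant": (value > comparator_nmb)
                if comparator_nmb is not None
                else None,
                "crossover_cost": crossover,
            }
        )
    return pd.DataFrame(rows)
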