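"""Incremental cost-effectiveness arithmetic: ICER, NMB, iNMB, dominance.

For strategies with costs :math:`C` and effectiveness :math:`E` (QALYs):

.. math::

    ICER = (C_{NOM} - C_{RES}) / (E_{NOM} - E_{RES}) \\qquad
    NMB = WTP \\times E - C

A positive incremental NMB (iNMB = NMB_NOM - NMB_RES) favours
watch-and-wait.  All monetary outputs are carried at full precision;
renderers round to whole EUR.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd


class Dominance(str, enum.Enum):
    NOM_DOMINANT = "NOM_DOMINANT"
    RESECTION_DOMINANT = "RESECTION_DOMINANT"
    TRADEOFF = "TRADEOFF"


@dataclass(frozen=True)
class CEAInput:
    """Cost/effectiveness pairs for both strategies plus the WTP threshold."""

    cost_nom: float
    cost_resection: float
    eff_nom: float
    eff_resection: float
    wtp: float

    def __post_init__(self):
        for name in ("cost_nom", "cost_resection", "eff_nom", "eff_resection", "wtp"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.wtp <= 0:
            raise ValueError("willingness-to-pay must be positive")


@dataclass(frozen=True)
class CEAResult:
    icer: Optional[float]          # None when effectiveness is equal
    nmb_nom: float
    nmb_resection: float
    inmb: float
    dominance: Dominance


def nmb(wtp: float, eff: float, cost: float) -> float:
    """Net monetary benefit ``WTP * E - C``."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return wtp * eff - cost


def inmb(nmb_a: float, nmb_b: float) -> float:
    """Incremental net monetary benefit, first strategy minus second."""
    return nmb_a - nmb_b


def icer(inp: CEAInput) -> tuple[Optional[float], Dominance]:
    """ICER of watch-and-wait vs. resection with dominance classification.

    Returns ``(None, dominance)`` when effectiveness is equal (the ICER is
    undefined); the dominance flag is raised whenever one strategy is at
    least as cheap and at least as effective with one strict inequality.
    """
    d_cost = inp.cost_nom - inp.cost_resection
    d_eff = inp.eff_nom - inp.eff_resection
    dominance = classify_dominance(inp)
    if d_eff == 0.0:
        return None, dominance
    return d_cost / d_eff, dominance


def classify_dominance(inp: CEAInput) -> Dominance:
    cheaper_nom = inp.cost_nom <= inp.cost_resection
    better_nom = inp.eff_nom >= inp.eff_resection
    strict = (inp.cost_nom != inp.cost_resection) or (inp.eff_nom != inp.eff_resection)
    if cheaper_nom and better_nom and strict:
        return Dominance.NOM_DOMINANT
    if not cheaper_nom and not better_nom:
        return Dominance.RESECTION_DOMINANT
    if inp.cost_nom >= inp.cost_resection and inp.eff_nom <= inp.eff_resection and strict:
        return Dominance.RESECTION_DOMINANT
    return Dominance.TRADEOFF


def evaluate(inp: CEAInput) -> CEAResult:
    """Full CEA block from one cost/effectiveness quadruple."""
    ratio, dominance = icer(inp)
    nmb_nom = nmb(inp.wtp, inp.eff_nom, inp.cost_nom)
    nmb_res = nmb(inp.wtp, inp.eff_resection, inp.cost_resection)
    return CEAResult(
        icer=ratio,
        nmb_nom=nmb_nom,
        nmb_resection=nmb_res,
        inmb=inmb(nmb_nom, nmb_res),
        dominance=dominance,
    )


def results_table(inputs: dict[str, CEAInput]) -> pd.DataFrame:
    """Strategy x scenario CEA table (one row per scenario)."""
    rows = []
    for scenario, inp in inputs.items():
        res = evaluate(inp)
        rows.append(
            {
                "scenario": scenario,
                "qaly_nom": inp.eff_nom,
                "qaly_resection": inp.eff_resection,
                "cost_nom": inp.cost_nom,
                "cost_resection": inp.cost_resection,
                "delta_cost": inp.cost_nom - inp.cost_resection,
                "icer": res.icer,
                "nmb_nom": res.nmb_nom,
                "nmb_resection": res.nmb_resection,
                "inmb": res.inmb,
                "dominance": res.dominance.value,
            }
        )
    return pd.DataFrame(rows)
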