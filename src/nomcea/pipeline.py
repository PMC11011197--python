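"""End-to-end runs: full model (engine + costs + CEA + thresholds) and the
CEA-only path operating on user-supplied aggregates.

The two entry points separate the exactly-reproducible layer (the CEA and
threshold arithmetic, which depends only on the four cost/effectiveness
aggregates and the WTP) from the assumption-laden cost layer (which depends
on assumed visit schedules and absence durations).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .cea import CEAInput, evaluate, results_table
from .costs import StateCostProfile, build_state_costs
from .markov import CohortResult, build_matrices, run_cohort, run_microsim
from .params import ModelConfig, Scenario, Strategy
from .sensitivity import ThresholdResult, threshold_row, threshold_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one run: parameter hash, seed, engine, sizes."""

    params_sha256: str
    seed: Optional[int]
    n_simulated: Optional[int]
    engine: str
    package_version: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def config_hash(config: ModelConfig) -> str:
    canonical = json.dumps(config.to_json_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _log_assumptions(profile: StateCostProfile) -> None:
    logger.warning(
        "assumed (non-published) cost defaults in force for %s/%s: %s",
        profile.strategy.value, profile.scenario.value,
        json.dumps(profile.assumptions, sort_keys=True, default=str),
    )


@dataclass(frozen=True)
class BaseCaseResult:
    scenario: Scenario
    engine: str
    cohorts: Dict[Strategy, CohortResult]
    cost_profiles: Dict[Strategy, StateCostProfile]
    cea_input: CEAInput
    cea_table: pd.DataFrame
    thresholds: pd.DataFrame
    manifest: RunManifest

    def occupancy_frames(self) -> Dict[str, pd.DataFrame]:
        return {s.value: c.occupancy_frame() for s, c in self.cohorts.items()}


def run_base_case(
    config: ModelConfig,
    scenario: Scenario = Scenario.MIXED,
    engine: str = "cohort",
    seed: int = 0,
    n: int = 100_000,
    n_cycles: int = 5,
) -> BaseCaseResult:
    """Run both strategies through the Markov engine with the scenario's
    cost profile, then the CEA and threshold analysis on the resulting
    discounted aggregates."""
    if engine not in ("cohort", "microsim"):
        raise ValueError("engine must be 'cohort' or 'microsim'")
    econ = config.economics
    cohorts: Dict[Strategy, CohortResult] = {}
    profiles: Dict[Strategy, StateCostProfile] = {}
    for strategy in (Strategy.NOM, Strategy.RESECTION):
        spec = config.strategy_spec(strategy)
        arm = config.transitions.for_strategy(strategy)
        profile = build_state_costs(
            spec, econ, config.assumptions, scenario, n_cycles=n_cycles,
            toxicity_probability=arm.overall_g3g4_toxicity,
        )
        _log_assumptions(profile)
        matrices = build_matrices(
            strategy, arm, n_cycles=n_cycles,
            perioperative_death_at_salvage=(
                config.assumptions.perioperative_death_at_salvage
            ),
        )
        utilities = config.utilities.for_strategy(strategy)
        if engine == "cohort":
            cohorts[strategy] = run_cohort(
                strategy, arm, matrices, utilities, profile,
                discount_rate=econ.discount_rate_annual,
            )
        else:
            cohorts[strategy] = run_microsim(
                strategy, arm, matrices, utilities, profile, n=n, seed=seed,
                discount_rate=econ.discount_rate_annual,
            )
        profiles[strategy] = profile

    inp = CEAInput(
        cost_nom=cohorts[Strategy.NOM].discounted_cost_total,
        cost_resection=cohorts[Strategy.RESECTION].discounted_cost_total,
        eff_nom=cohorts[Strategy.NOM].discounted_qaly_total,
        eff_resection=cohorts[Strategy.RESECTION].discounted_qaly_total,
        wtp=econ.wtp_per_qaly,
    )
    table = results_table({scenario.value: inp})
    thresholds = threshold_table(cea_thresholds(inp, scenario.value))
    manifest = RunManifest(
        params_sha256=config_hash(config),
        seed=seed if engine == "microsim" else None,
        n_simulated=n if engine == "microsim" else None,
        engine=engine,
        package_version=__version__,
    )
    return BaseCaseResult(
        scenario=scenario,
        engine=engine,
        cohorts=cohorts,
        cost_profiles=profiles,
        cea_input=inp,
        cea_table=table,
        thresholds=thresholds,
        manifest=manifest,
    )


def cea_thresholds(inp: CEAInput, scenario: str) -> list[ThresholdResult]:
    """Both strategies' equivalence points against each other's base NMB."""
    res = evaluate(inp)
    return [
        threshold_row(
            "NOM", scenario, inp.wtp, inp.eff_nom, inp.cost_nom, res.nmb_resection
        ),
        threshold_row(
            "RESECTION", scenario, inp.wtp, inp.eff_resection, inp.cost_resection,
            res.nmb_nom,
        ),
    ]


def run_cea_only(
    cost_nom: float,
    cost_resection: float,
    eff_nom: float,
    eff_resection: float,
    wtp: float,
    scenario: str = "ALL",
) -> dict:
    """CEA + threshold block from user-supplied aggregates, bypassing the
    engine and cost model entirely."""
    inp = CEAInput(
        cost_nom=cost_nom,
        cost_resection=cost_resection,
        eff_nom=eff_nom,
        eff_resection=eff_resection,
        wtp=wtp,
    )
    res = evaluate(inp)
    return {
        "cea": results_table({scenario: inp}),
        "thresholds": threshold_table(cea_thresholds(inp, scenario)),
        "result": res,
    }
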