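"""Synthetic survey-cohort generator emulating the FinTox reference subgroup.

The reference cohort is a 44-patient survey of German rectal-cancer
patients (38 insured with a statutory health insurance, SHI) with published
marginal distributions only: age quantiles, gender, insurance, employment,
net-household-income brackets, treatment-related loss of income and
additional expenses, multi-select expense causes and perceived financial
difficulty.  Records are drawn independently per field (no copula — only
marginals are published), which reproduces every marginal but no
cross-field correlation.

SHI-specific survey fields (employment, income, expenses, difficulty) are
populated only for SHI-insured records, mirroring the survey's reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .demographics import net_household_income
from .params import AgeStratum, CohortMarginals, EconomicParams

NOT_REPORTED = "not_reported"
NONE = "none"

# income bracket bounds (EUR/month) for bracket lookup
INCOME_BRACKET_BOUNDS: Dict[str, tuple[float, float]] = {
    "<1300": (0.0, 1300.0),
    "1300-1700": (1300.0, 1700.0),
    "1701-2600": (1700.0, 2600.0),
    "2601-3600": (2600.0, 3600.0),
    "3601-5000": (3600.0, 5000.0),
    ">5000": (5000.0, float("inf")),
}


@dataclass(frozen=True)
class PatientRecord:
    age: float
    gender: str
    shi_insured: bool
    employment: Optional[str] = None
    income_bracket: Optional[str] = None
    income_loss_bracket: Optional[str] = None
    extra_expense_bracket: Optional[str] = None
    expense_causes: tuple = ()
    financial_difficulty: Optional[str] = None


def _probs(counts: Dict[str, int]) -> tuple[List[str], np.ndarray]:
    labels = list(counts)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("marginal counts must have a positive total")
    return labels, np.array([counts[k] / total for k in labels])


def _age_quantile_sampler(marg: CohortMarginals):
    """Piecewise-linear inverse-CDF through the published age quantiles
    (median and interquartile range), extended linearly to assumed extremes."""
    q = marg.age
    xs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    ys = np.array([q.min, q.q25, q.median, q.q75, q.max])
    return lambda u: np.interp(u, xs, ys)


def generate(
    n: int, seed: int, marginals: CohortMarginals
) -> List[PatientRecord]:
    """Draw ``n`` synthetic survey records matching the published marginals.

    Deterministic per seed.  Expense causes are drawn only for records
    reporting additional expenses (multi-select Bernoulli per cause, with
    rates set by mentions per affected patient, clipped to 1); a record with
    expenses is guaranteed at least one cause.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    age_of = _age_quantile_sampler(marginals)

    g_labels, g_p = _probs(marginals.gender)
    e_labels, e_p = _probs(marginals.employment)
    i_labels, i_p = _probs(marginals.income_bracket)
    l_labels, l_p = _probs(marginals.income_loss_bracket)
    x_labels, x_p = _probs(marginals.extra_expense_bracket)
    f_labels, f_p = _probs(marginals.financial_difficulty)
    p_shi = marginals.n_shi / marginals.n_total

    n_with_expenses = sum(
        c for k, c in marginals.extra_expense_bracket.items()
        if k not in (NONE, NOT_REPORTED)
    )
    cause_labels = list(marginals.expense_cause_mentions)
    cause_p = np.array(
        [
            min(1.0, c / n_with_expenses) if n_with_expenses else 0.0
            for c in marginals.expense_cause_mentions.values()
        ]
    )
    top_cause = cause_labels[int(np.argmax(cause_p))] if cause_labels else None

    records = []
    for _ in range(n):
        age = float(age_of(rng.random()))
        gender = g_labels[rng.choice(len(g_labels), p=g_p)]
        shi = bool(rng.random() < p_shi)
        if not shi:
            records.append(PatientRecord(age=age, gender=gender, shi_insured=False))
            continue
        expense_bracket = x_labels[rng.choice(len(x_labels), p=x_p)]
        causes: tuple = ()
        if expense_bracket not in (NONE, NOT_REPORTED):
            picks = [
                lab for lab, p in zip(cause_labels, cause_p) if rng.random() < p
            ]
            if not picks and top_cause is not None:
                picks = [top_cause]
            causes = tuple(picks)
        records.append(
            PatientRecord(
                age=age,
                gender=gender,
                shi_insured=True,
                employment=e_labels[rng.choice(len(e_labels), p=e_p)],
                income_bracket=i_labels[rng.choice(len(i_labels), p=i_p)],
                income_loss_bracket=l_labels[rng.choice(len(l_labels), p=l_p)],
                extra_expense_bracket=expense_bracket,
                expense_causes=causes,
                financial_difficulty=f_labels[rng.choice(len(f_labels), p=f_p)],
            )
        )
    return records


def records_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    df["expense_causes"] = df["expense_causes"].map(
        lambda c: ";".join(c) if c else ""
    )
    return df


@dataclass(frozen=True)
class CohortSummary:
    """Counts and integer percentages per categorical, survey-table shaped."""

    n_total: int
    n_shi: int
    age_median: float
    age_iqr: tuple
    categoricals: Dict[str, Dict[str, dict]] = field(default_factory=dict)
    cause_mentions: Dict[str, int] = field(default_factory=dict)
    # financial difficulty is additionally reported against the denominator
    # excluding non-responders, as the survey text does
    difficulty_reported_denominator: int = 0

    def percentage(self, field_name: str, category: str) -> int:
        return self.categoricals[field_name][category]["pct"]


def summarize(records: Sequence[PatientRecord]) -> CohortSummary:
    """Survey-table-shaped summary: counts, integer percentages (which may
    not total 100 due to rounding), multi-select causes tallied as mentions."""
    if not records:
        raise ValueError("records must be non-empty")
    shi = [r for r in records if r.shi_insured]
    ages = np.array([r.age for r in records])
    cats: Dict[str, Dict[str, dict]] = {}

    def tally(field_name: str, pop: Sequence[PatientRecord]):
        counts: Dict[str, int] = {}
        for r in pop:
            v = getattr(r, field_name)
            if v is None:
                continue
            counts[v] = counts.get(v, 0) + 1
        total = sum(counts.values())
        cats[field_name] = {
            k: {"count": c, "pct": int(round(100.0 * c / total)) if total else 0}
            for k, c in counts.items()
        }

    tally("gender", records)
    for f_name in (
        "employment", "income_bracket", "income_loss_bracket",
        "extra_expense_bracket", "financial_difficulty",
    ):
        tally(f_name, shi)

    mentions: Dict[str, int] = {}
    for r in shi:
        for cause in r.expense_causes:
            mentions[cause] = mentions.get(cause, 0) + 1

    difficulty_reported = sum(
        1 for r in shi
        if r.financial_difficulty is not None
        and r.financial_difficulty != NOT_REPORTED
    )
    return CohortSummary(
        n_total=len(records),
        n_shi=len(shi),
        age_median=float(np.median(ages)),
        age_iqr=(float(np.quantile(ages, 0.25)), float(np.quantile(ages, 0.75))),
        categoricals=cats,
        cause_mentions=mentions,
        difficulty_reported_denominator=difficulty_reported,
    )


def median_income_bracket(summary: CohortSummary) -> Optional[str]:
    """Bracket containing the median SHI respondent income (non-responders
    excluded), walking the ordered brackets."""
    counts = {
        k: v["count"]
        for k, v in summary.categoricals.get("income_bracket", {}).items()
        if k != NOT_REPORTED
    }
    ordered = [k for k in INCOME_BRACKET_BOUNDS if k in counts]
    total = sum(counts.values())
    if total == 0:
        return None
    half = total / 2.0
    acc = 0
    for k in ordered:
        acc += counts[k]
        if acc >= half:
            return k
    return ordered[-1]


def bracket_of(value: float) -> Optional[str]:
    for label, (lo, hi) in INCOME_BRACKET_BOUNDS.items():
        if lo < value <= hi or (lo == 0.0 and value <= hi):
            return label
    return None


def consistency_check(
    summary: CohortSummary,
    econ: EconomicParams,
    strata: Sequence[AgeStratum],
) -> dict:
    """Descriptive comparison (no hypothesis test) of the model's
    population-based assumptions against the survey cohort.

    Reports whether the modelled net household income falls in the cohort's
    median income bracket (or an adjacent one) and compares the modelled
    employment rate with the cohort's employed share.
    """
    if summary.n_shi == 0:
        return {}
    model_income = net_household_income(strata, econ)
    cohort_bracket = median_income_bracket(summary)
    model_bracket = bracket_of(model_income)
    ordered = list(INCOME_BRACKET_BOUNDS)
    adjacency = None
    if cohort_bracket is not None and model_bracket is not None:
        adjacency = abs(ordered.index(cohort_bracket) - ordered.index(model_bracket))

    emp = summary.categoricals.get("employment", {})
    emp_total = sum(v["count"] for v in emp.values())
    cohort_employed = (
        emp.get("employed", {}).get("count", 0) / emp_total if emp_total else None
    )
    model_employed = econ.employment_rate_mixed
    return {
        "model_net_household_income": model_income,
        "model_income_bracket": model_bracket,
        "cohort_median_income_bracket": cohort_bracket,
        "income_bracket_distance": adjacency,
        "income_consistent": adjacency is not None and adjacency <= 1,
        "model_employment_rate": model_employed,
        "cohort_employed_share": cohort_employed,
        "employment_abs_difference": (
            abs(model_employed - cohort_employed)
            if cohort_employed is not None
            else None
        ),
    }
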