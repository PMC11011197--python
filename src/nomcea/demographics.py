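"""Incidence-weighted income, employment and co-payment derivations.

German rectal-cancer incidence is strongly age-skewed (about two thirds of
new diagnoses are in patients of retirement age), so every population-level
income or employment figure used by the cost model is an incidence-weighted
mean over four age bands.

Two weighting conventions are provided.  ``"exact"`` uses the raw case
counts.  ``"printed"`` reproduces the two-stage published computation, in
which the incidence shares were first rounded to one-decimal percentages
and the smallest band (below 0.5 % of cases) was dropped; the conventions
differ by about 1 EUR on the weighted gross income.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Literal, Sequence

import pandas as pd

from .params import AgeStratum, EconomicParams

Weighting = Literal["exact", "printed"]


def incidence_weights(
    strata: Sequence[AgeStratum], weighting: Weighting = "exact"
) -> Dict[str, float]:
    """Fraction of incident cases per age band.

    ``exact`` weights are ``cases / total`` and sum to 1 to machine
    precision.  ``printed`` weights are rounded to one-decimal percentages,
    with bands below 0.5 % of cases set to zero (the published convention).
    """
    if not strata:
        raise ValueError("at least one age stratum is required")
    total = sum(s.cases for s in strata)
    if total <= 0:
        raise ValueError("total case count must be positive")
    exact = {s.label: s.cases / total for s in strata}
    if weighting == "exact":
        return exact
    if weighting == "printed":
        return {
            label: (0.0 if w < 0.005 else round(100.0 * w, 1) / 100.0)
            for label, w in exact.items()
        }
    raise ValueError(f"unknown weighting {weighting!r}")


def weighted_mean(
    strata: Sequence[AgeStratum],
    field: Literal["employment_rate", "gross_income_monthly"],
    weighting: Weighting = "exact",
) -> float:
    """Incidence-weighted mean of an age-band field.

    The result always lies between the smallest and largest stratum value.
    """
    weights = incidence_weights(strata, weighting=weighting)
    values = {}
    for s in strata:
        v = getattr(s, field, None)
        if v is None:
            raise ValueError(f"stratum {s.label!r} lacks field {field!r}")
        values[s.label] = float(v)
    wsum = sum(weights.values())
    return sum(weights[lab] * values[lab] for lab in weights) / wsum


def copay_exemption_limit(
    gross_income_monthly: float,
    household_size: int,
    allowance_per_person: float,
    rate: float,
) -> float:
    """Annual out-of-pocket co-payment cap.

    The statutory rule: ``rate`` (2 % generally, 1 % for chronic disease)
    of annual gross household income after deducting a personal allowance
    per additional household member beyond the insured person.  Floored at
    zero when allowances exceed income.

    The deduction applies to the ``household_size - 1`` additional members
    plus one partner allowance convention; here the published arithmetic
    (two-person household, one allowance per person) is followed literally:
    ``(12 * gross - household_size * allowance) * rate``.
    """
    if gross_income_monthly < 0 or allowance_per_person < 0:
        raise ValueError("incomes and allowances must be non-negative")
    if household_size < 1:
        raise ValueError("household size must be at least 1")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be a fraction in [0, 1]")
    base = 12.0 * gross_income_monthly - household_size * allowance_per_person
    return max(0.0, base) * rate


def pension_is_taxed(econ: EconomicParams) -> bool:
    """Whether the taxable share of the annual pension exceeds the personal
    tax allowance (if not, the pension passes to net income untaxed)."""
    taxable = econ.pension_taxable_fraction * 12.0 * econ.pension_monthly
    return taxable > econ.tax_allowance_annual

def net_household_income(
    strata: Sequence[AgeStratum],
    econ: EconomicParams,
    weighting: Weighting = "exact",
) -> float:
    """Blended monthly net household income of the modelled cohort.

    Employment-rate-weighted mix of two household types:

    * working households at the general-population average net household
      income;
    * retired households at ``household_size x pension`` — the average
      pension is below the tax allowance (80 % taxable share), so it passes
      to net income untaxed.

    With the default profile this reproduces the published 2580 EUR/month.
    """
    rate = weighted_mean(strata, "employment_rate", weighting=weighting)
    pension_net = econ.pension_monthly
    if pension_is_taxed(econ):
        # only the allowance-exceeding taxable share would attract tax; a
        # full tax schedule is out of scope, so flag by simple truncation
        raise NotImplementedError(
            "pension exceeds the tax allowance; a net-of-tax pension rule "
            "is not implemented (not needed for the default profile)"
        )
    retired_household = econ.household_size * pension_net
    working_household = econ.net_household_income_general_monthly
    return rate * working_household + (1.0 - rate) * retired_household


def summary_table(
    strata: Sequence[AgeStratum], econ: EconomicParams
) -> pd.DataFrame:
    """Income and co-payment summary of the derived quantities (one row per
    quantity, with the weighting convention used)."""
    rows: List[dict] = []
    for weighting in ("exact", "printed"):
        emp = weighted_mean(strata, "employment_rate", weighting=weighting)
        inc = weighted_mean(strata, "gross_income_monthly", weighting=weighting)
        rows.append(
            {
                "weighting": weighting,
                "employment_rate": emp,
                "gross_income_monthly": inc,
                "net_household_income_monthly": net_household_income(
                    strata, econ, weighting=weighting
                ),
                "copay_limit_general_annual": copay_exemption_limit(
                    inc, econ.household_size,
                    econ.personal_allowance_per_person, econ.copay_rate_general,
                ),
                "copay_limit_chronic_annual": copay_exemption_limit(
                    inc, econ.household_size,
                    econ.personal_allowance_per_person, econ.copay_rate_chronic,
                ),
            }
        )
    return pd.DataFrame(rows)
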