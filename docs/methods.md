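# Methods

This note documents the model, its assumptions, the parameters that matter,
and the design choices made where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The decision problem

Two strategies for stage-III low rectal cancer after neoadjuvant treatment
are compared from the patient's financial perspective under German
statutory health insurance (SHI):

* **NOM** — total neoadjuvant therapy (long-course chemoradiation plus
  consolidation chemotherapy) followed by watch-and-wait in complete
  responders, with intensified surveillance; resection only at local
  regrowth.
* **RESECTION** — chemoradiotherapy, abdominoperineal resection with
  definitive ostomy (16 inpatient nights; distal tumours are assumed, so
  sphincter preservation is not available), adjuvant chemotherapy.

Effectiveness is measured in QALYs (state utilities 0–1 per year of
occupancy), costs in EUR borne by the patient. Both are discounted at
3.5 %/year and compared via ICER and net monetary benefit at a
willingness-to-pay of 6000 EUR per QALY (interpreted per QALY; this is the
only reading under which the published NMB arithmetic is internally
consistent).

## Markov engine

Six states: stable (A), stable after successful salvage (B), local
recurrence (C), distant recurrence (D), local + distant recurrence (E),
death (F, absorbing). Five cycles of one year. The implemented arrow set
is the minimal one consistent with the published transition inputs:
A→C/D/E/F, C→B/E/F, D→B/E/F, B→C/F, E→F, self-loops, F absorbing.

**Annualization.** Inputs are cumulative risks at 2/3/5-year anchors.
Within each inter-anchor interval the hazard is constant:
`p_annual = 1 - ((1-p_hi)/(1-p_lo))^(1/(t_hi-t_lo))`; beyond the last
anchor the final interval's hazard is carried forward. This is the
standard actuarial conversion; the sources give anchors only.

**Row composition.** Competing exits from a state are summed from branch
probabilities; other-cause mortality (0.02/year) is composed
multiplicatively as an additional exit everywhere except from death. If
the exits exceed 1 the row is renormalized (a warning is logged when the
excess is more than 0.25 — parameter tension, not an error); otherwise the
residual is "remain in state".

**Recurrence pathways.** A local or distant event from the stable state
routes to the combined state E with the published conditional
co-occurrence probabilities (distant-given-local, local-given-distant).
Successful salvage routes C→B (probability 0.94 NOM / 0.59 resection) and
D→B (metastasectomy, 0.57). Perioperative mortality (0.04) applies at
entry for the resection arm and at salvage resection in the NOM arm
(configurable to both arms via `perioperative_death_at_salvage`).

**Where the post-salvage mortality acts.** The published 5-year
mortalities after local recurrence (0.5 salvaged / 0.7 unsalvaged) and
after distant or combined recurrence (0.8) are annualized and charged *at
the recurrence states themselves* (C/D/E exits to F), weighted by the
salvage probability; the post-salvage stable state B carries background
mortality plus re-recurrence risk (0.13 at 5 years, annualized) only. The
design was open: letting the salvaged-recurrence mortality persist in B
instead pushes 5-year overall mortality to ~19 % (NOM) / ~22 % (resection),
outside the ±2-percentage-point calibration band around the trial-reported
15 % / 20 %; charging it at the recurrence state yields ~16.7 % / ~20.3 %,
inside the band for both arms. The parameter `distant_after_local_3y`
(0.11) is carried in the containers but unused by this arrow set (B→D is
not an arrow); it is retained for completeness.

**Accounting.** Cycle accruals use end-of-cycle occupancy, discounted by
`(1+r)^-t`, with no half-cycle correction (exposed as a config switch,
default off — the simplest auditable convention). The "initial state"
utility (0.80 NOM / 0.61 resection) applies to state A in cycle 1 only;
long-term stable utilities thereafter. State B uses the salvage-surgery
utility (0.70).

**Microsimulation.** `run_microsim` samples n independent trajectories
from the per-cycle matrix rows with one seeded `numpy` generator
(inverse-CDF sampling vectorized over patients) and applies accounting
identical to the deterministic cohort. Runs are bit-reproducible per seed.
The default n = 100,000 finishes in well under a second; the test suite
checks every state/cycle occupancy against the deterministic expectation
within 3·sqrt(p(1−p)/n).

## Demographics

Income and employment quantities are incidence-weighted means over four
age bands (cases 14 / 460 / 5807 / 11,614; total 17,895). Two weighting
conventions are implemented: `exact` (raw counts; weights sum to 1 to
machine precision) and `printed` (shares rounded to one-decimal
percentages with the <0.5 % band dropped — the two-stage convention under
which the published weighted gross income of 4409 EUR reproduces; the
exact convention gives 4407.9 EUR). The weighted employment rate is
28.2 % under either convention.

The blended net household income has no published formula; it is
reconstructed as an employment-rate mix of two household types — working
households at the general-population average net household income
(3813 EUR/month) and retired households at household-size × pension
(2 × 1048 EUR, which passes untaxed because 80 % of the annual pension is
below the 10,347 EUR personal tax allowance). The default profile
reproduces the published 2580 EUR/month to within 1 EUR. This
construction, not a tax calculator, is the model's net-from-gross rule;
the conversion inputs are exposed in the config.

Co-payment exemption limits follow
`(12 × gross − household_size × allowance) × rate`, giving 821.28 EUR
(general, 2 %) and 410.64 EUR (chronic, 1 %) annually. These are annual
caps: the published table labels them per month, but the defining rule and
the arithmetic only reconcile as per-year values.

## Cost model

Annual cost per state, strategy and employment scenario is the sum of four
non-negative components:

| component | rule |
|---|---|
| co-payments | 10 EUR/unit + inpatient nights at 10 EUR capped at 280 EUR/yr, all capped by the exemption limit (2 % in the primary-treatment year, 1 % in follow-up years and recurrence states); state E is pinned at the chronic limit (continuous therapy) |
| driving | covered therapy series (chemoradiation, chemotherapy): 5 EUR taxi co-pay for first and last drive only; uncovered follow-up visits: round-trip mileage 2 × 26.3 km × 0.2 EUR/km = 10.52 EUR/visit |
| supplements | 10 EUR/month for ostomy-care products / non-prescription medication, for ostomy carriers (resection always; either arm after salvage APR) |
| loss of income | retired: 0; employed: 30 % of gross weekly income per absence week beyond 6, capped at 72 weeks; permanent disability (state E): personal net income (gross × net-conversion factor 0.65, assumed) minus the 925 EUR reduced-earning-capacity pension, per month; mixed: employed value × 28.2 % |

Costs accrue at the state occupied during the cycle; primary-treatment
costs (therapy series, primary inpatient stay, initial absence) attach to
state A in cycle 1. Expected supportive inpatient nights from grade-3/4
toxicity (probability × 7 nights, assumed) enter the first-year co-payment
as an expectation.

**Assumed, calibrated defaults.** The sources defer per-state visit
counts and absence durations to an appendix not available here, so they
are declared in the config's `assumptions` block and echoed in every cost
report: watch-and-wait surveillance at 8 visits/year in years 1–2
(contact every ~3 months including endoscopy and imaging appointments)
and 4/year thereafter, post-resection follow-up at 2/2/1/1/1; absence 8
weeks (NOM primary), 16 weeks (resection primary), 26 weeks (salvage or
metastasectomy year); co-payment units 5 (treatment year), 1/6
(NOM/resection follow-up years), 10 (recurrence years); salvage resection
16 inpatient nights. Under these defaults the structural cost claims hold:
resection totals exceed NOM totals in every scenario, employed > mixed >
retired within each strategy, driving is the largest stable-state
component for NOM except in the employed scenario (income loss), and
ostomy/medication supplements plus the longer absence raise resection
totals. **Absolute aggregate totals are sensitive to these assumptions and
are not claimed to reproduce any published totals**; only the orderings
above are asserted.

## Synthetic survey cohort

`cohort.generate` draws records matching the published marginals of the
44-patient reference survey (86 % SHI-insured; employment, income, loss,
expense and difficulty brackets among the 38 SHI patients). Age is drawn
from a piecewise-linear inverse CDF through the published quantiles
(median 67, IQR 58–75) extended to assumed extremes (30, 90). Fields are
drawn independently — only marginals are published, so no cross-field
correlation is emulated, and passing marginal-recovery tests says nothing
about joint structure in real data. Multi-select expense causes are
Bernoulli per cause at mentions-per-affected-patient rates (clipped to 1;
at least one cause is forced when expenses are reported, since the
mentions outnumber the affected patients). "Not reported" is an explicit
category throughout, never imputed. The financial-difficulty summary
reports both the all-SHI denominator and the respondents-only denominator,
since the source uses both.

The consistency report is descriptive only (the source performed no test):
the modelled 2580 EUR/month falls inside the cohort's median income
bracket (1701–2600 EUR), and the modelled 28.2 % employment rate sits a
few points below the cohort's 32 % employed share.

## Numerical choices and degenerate inputs

* Thresholds are computed in closed form (NMB is affine in cost and
  effectiveness); `qaly_threshold(cost_threshold(e)) == e` to 1e-9.
* Equal effectiveness makes the ICER undefined: reported as `None` with a
  dominance classification, never an exception.
* A negative cost threshold or a QALY threshold above 5 (the 5-year
  maximum) is reported with `feasible=False`, not clamped.
* Monetary values are carried at full precision; renderers round to whole
  EUR; QALY thresholds are additionally rendered at 2 decimals.
* `annualize(1.0, h)` is rejected (infinite hazard); cumulative maps must
  be non-decreasing and survival maps non-increasing at load time.
* Probability/monetary validation happens once, in the pydantic layer;
  unknown config keys are rejected.

## Known limitations

* The five-year horizon ignores costs and QALYs beyond year 5, where the
  ostomy-related cost difference would keep growing.
* Absolute patient-cost totals depend on the assumed schedules above;
  treat them as scenario outputs, not point estimates.
* The published comparison table's employed/retired ICER cells are
  internally inconsistent with the ICER definition applied to their own
  rows (the two values appear swapped); this package computes ICERs from
  the definition and its tests assert the arithmetic, not those two cells.
* Transition parameters are pooled from heterogeneous trial populations;
  the row-renormalization convention spreads any excess hazard
  proportionally, which is a modelling choice, not an estimate.
* German SHI rules only; no private insurance, no payer perspective, no
  probabilistic sensitivity analysis (one-way only, matching the design).
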