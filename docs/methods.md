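# Methods

## Model structure and assumptions

The disease course of first-line DLBCL therapy is represented by three
mutually exclusive states — progression-free, progressive, death — on a
3-week cycle grid, matching the chemotherapy course interval. The
cohort (average entry age ≥ 55) starts fully progression-free.
Structural assumptions, all deliberate simplifications of the clinical
pathway:

* no remission return: progressive patients never re-enter the
  progression-free state, and second-line regimens (ICE/DHAP) are not
  modelled as separate states — their costs are folded into the
  progressive-state cost profile;
* death is a single absorbing state; background mortality is the single
  life-table probability 0.004/year, age-constant by default (an
  age-indexed mortality-table hook exists in `calibrate` but is off,
  because the evidence base provides only the single number);
* transition hazards are constant within and across cycles
  (exponential survival between anchors);
* full treatment compliance; no dropouts or delayed courses.

"Lifetime" is operationalized as 1200 cycles (≈ 69 years) with early
termination once death occupancy reaches 1 − 1e-6. One cycle is
3/52.1786 = 0.057495 years (365.25-day year).

## Calibration policies

The evidence tables print baseline transition probabilities (0.370
progression, 0.004 background death, 0.001 progressive death) without a
time basis, so the mapping onto the cycle grid is an explicit policy:

* `as_printed_per_cycle` — take them as 3-week-cycle probabilities;
* `annual_to_cycle` — treat them as annual and rescale via
  r = −ln(1−p)/t, p = 1 − e^(−rt);
* `anchor_to_cycle` (default) — ignore the printed progression and
  progressive-death values and derive hazards from the randomized-trial
  survival anchors: the 2-year event-free survival (CHOP 38%) gives the
  progression-free exit hazard, background mortality is subtracted to
  isolate the progression hazard, and the 2-year overall survival
  (CHOP 57%) gives the progressive→death hazard.

The anchor policy is the default because the printed probabilities are
not jointly interpretable on any single time basis: progressive→death =
0.001 implies a mean post-progression survival of ~1000 years if annual
(~57 years if per-cycle), which explodes lifetime life-years to ~30
discounted years in both arms and contradicts the trial's 57% two-year
overall survival. The 2-year anchors are used because the relative
risks are reported at that follow-up. All three policies remain
config-switchable, and every intermediate rate is recorded in the
calibration report.

The treated arm applies RR = 0.55 to the progression hazard and
RR = 0.53 to the progressive-death hazard, on the hazard scale
(p′ = 1 − (1−p)^RR), which keeps probabilities in [0,1] for any
positive RR and is consistent with the constant-hazard framework.
Background mortality is arm-independent.

## Economics

Costs are 2019 USD (1 USD = IDR 14,000, metadata only), per 3-week
cycle, split into direct medical (DMC), drug, direct non-medical (DNMC)
and indirect (IC) components per state and arm; the CHOP arm's
progressive-state DMC reuses its progression-free value, and DNMC/IC
are shared across arms, as the evidence table declares. Each arm's drug
cost is its own column's value (rituximab 643.0/563.4 per cycle for the
combination arm; 50.7 for chemotherapy alone); the chemotherapy
backbone is not added on top of the rituximab figure, since the source
table does not combine them. Historical billing years are inflated to
2019 through a CPI series; the bundled 2015–2019 series (100 → 114) is
a synthetic representative path at ≈3.3%/year, not official statistics.

Accumulation is trapezoidal: effective occupancy for cycle k is the
mean of boundary rows k and k+1 (the named half-cycle correction,
method chosen here), discounted at the cycle midpoint with discrete
annual compounding, (1+r)^(−t), r = 3% for both costs and effects;
with the correction off, membership and discounting use the cycle
start. The drug component accrues only during the first 8 cycles (the
formulary's maximum course length) by default; DMC/DNMC/IC accrue for
the full time alive in state. The cap is configurable including `None`
(lifetime drug dosing), but lifetime rituximab is clinically wrong and
was rejected as a default. Death carries zero cost and utility.

ICER quadrant logic: cheaper-and-better is "dominant",
dearer-and-worse "dominated"; equal effects never divide (label
instead); zero incremental cost with positive gain yields a numeric
ICER of 0. Cost-effectiveness at threshold λ means dominance or
ΔE > 0 with ΔC/ΔE ≤ λ.

## Probabilistic sensitivity analysis

Each of 1000 iterations resamples: the anchor event probabilities and
background mortality (Beta, mean = point value, effective sample size
`ess`), both relative risks (log-normal, point = median, log-SD from
the 95% CI), ten cost components (Gamma, moment-matched) and two
utilities (Gamma as the evidence table declares — Beta would be
conventional — clipped to [0,1]). Components declared shared are drawn
once per iteration and reused across arms/states so they cancel in the
increments. Draws producing invalid transition rows are resampled
rather than clipped (avoiding boundary atoms), with a count reported.
Everything is driven by one seeded `numpy` generator: identical seeds
give bitwise-identical draw tables.

The evidence base gives **no dispersion** for the Beta-distributed
probabilities; `ess = 1000` is the default and the acceptability
probability's sensitivity to it is emitted by the test suite
(`results/psa_ess_sensitivity.csv`). The CEAC grid is 0–30,000
USD/QALY in steps of 250, always containing 3,846 / 7,692 / 11,538.

## Budget impact

Payer perspective (drug + direct medical cost only), undiscounted, five
years — standard budget-impact convention. Per-patient annual costs are
per-cycle values × 8 cycles (one course fits within a year). Scenarios:
full price, −10/25/50/75% drug price, and chemotherapy-only. The real
projection requires the payer's unpublished prevalence/incidence claim
counts; the bundled population (~1000 treated patients/year, 5% annual
growth including a 25% prevalent carry-over) is synthetic, sized only
to land totals in the published tens-of-millions-USD magnitude. Only
structural properties (scenario ordering, linearity in population,
chemotherapy-only floor) are meaningful, and only those are tested.

## Synthetic patient-level data

The generator emulates the study's primary data: 54 + 6 per-visit
billing records with Gamma dispersion moment-matched to the per-state
cost summaries (drawn at 2019 price level, deflated to a random
2015–2018 billing year so CPI re-adjustment recovers the targets
exactly in expectation), and 41 + 5 EQ-5D-5L questionnaires whose
five dimension levels follow 1 + Binomial(4, s) with the per-state
severity s solved by bisection so the value-set-mapped expected utility
equals the state target (0.74 / 0.48). A VAS score is generated but
unused. The bundled value set is an explicitly synthetic additive
decrement stub (full health = 1.0, worst profile = −0.6), NOT the
Indonesian tariff, and is swappable via a coefficient table.

What the synthetic data do not emulate: real billing-system export
formats, within-patient longitudinal cost correlation, dimension-level
response patterns of the actual interview sample (only the utility
means are constrained). Passing pipeline-recovery tests therefore show
estimator/model consistency, not fidelity to the unpublished hospital
data.

## Reproduction of the published results, and why it fails

The published deterministic base case is internally inconsistent, and —
more fundamentally — unreachable from its own printed inputs:

* the narrative and the results table swap 4.06/4.18 between arms and
  outcome measures, and printed ΔC/ΔQALY (10,916/1.18 = 9,251) differs
  from the printed 9,280;
* the chemotherapy arm's printed lifetime cost (USD 94,931 over ≤ 4.18
  discounted LY) requires ≥ USD 22,700 per alive-year, while that arm's
  printed per-cycle costs cap at ≈ USD 13,700 per alive-year — no
  calibration can bridge this;
* printed ΔC = 10,916 with ΔLY = 2.33 implies ≈ USD 4,700 per added
  life-year, below the cheapest alive state's annual cost (≈ 11,500),
  impossible unless survivors accrue almost no cost — contradicting the
  ~100k lifetime totals.

Under the documented default calibration this package obtains ICERs of
≈ 31,500 USD/QALY and ≈ 18,600 USD/LYG (CHOP QALY 2.90 lands within
~3.5% of the published 3.00; the other published figures do not), and a
PSA acceptability of ≈ 14% at 11,538 USD/QALY versus the published
~65% — the gap is driven by the deterministic cost structure, not by
PSA settings. The full computed-vs-published comparison is emitted to
`results/base_case_discrepancy.csv` by the test suite, and the
corresponding acceptance tests are expected to fail until the original
model's exact cost-accrual rules become available.

## Numerical choices

Row-stochasticity is enforced at 1e-12 on matrices and 1e-9 on traces;
`log1p`/`expm1` are used in the hazard conversions for small-probability
accuracy; prob↔rate round-trips hold to 1e-12; sample SDs use the n−1
denominator; file outputs are plain CSV/JSON with units in headers, and
a manifest (config digest, seeds, policy, version) stamps every run
directory.
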