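# dlbclcea

Cost-utility and budget impact modelling of adding rituximab to CHOP
chemotherapy (R-CHOP vs CHOP) for diffuse large B-cell lymphoma (DLBCL)
in the Indonesian national health-insurance setting.

The package is aimed at health-economics analysts and methods
researchers who want a fully tested, scriptable re-implementation of a
published Indonesian HTA decision model — to audit its assumptions, vary
its calibration, or reuse the machinery (Markov cohort engine, PSA,
budget projection) for similar oncology appraisals.

## The model

A three-state Markov cohort model on a 3-week cycle grid (one
chemotherapy course interval):

```
progression-free ──p_pf→prog──▶ progressive ──p_prog→death──▶ death
        └──────────p_pf→death (background mortality)──────────▶
```

Death is absorbing and there is no remission return. Per-cycle
transition probabilities come from trial survival fractions S(t) through
the constant-hazard pair

    r = −ln(1 − p) / t,    p = 1 − e^(−r·t)

and the rituximab effect enters as relative risks applied on the hazard
scale, p′ = 1 − (1 − p)^RR (RR = 0.55 on progression, 0.53 on
post-progression death). Lifetime discounted totals per arm are

    Cost  = Σ_k d(t_k) · x_k · c,     QALY = Σ_k d(t_k) · x_k · u · Δt

with half-cycle-corrected occupancy x_k, per-cycle state costs c (four
societal components: direct medical, drug, direct non-medical,
indirect), state utilities u (EQ-5D-5L-derived: 0.74 progression-free,
0.48 progressive), and discrete annual discounting d(t) = 1.03^(−t).
The decision statistic is the ICER ΔC/ΔE judged against 1–3× GDP per
capita (USD 3,846–11,538 per QALY). Uncertainty is handled by
Monte-Carlo PSA (Beta / Gamma / log-normal parameter distributions) with
a cost-effectiveness acceptability curve, and affordability by a
five-year payer budget projection under drug-price-reduction scenarios.

## Worked example

```python
from dlbclcea import default_parameters, run_base_case
result = run_base_case(default_parameters())
```

or `python examples/01_base_case.py`, which prints:

```
arm      cost(USD)   LY      QALY   (discounted at 3%)
R-CHOP      122,303   8.35   4.88
CHOP         59,672   4.98   2.90

incremental cost :     62,632 USD
incremental QALY :       1.99
ICER             :     31,543 USD/QALY
ICER             :     18,580 USD/LYG
```

Adding rituximab buys 3.37 discounted life years (1.99 QALYs) per
patient at an extra lifetime cost of USD 62.6k, i.e. USD 31.5k per QALY
under the default calibration — above the 3×GDP willingness-to-pay
threshold of USD 11,538/QALY. Note this differs from the originally
published verdict; `docs/methods.md` explains why the published
base-case numbers cannot be recovered from the published inputs and
what the discrepancy table shows. The other examples cover the PSA/CEAC
(`02`), the budget projection (`03`) and the synthetic patient-level
pipeline (`04`); a thin CLI (`dlbclcea run-base-case|run-psa|run-bia|
simulate-data|all-in-one`) wraps the same entry points for shell use.

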