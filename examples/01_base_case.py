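"""Base case: lifetime costs, life years, QALYs and ICERs for both arms.

Builds the default evidence base (trial survival anchors, relative
risks, per-state cost and utility summaries), calibrates per-cycle
transition matrices for each arm, runs the Markov cohort over a
lifetime horizon of 3-week cycles, and prints discounted totals and the
incremental cost-effectiveness ratios against the 3x GDP-per-capita
willingness-to-pay threshold.
"""

from dlbclcea import default_parameters, gdp_threshold
from dlbclcea.reporting import run_base_case

params = default_parameters()
result = run_base_case(params)

print("arm      cost(USD)   LY      QALY   (discounted at 3%)")
for arm in ("R-CHOP", "CHOP"):
    s = result.summaries[arm]
    print(f"{arm:8s} {s.total_cost:10,.0f}  {s.life_years:5.2f}  {s.qalys:5.2f}")

print(f"\nincremental cost : {result.icer_qaly.delta_cost:10,.0f} USD")
print(f"incremental QALY : {result.icer_qaly.delta_effect:10.2f}")
print(f"ICER             : {result.icer_qaly.icer:10,.0f} USD/QALY")
print(f"ICER             : {result.icer_lyg.icer:10,.0f} USD/LYG")
threshold = gdp_threshold(params.gdp_per_capita, 3)
print(f"\nat 3x GDP per capita ({threshold:,.0f} USD/QALY) the rituximab")
print(f"combination is {'cost-effective' if result.verdicts[3] else 'NOT cost-effective'}")
print("\nA lower ICER means each extra quality-adjusted life year from")
print("adding rituximab costs the health system less.")
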