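"""Probabilistic sensitivity analysis and the acceptability curve.

Samples every uncertain parameter from its distribution (Beta for
probabilities, Gamma for costs and utilities, log-normal for relative
risks), reruns the whole model 1000 times, and summarizes the
incremental cost-effectiveness plane and the probability that the
rituximab combination is cost-effective across willingness-to-pay
thresholds.
"""

from dlbclcea import ceac, default_parameters, gdp_threshold, run_psa

params = default_parameters()
result = run_psa(params, n_iterations=1000, seed=7)
draws = result.draws

print(f"iterations: {result.n_iterations}, invalid draws resampled: {result.resampled}")
print(
    "incremental cost : "
    f"mean {draws['delta_cost'].mean():,.0f} USD "
    f"(2.5-97.5%: {draws['delta_cost'].quantile(0.025):,.0f} to "
    f"{draws['delta_cost'].quantile(0.975):,.0f})"
)
print(
    "incremental QALY : "
    f"mean {draws['delta_qaly'].mean():.2f} "
    f"(2.5-97.5%: {draws['delta_qaly'].quantile(0.025):.2f} to "
    f"{draws['delta_qaly'].quantile(0.975):.2f})"
)

curve = ceac(draws)
for mult in (1, 2, 3):
    thr = gdp_threshold(params.gdp_per_capita, mult)
    print(
        f"P(cost-effective at {mult}x GDP = {thr:7,.0f} USD/QALY): "
        f"{curve.at(thr):.1%}"
    )
print("\nEach probability is the fraction of simulations in which the net")
print("monetary benefit (threshold x dQALY - dCost) is non-negative.")
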