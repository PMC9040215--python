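"""Full pipeline on synthetic patient-level data.

Generates study-sized synthetic hospital billing records (54
progression-free + 6 progressive patients) and EQ-5D-5L interview
responses (41 + 5), re-estimates the per-state cost and utility
summaries from them, plugs the estimates into the model, and compares
the resulting ICER with the one built directly from the published
summaries — demonstrating the generate -> estimate -> calibrate -> run
loop end to end.
"""

from dlbclcea import (
    CostComponent,
    StateCostProfile,
    StateCosts,
    UtilityProfile,
    default_parameters,
)
from dlbclcea.reporting import run_base_case
from dlbclcea.synthetic import (
    estimate_state_parameters,
    estimate_utilities,
    generate_cost_records,
    generate_eq5d_records,
)

params = default_parameters()
targets = {
    "progression_free": params.costs["R-CHOP"].progression_free,
    "progressive": params.costs["R-CHOP"].progressive,
}

costs = generate_cost_records(54, 6, targets, cpi=params.cpi, seed=7)
eq5d = generate_eq5d_records(41, 5, seed=11)
print(f"generated {len(costs)} cost records and {len(eq5d)} EQ-5D responses")

est = estimate_state_parameters(costs, cpi=params.cpi)
est_u = estimate_utilities(eq5d)
print("\nre-estimated summaries (mean +/- SD, 2019 USD):")
print(est.to_string(index=False))
print(est_u.to_string(index=False))


def cell(state, comp):
    row = est[(est["state"] == state) & (est["component"] == comp)].iloc[0]
    return CostComponent(row["mean"], row["sd"])


fitted = default_parameters()
fitted.costs = dict(fitted.costs)
fitted.costs["R-CHOP"] = StateCostProfile(
    arm="R-CHOP",
    progression_free=StateCosts(
        **{c: cell("progression_free", c) for c in ("dmc", "drug", "dnmc", "ic")}
    ),
    progressive=StateCosts(
        **{c: cell("progressive", c) for c in ("dmc", "drug", "dnmc", "ic")}
    ),
)
u = {row["state"]: row["mean"] for _, row in est_u.iterrows()}
fitted.utilities = UtilityProfile(
    progression_free=u["progression_free"], progressive=u["progressive"]
)

direct = run_base_case(params)
refit = run_base_case(fitted)
print(f"\nICER from published summaries : {direct.icer_qaly.icer:,.0f} USD/QALY")
print(f"ICER from synthetic-data refit: {refit.icer_qaly.icer:,.0f} USD/QALY")
print("\nThe gap is pure sampling noise from the study-sized (n=60/n=46)")
print("synthetic samples; it shrinks as the generated cohorts grow.")
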