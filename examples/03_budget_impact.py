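"""Five-year payer budget projection under drug-price scenarios.

Uses a SYNTHETIC national treated-patient projection (the real payer
claim counts are unpublished) and the default per-cycle cost profiles
to compare six scenarios: rituximab at current price, at 10/25/50/75%
price reductions, and a chemotherapy-only benefit package.
"""

from dlbclcea import (
    DEFAULT_SCENARIOS,
    annual_payer_costs,
    default_parameters,
    project_budget,
    scenario_table,
    synthetic_population,
)

params = default_parameters()
population = synthetic_population()
payer = annual_payer_costs(params.costs["R-CHOP"], params.costs["CHOP"])

print("synthetic population (treated patients/year):",
      [int(t) for t in population.treated])
print(f"per-patient annual drug cost   : {payer.drug_cost:8,.0f} USD")
print(f"per-patient annual medical cost: {payer.medical_cost:8,.0f} USD\n")

results = [project_budget(population, sc, payer) for sc in DEFAULT_SCENARIOS]
table = scenario_table(results)
for _, row in table.iterrows():
    print(
        f"{row['scenario']}: {row['five_year_total_usd'] / 1e6:6.2f} M USD "
        f"({row['regimen']}, drug price x{row['drug_price_multiplier']:.2f})"
    )
print("\nTotals fall monotonically with the price reduction; the")
print("chemotherapy-only package is the payer's floor. Absolute levels")
print("scale linearly with the (synthetic) patient counts.")
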