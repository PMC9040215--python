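"""Five-year payer-perspective budget impact projection.

From the payer's point of view (the national single payer, BPJS) the
relevant spend per treated patient-year is drug acquisition plus direct
medical cost — no non-medical or productivity costs. Scenarios vary the
drug price (full price, then 10/25/50/75% reductions) or substitute the
chemotherapy-only regimen entirely; totals are undiscounted, following
standard budget-impact practice.

The published projection is driven by unpublished insurance claim
counts, so absolute totals are not reproducible; a clearly labelled
synthetic population ships as the default input instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import StateCostProfile

__all__ = [
    "PopulationProjection",
    "BudgetScenario",
    "PayerCostInputs",
    "BudgetResult",
    "DEFAULT_SCENARIOS",
    "synthetic_population",
    "annual_payer_costs",
    "project_budget",
    "scenario_table",
]


@dataclass(frozen=True)
class PopulationProjection:
    """Treated patient counts per projection year (1..n)."""

    years: tuple
    prevalent: tuple
    incident: tuple

    def __post_init__(self) -> None:
        if not (len(self.years) == len(self.prevalent) == len(self.incident)):
            raise ValueError("years, prevalent and incident must align")
        if any(p < 0 for p in self.prevalent) or any(i < 0 for i in self.incident):
            raise ValueError("patient counts must be non-negative")
        if list(self.years) != list(range(self.years[0], self.years[0] + len(self.years))):
            raise ValueError("projection years must be consecutive")

    @property
    def treated(self) -> np.ndarray:
        return np.asarray(self.prevalent, dtype=float) + np.asarray(
            self.incident, dtype=float
        )

    def scaled(self, factor: float) -> "PopulationProjection":
        return PopulationProjection(
            years=self.years,
            prevalent=tuple(p * factor for p in self.prevalent),
            incident=tuple(i * factor for i in self.incident),
        )


def synthetic_population(
    start_year: int = 1,
    n_years: int = 5,
    incident_start: float = 800.0,
    growth: float = 0.05,
    prevalent_fraction: float = 0.25,
) -> PopulationProjection:
    """SYNTHETIC stand-in population for the unpublished claim counts.

    Roughly sized so that national five-year totals land in the
    tens-of-millions USD range: ~800 newly treated DLBCL patients per
    year growing 5%/year, plus a 25% carry-over of prevalent patients
    still on therapy.
    """
    incident = [incident_start * (1 + growth) ** k for k in range(n_years)]
    prevalent = [round(i * prevalent_fraction, 1) for i in incident]
    return PopulationProjection(
        years=tuple(range(start_year, start_year + n_years)),
        prevalent=tuple(prevalent),
        incident=tuple(round(i, 1) for i in incident),
    )


@dataclass(frozen=True)
class BudgetScenario:
    """A drug-price multiplier scenario (or chemotherapy-only substitution)."""

    label: str
    drug_price_multiplier: float = 1.0
    regimen: str = "R-CHOP"  # or "CHOP-only"

    def __post_init__(self) -> None:
        if not 0.0 <= self.drug_price_multiplier <= 1.0:
            raise ValueError("drug price multiplier must lie in [0, 1]")
        if self.regimen not in ("R-CHOP", "CHOP-only"):
            raise ValueError("regimen must be 'R-CHOP' or 'CHOP-only'")


DEFAULT_SCENARIOS = (
    BudgetScenario("S1", 1.00),
    BudgetScenario("S2", 0.90),
    BudgetScenario("S3", 0.75),
    BudgetScenario("S4", 0.50),
    BudgetScenario("S5", 0.25),
    BudgetScenario("S6", 1.00, regimen="CHOP-only"),
)


@dataclass(frozen=True)
class PayerCostInputs:
    """Per-patient annual payer costs (USD/patient-year)."""

    drug_cost: float
    medical_cost: float
    chop_drug_cost: float = 0.0

    def __post_init__(self) -> None:
        if min(self.drug_cost, self.medical_cost, self.chop_drug_cost) < 0:
            raise ValueError("payer costs must be non-negative")


def annual_payer_costs(
    rchop: StateCostProfile,
    chop: StateCostProfile,
    cycles_per_course: int = 8,
) -> PayerCostInputs:
    """Derive per-patient annual payer costs from the per-cycle profiles.

    A treatment course is at most ``cycles_per_course`` 3-week cycles
    (the formulary maximum) and fits within one year, so annual drug and
    direct-medical spend are the per-cycle values times the course length.
    """
    return PayerCostInputs(
        drug_cost=rchop.progression_free.drug.mean * cycles_per_course,
        medical_cost=rchop.progression_free.dmc.mean * cycles_per_course,
        chop_drug_cost=chop.progression_free.drug.mean * cycles_per_course,
    )


@dataclass(frozen=True)
class BudgetResult:
    scenario: BudgetScenario
    annual_costs: tuple

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.annual_costs):
            raise ValueError("annual costs must be non-negative")

    @property
    def five_year_total(self) -> float:
        return float(sum(self.annual_costs))


def project_budget(
    population: PopulationProjection,
    scenario: BudgetScenario,
    payer_costs: PayerCostInputs,
    uptake: float | Sequence[float] = 1.0,
) -> BudgetResult:
    """Undiscounted payer budget per year and in total under one scenario.

    Annual cost = treated patients x uptake x (drug price x multiplier +
    medical cost); the chemotherapy-only scenario swaps in the CHOP drug
    cost at full price.
    """
    uptake_arr = np.broadcast_to(
        np.asarray(uptake, dtype=float), (len(population.years),)
    )
    if np.any((uptake_arr < 0) | (uptake_arr > 1)):
        raise ValueError("uptake fractions must lie in [0, 1]")
    if scenario.regimen == "CHOP-only":
        drug = payer_costs.chop_drug_cost
    else:
        drug = payer_costs.drug_cost * scenario.drug_price_multiplier
    per_patient = drug + payer_costs.medical_cost
    annual = population.treated * uptake_arr * per_patient
    return BudgetResult(scenario=scenario, annual_costs=tuple(float(a) for a in annual))


def scenario_table(results: Sequence[BudgetResult]) -> pd.DataFrame:
    """Comparative table ordered as given, with differences vs the first scenario."""
    if len(results) == 0:
        raise ValueError("need at least one scenario result")
    ref = results[0].five_year_total
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.scenario.label,
                "regimen": r.scenario.regimen,
                "drug_price_multiplier": r.scenario.drug_price_multiplier,
                **{
                    f"year_{y}_usd": c
                    for y, c in zip(
                        range(1, len(r.annual_costs) + 1), r.annual_costs
                    )
                },
                "five_year_total_usd": r.five_year_total,
                "difference_vs_first_usd": r.five_year_total - ref,
            }
        )
    return pd.DataFrame(rows)
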