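"""Discounted cost, life-year and QALY accumulation, and ICER logic.

Costs are split into four societal-perspective components per alive
state and arm: direct medical costs (DMC), drug acquisition costs, direct
non-medical costs (DNMC, e.g. transport and accommodation) and indirect
productivity costs (IC). All are per-3-week-cycle means with standard
deviations, in 2019 USD (1 USD = IDR 14,000, recorded as metadata only).
The death state carries zero cost and zero utility.

Accumulation walks the cohort trace cycle by cycle: effective (optionally
half-cycle-corrected) occupancy x per-cycle state value x discount factor
at that cycle's time. The drug component can be restricted to an initial
treatment window (default 8 cycles, the formulary's maximum course),
while care, non-medical and productivity costs accrue for as long as the
cohort is alive in a state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import (
    DEATH,
    PF,
    PROG,
    CohortTrace,
    CyclePlan,
    ModelConfig,
    discount_factor,
    half_cycle_weights,
)

__all__ = [
    "COST_COMPONENTS",
    "CostComponent",
    "StateCosts",
    "StateCostProfile",
    "UtilityProfile",
    "OutcomeSummary",
    "ICERResult",
    "CPISeries",
    "cpi_adjust",
    "accumulate_costs",
    "accumulate_effects",
    "summarize_arm",
    "compute_icer",
    "gdp_threshold",
]

COST_COMPONENTS = ("dmc", "drug", "dnmc", "ic")


@dataclass(frozen=True)
class CostComponent:
    """A per-cycle cost summarized as mean +/- SD (USD)."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("cost mean and SD must be non-negative")


@dataclass(frozen=True)
class StateCosts:
    dmc: CostComponent
    drug: CostComponent
    dnmc: CostComponent
    ic: CostComponent

    def component(self, name: str) -> CostComponent:
        return getattr(self, name)

    @property
    def total_mean(self) -> float:
        return sum(self.component(c).mean for c in COST_COMPONENTS)


@dataclass(frozen=True)
class StateCostProfile:
    """Per-cycle costs for one arm: progression-free and progressive states.

    Death costs nothing by construction.
    """

    arm: str
    progression_free: StateCosts
    progressive: StateCosts

    def state(self, index: int) -> StateCosts:
        if index == PF:
            return self.progression_free
        if index == PROG:
            return self.progressive
        raise KeyError(f"no cost profile for state index {index}")

    def component_means(self, name: str) -> np.ndarray:
        """Per-state per-cycle means for one component, death = 0."""
        return np.array(
            [
                self.progression_free.component(name).mean,
                self.progressive.component(name).mean,
                0.0,
            ]
        )


@dataclass(frozen=True)
class UtilityProfile:
    """EQ-5D-5L-derived preference weights per alive state; death fixed at 0."""

    progression_free: float = 0.74
    progressive: float = 0.48
    progression_free_sd: float = 0.23
    progressive_sd: float = 0.26

    def __post_init__(self) -> None:
        for name in ("progression_free", "progressive"):
            u = getattr(self, name)
            if not -1.0 <= u <= 1.0:
                raise ValueError(f"utility {name}={u} outside [-1, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.progression_free, self.progressive, 0.0])


@dataclass(frozen=True)
class OutcomeSummary:
    """Lifetime totals for one arm, discounted and undiscounted."""

    arm: str
    total_cost: float
    life_years: float
    qalys: float
    total_cost_undiscounted: float
    life_years_undiscounted: float
    qalys_undiscounted: float
    cost_components: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "arm": self.arm,
            "total_cost": self.total_cost,
            "life_years": self.life_years,
            "qalys": self.qalys,
            "total_cost_undiscounted": self.total_cost_undiscounted,
            "life_years_undiscounted": self.life_years_undiscounted,
            "qalys_undiscounted": self.qalys_undiscounted,
        }
        d.update({f"cost_{k}": v for k, v in self.cost_components.items()})
        return d


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of arm A against arm B.

    ``icer`` is numeric only when the incremental effect is non-zero;
    otherwise ``label`` carries a dominance verdict. ``cost_effective``
    is true when A dominates, or when A adds effect at a cost per unit
    no greater than the threshold.
    """

    arm_a: str
    arm_b: str
    effect_measure: str
    delta_cost: float
    delta_effect: float
    threshold: float
    icer: Optional[float] = None
    label: Optional[str] = None
    cost_effective: bool = False


@dataclass(frozen=True)
class CPISeries:
    """Consumer price index by calendar year (base year 2019 = reference)."""

    values: Mapping[int, float]
    base_year: int = 2019

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("CPI index values must be positive")

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise KeyError(f"year {year} missing from CPI series") from None

    def __contains__(self, year: int) -> bool:
        return year in self.values


def cpi_adjust(cost: float, from_year: int, to_year: int, cpi: CPISeries) -> float:
    """Inflate/deflate a cost between calendar years via the CPI ratio."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    return cost * cpi[to_year] / cpi[from_year]


def _cycle_times(trace: CohortTrace, plan: CyclePlan, half_cycle: bool) -> np.ndarray:
    n = trace.n_cycles
    starts = np.arange(n) * plan.cycle_length_years
    return starts + 0.5 * plan.cycle_length_years if half_cycle else starts


def accumulate_costs(
    trace: CohortTrace,
    profile: StateCostProfile,
    config: ModelConfig,
    plan: CyclePlan,
    treatment_cycle_cap: Optional[int] = 8,
) -> tuple[float, float, dict]:
    """Lifetime cost for one arm: (discounted, undiscounted, per-component discounted).

    The drug component accrues only during the first
    ``treatment_cycle_cap`` cycles when a cap is set (``None`` = no cap);
    all other components accrue over the full horizon.
    """
    eff = half_cycle_weights(trace, config.half_cycle_correction)
    times = _cycle_times(trace, plan, config.half_cycle_correction)
    df = discount_factor(times, config.discount_rate_costs)
    n = eff.shape[0]
    if treatment_cycle_cap is None:
        drug_mask = np.ones(n)
    else:
        if treatment_cycle_cap < 0:
            raise ValueError("treatment_cycle_cap must be non-negative or None")
        drug_mask = (np.arange(n) < treatment_cycle_cap).astype(float)

    disc = 0.0
    undisc = 0.0
    components: dict[str, float] = {}
    for name in COST_COMPONENTS:
        per_cycle = eff @ profile.component_means(name)
        if name == "drug":
            per_cycle = per_cycle * drug_mask
        comp_disc = float(per_cycle @ df)
        components[name] = comp_disc
        disc += comp_disc
        undisc += float(per_cycle.sum())
    return disc, undisc, components


def accumulate_effects(
    trace: CohortTrace,
    utilities: UtilityProfile,
    config: ModelConfig,
    plan: CyclePlan,
) -> tuple[float, float, float, float]:
    """(life_years, qalys, life_years_undiscounted, qalys_undiscounted)."""
    eff = half_cycle_weights(trace, config.half_cycle_correction)
    times = _cycle_times(trace, plan, config.half_cycle_correction)
    df = discount_factor(times, config.discount_rate_effects)
    cyc = plan.cycle_length_years

    alive = eff[:, PF] + eff[:, PROG]
    uw = eff @ utilities.as_array()
    ly = float((alive * df).sum() * cyc)
    qaly = float((uw * df).sum() * cyc)
    ly_u = float(alive.sum() * cyc)
    qaly_u = float(uw.sum() * cyc)
    return ly, qaly, ly_u, qaly_u


def summarize_arm(
    trace: CohortTrace,
    profile: StateCostProfile,
    utilities: UtilityProfile,
    config: ModelConfig,
    plan: CyclePlan,
    treatment_cycle_cap: Optional[int] = 8,
) -> OutcomeSummary:
    """Full lifetime outcome summary (costs + effects) for one arm."""
    cost_d, cost_u, components = accumulate_costs(
        trace, profile, config, plan, treatment_cycle_cap
    )
    ly, qaly, ly_u, qaly_u = accumulate_effects(trace, utilities, config, plan)
    return OutcomeSummary(
        arm=profile.arm,
        total_cost=cost_d,
        life_years=ly,
        qalys=qaly,
        total_cost_undiscounted=cost_u,
        life_years_undiscounted=ly_u,
        qalys_undiscounted=qaly_u,
        cost_components=components,
    )


_EFFECT_FIELDS = {"QALY": "qalys", "LYG": "life_years"}


def compute_icer(
    arm_a: OutcomeSummary,
    arm_b: OutcomeSummary,
    effect: str = "QALY",
    threshold: float = 11538.0,
) -> ICERResult:
    """Incremental cost-effectiveness of arm A versus arm B (A - B, discounted).

    Quadrant handling: cheaper-and-better is "dominant", dearer-and-worse
    is "dominated"; equal effects never divide (a label is returned
    instead); otherwise the ratio is numeric.
    """
    if effect not in _EFFECT_FIELDS:
        raise ValueError(f"effect must be one of {sorted(_EFFECT_FIELDS)}")
    d_cost = arm_a.total_cost - arm_b.total_cost
    d_eff = getattr(arm_a, _EFFECT_FIELDS[effect]) - getattr(
        arm_b, _EFFECT_FIELDS[effect]
    )

    icer: Optional[float] = None
    label: Optional[str] = None
    if d_eff == 0.0:
        if d_cost == 0.0:
            label = "equivalent"
        else:
            label = "dominated" if d_cost > 0 else "dominant"
    elif d_eff > 0 and d_cost < 0:
        label = "dominant"
    elif d_eff < 0 and d_cost >= 0:
        label = "dominated"
    else:
        # includes the free-benefit edge (d_cost = 0, d_eff > 0) -> ICER 0
        icer = d_cost / d_eff

    cost_effective = label == "dominant" or (
        icer is not None and d_eff > 0 and icer <= threshold
    )
    return ICERResult(
        arm_a=arm_a.arm,
        arm_b=arm_b.arm,
        effect_measure=effect,
        delta_cost=d_cost,
        delta_effect=d_eff,
        threshold=threshold,
        icer=icer,
        label=label,
        cost_effective=cost_effective,
    )


def gdp_threshold(gdp_per_capita: float, multiplier: int) -> float:
    """Willingness-to-pay threshold as a multiple (1-3x) of GDP per capita."""
    if gdp_per_capita <= 0:
        raise ValueError("GDP per capita must be positive")
    if multiplier not in (1, 2, 3):
        raise ValueError("multiplier must be 1, 2 or 3")
    return gdp_per_capita * multiplier
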