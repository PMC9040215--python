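"""Synthetic patient-level data with the structure the analysis assumes.

The primary data behind the cost and utility inputs — per-patient hospital
billing records (2015-2018, CPI-adjusted to 2019) and EQ-5D-5L interview
responses — are not deposited, so this module generates statistically
equivalent stand-ins: per-patient cost records with Gamma dispersion
moment-matched to the published per-state means/SDs, and five-dimension
five-level questionnaire responses whose value-set-mapped utilities hit
the published state means. Estimation routines close the loop, turning
records back into the mean +/- SD summaries the model consumes, so the
whole generate -> estimate -> calibrate -> run pipeline is testable
offline.

The bundled value-set table is an explicitly SYNTHETIC stub (an additive
per-dimension decrement scheme anchored at full health = 1.0), NOT the
Indonesian EQ-5D-5L tariff, and is swappable via a coefficient file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .economics import COST_COMPONENTS, CPISeries, StateCosts, cpi_adjust

__all__ = [
    "DIMENSIONS",
    "ValueSetTable",
    "stub_value_set",
    "generate_cost_records",
    "generate_eq5d_records",
    "estimate_state_parameters",
    "estimate_utilities",
]

#: EQ-5D dimensions: mobility, self-care, usual activities, pain/discomfort,
#: anxiety/depression.
DIMENSIONS = ("mo", "sc", "ua", "pd", "ad")

COST_SCHEMA = ["patient_id", "state", "year", "dmc", "drug", "dnmc", "ic"]
EQ5D_SCHEMA = ["patient_id", "state", *DIMENSIONS, "vas"]

ALIVE_STATES = ("progression_free", "progressive")


@dataclass(frozen=True)
class ValueSetTable:
    """Maps a five-level response vector to a utility via additive decrements.

    ``decrements[dim]`` is a length-5 non-decreasing array of utility
    losses for levels 1..5 (level 1 = no problems = 0 loss), so the
    full-health vector (1,1,1,1,1) maps to exactly 1.0 and every
    worsening level costs utility.
    """

    decrements: Mapping[str, tuple]

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ValueError(f"value set missing dimension {dim!r}")
            dec = self.decrements[dim]
            if len(dec) != 5 or dec[0] != 0.0:
                raise ValueError(
                    f"dimension {dim!r} needs 5 levels with zero loss at level 1"
                )
            if any(b < a for a, b in zip(dec, dec[1:])):
                raise ValueError(f"decrements for {dim!r} must be non-decreasing")

    def utility(self, levels) -> float:
        """Utility of one response vector (five levels, each in 1..5)."""
        levels = np.asarray(levels, dtype=int)
        if levels.shape != (5,) or np.any((levels < 1) | (levels > 5)):
            raise ValueError("need five levels, each in 1..5")
        return 1.0 - sum(
            self.decrements[dim][lvl - 1] for dim, lvl in zip(DIMENSIONS, levels)
        )

    def utilities(self, frame: pd.DataFrame) -> np.ndarray:
        """Vectorized mapping over an EQ-5D record frame."""
        total = np.zeros(len(frame))
        for dim in DIMENSIONS:
            dec = np.asarray(self.decrements[dim])
            total += dec[frame[dim].to_numpy(dtype=int) - 1]
        return 1.0 - total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"dimension": dim, "level": lvl + 1, "decrement": self.decrements[dim][lvl]}
            for dim in DIMENSIONS
            for lvl in range(5)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ValueSetTable":
        dec = {}
        for dim, grp in df.groupby("dimension"):
            grp = grp.sort_values("level")
            dec[str(dim)] = tuple(float(x) for x in grp["decrement"])
        return cls(decrements=dec)


def stub_value_set() -> ValueSetTable:
    """SYNTHETIC value-set stub (not the Indonesian EQ-5D-5L tariff).

    Per-dimension maximum losses sum to 1.6 (worst profile maps to -0.6,
    the rough floor national tariffs exhibit) with a convex level curve.
    """
    curve = np.array([0.0, 0.20, 0.45, 0.75, 1.0])
    max_loss = {"mo": 0.32, "sc": 0.28, "ua": 0.28, "pd": 0.40, "ad": 0.32}
    return ValueSetTable(
        decrements={
            dim: tuple(float(x) for x in curve * max_loss[dim]) for dim in DIMENSIONS
        }
    )


def generate_cost_records(
    n_pf: int,
    n_prog: int,
    targets: Mapping[str, StateCosts],
    year_range: tuple[int, int] = (2015, 2018),
    cpi: Optional[CPISeries] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient cost records with Gamma dispersion matching the targets.

    Costs are drawn at base-year (2019) price level from Gamma
    distributions moment-matched to each state/component target, then
    deflated to the record's billing year through the CPI — so
    re-adjusting to 2019 during estimation recovers the targets.
    """
    if n_pf < 0 or n_prog < 0:
        raise ValueError("patient counts must be non-negative")
    for state in ("progression_free", "progressive"):
        if (n_pf if state == "progression_free" else n_prog) > 0 and state not in targets:
            raise ValueError(f"missing cost targets for state {state!r}")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for state, n in (("progression_free", n_pf), ("progressive", n_prog)):
        if n == 0:
            continue
        sc = targets[state]
        years = rng.integers(year_range[0], year_range[1] + 1, size=n)
        draws = {}
        for comp in COST_COMPONENTS:
            c = sc.component(comp)
            if c.mean == 0.0:
                if c.sd > 0:
                    raise ValueError(
                        f"impossible target for {state}/{comp}: sd > 0 with mean = 0"
                    )
                draws[comp] = np.zeros(n)
            elif c.sd == 0.0:
                draws[comp] = np.full(n, c.mean)
            else:
                shape = (c.mean / c.sd) ** 2
                scale = c.sd**2 / c.mean
                draws[comp] = rng.gamma(shape, scale, size=n)
        for i in range(n):
            year = int(years[i])
            deflate = 1.0 if cpi is None else cpi[year] / cpi[cpi.base_year]
            rows.append(
                {
                    "patient_id": pid,
                    "state": state,
                    "year": year,
                    **{comp: draws[comp][i] * deflate for comp in COST_COMPONENTS},
                }
            )
            pid += 1
    return pd.DataFrame(rows, columns=COST_SCHEMA)


def _expected_utility(value_set: ValueSetTable, severity: float) -> float:
    """E[utility] when each dimension level-1 ~ Binomial(4, severity)."""
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(5), 4, severity)
    total = 0.0
    for dim in DIMENSIONS:
        total += float(pmf @ np.asarray(value_set.decrements[dim]))
    return 1.0 - total


def _severity_for_target(value_set: ValueSetTable, target: float) -> float:
    """Bisection on the severity parameter so expected utility hits the target."""
    lo, hi = 0.0, 1.0
    if target >= _expected_utility(value_set, 0.0):
        return 0.0
    if target <= _expected_utility(value_set, 1.0):
        return 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_utility(value_set, mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_eq5d_records(
    n_pf: int,
    n_prog: int,
    value_set: Optional[ValueSetTable] = None,
    target_utilities: Mapping[str, float] = {"progression_free": 0.74, "progressive": 0.48},
    seed: int = 0,
) -> pd.DataFrame:
    """EQ-5D-5L response records whose mapped utilities centre on the targets.

    Each dimension's level is 1 + Binomial(4, severity), with the
    per-state severity solved by bisection so the value-set-mapped
    expected utility equals the state target. A VAS score correlated
    with utility is generated but not used downstream.
    """
    if n_pf < 0 or n_prog < 0:
        raise ValueError("patient counts must be non-negative")
    vs = value_set if value_set is not None else stub_value_set()
    for state in ALIVE_STATES:
        if state not in target_utilities:
            raise ValueError(f"missing target utility for state {state!r}")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for state, n in (("progression_free", n_pf), ("progressive", n_prog)):
        if n == 0:
            continue
        sev = _severity_for_target(vs, target_utilities[state])
        levels = 1 + rng.binomial(4, sev, size=(n, 5))
        for i in range(n):
            u = vs.utility(levels[i])
            vas = float(np.clip(rng.normal(10 + 85 * max(u, 0.0), 10.0), 0.0, 100.0))
            rows.append(
                {
                    "patient_id": pid,
                    "state": state,
                    **{dim: int(levels[i, j]) for j, dim in enumerate(DIMENSIONS)},
                    "vas": round(vas, 1),
                }
            )
            pid += 1
    return pd.DataFrame(rows, columns=EQ5D_SCHEMA)


def estimate_state_parameters(
    records: pd.DataFrame,
    cpi: Optional[CPISeries] = None,
    base_year: int = 2019,
) -> pd.DataFrame:
    """Sample mean +/- SD per state and cost component, CPI-adjusted first.

    Returns a tidy frame (state, component, mean, sd, n) ready to feed a
    :class:`~dlbclcea.economics.StateCostProfile`. Sample SDs use the
    n-1 denominator.
    """
    if len(records) == 0:
        raise ValueError("no records to estimate from")
    out = []
    for state, grp in records.groupby("state", sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"state {state!r} has fewer than 2 records; cannot estimate SD"
            )
        for comp in COST_COMPONENTS:
            vals = grp[comp].to_numpy(dtype=float)
            if cpi is not None:
                years = grp["year"].to_numpy(dtype=int)
                vals = np.array(
                    [
                        cpi_adjust(v, int(y), base_year, cpi)
                        for v, y in zip(vals, years)
                    ]
                )
            out.append(
                {
                    "state": state,
                    "component": comp,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(out, columns=["state", "component", "mean", "sd", "n"])


def estimate_utilities(
    records: pd.DataFrame, value_set: Optional[ValueSetTable] = None
) -> pd.DataFrame:
    """Mean +/- SD of value-set-mapped utilities per state."""
    if len(records) == 0:
        raise ValueError("no records to estimate from")
    vs = value_set if value_set is not None else stub_value_set()
    df = records.copy()
    df["utility"] = vs.utilities(df)
    out = []
    for state, grp in df.groupby("state", sort=True):
        if len(grp) < 2:
            raise ValueError(f"state {state!r} has fewer than 2 records")
        out.append(
            {
                "state": state,
                "mean": float(grp["utility"].mean()),
                "sd": float(grp["utility"].std(ddof=1)),
                "n": len(grp),
            }
        )
    return pd.DataFrame(out, columns=["state", "mean", "sd", "n"])
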