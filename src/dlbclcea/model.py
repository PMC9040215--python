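"""Markov cohort engine for the three-state DLBCL model.

The disease course is represented by three mutually exclusive health
states — *progression-free*, *progressive* and *death* — evaluated on a
3-week cycle grid. A cohort starts fully progression-free and moves
forward through a per-cycle transition matrix; death is absorbing and
there is no return from the progressive to the progression-free state
(no remission / relapse modelling).

This module knows nothing about costs or utilities: it only builds
transition matrices, runs the cohort forward, and provides the two
time-related primitives every economic accumulation needs —
half-cycle-corrected occupancy weights and discrete annual discounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "STATE_LABELS",
    "PF",
    "PROG",
    "DEATH",
    "WEEKS_PER_YEAR",
    "CyclePlan",
    "ModelConfig",
    "TransitionMatrix",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "half_cycle_weights",
    "discount_factor",
]

#: Canonical state ordering used by every array in the package.
STATE_LABELS = ("progression_free", "progressive", "death")
PF, PROG, DEATH = 0, 1, 2

#: Year convention: 365.25 days / 7 = 52.1786 weeks per year.
WEEKS_PER_YEAR = 365.25 / 7.0

_ROW_TOL = 1e-12
_TRACE_TOL = 1e-9


@dataclass(frozen=True)
class CyclePlan:
    """Cycle grid and stopping rule for a cohort run.

    Parameters
    ----------
    cycle_length_weeks:
        Length of one Markov cycle in weeks (3 weeks: one chemotherapy
        course interval).
    weeks_per_year:
        Calendar convention used to convert cycles to years.
    max_cycles:
        Hard horizon; 1200 cycles of 3 weeks is ~69 years, which
        operationalizes "lifetime" for a cohort entering at age >= 55.
    stop_epsilon:
        Terminate early once death occupancy reaches ``1 - stop_epsilon``.
    """

    cycle_length_weeks: float = 3.0
    weeks_per_year: float = WEEKS_PER_YEAR
    max_cycles: int = 1200
    stop_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.cycle_length_weeks <= 0:
            raise ValueError("cycle_length_weeks must be positive")
        if self.weeks_per_year <= 0:
            raise ValueError("weeks_per_year must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if not 0.0 < self.stop_epsilon < 1.0:
            raise ValueError("stop_epsilon must lie strictly in (0, 1)")

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_weeks / self.weeks_per_year


@dataclass(frozen=True)
class ModelConfig:
    """Discounting and correction settings shared by both treatment arms."""

    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    half_cycle_correction: bool = True
    cohort_start_age: float = 55.0
    arms: tuple[str, str] = ("R-CHOP", "CHOP")

    def __post_init__(self) -> None:
        for name in ("discount_rate_costs", "discount_rate_effects"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {rate}")
        if self.cohort_start_age < 0:
            raise ValueError("cohort_start_age must be non-negative")


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-cycle transition probabilities, rows = from-state, cols = to-state.

    Invariants enforced on construction: entries in [0, 1], each row sums
    to 1 within 1e-12, the death row is absorbing (0, 0, 1), and the
    progressive -> progression-free entry is 0 (patients continuously
    progress; the model has no remission return).
    """

    probs: np.ndarray
    arm: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (3, 3):
            raise ValueError(f"transition matrix must be 3x3, got {probs.shape}")
        if np.any(probs < -_ROW_TOL) or np.any(probs > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = probs.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > _ROW_TOL:
                raise ValueError(
                    f"row '{STATE_LABELS[i]}' sums to {s!r}, expected 1"
                )
        if not np.allclose(probs[DEATH], [0.0, 0.0, 1.0], atol=_ROW_TOL):
            raise ValueError("death row must be absorbing (0, 0, 1)")
        if abs(probs[PROG, PF]) > _ROW_TOL:
            raise ValueError(
                "progressive -> progression_free must be 0 (no remission return)"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=STATE_LABELS, columns=STATE_LABELS)


def build_transition_matrix(
    p_pf_to_prog: float,
    p_pf_to_death: float,
    p_prog_to_death: float,
    arm: str = "",
) -> TransitionMatrix:
    """Assemble a valid per-cycle matrix from the three free probabilities.

    Diagonal remainders are filled so each row sums to exactly 1; the
    death row is absorbing by construction.
    """
    for name, p in (
        ("p_pf_to_prog", p_pf_to_prog),
        ("p_pf_to_death", p_pf_to_death),
        ("p_prog_to_death", p_prog_to_death),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} is outside [0, 1]")
    if p_pf_to_prog + p_pf_to_death > 1.0 + _ROW_TOL:
        raise ValueError(
            "row 'progression_free': competing probabilities "
            f"{p_pf_to_prog} + {p_pf_to_death} exceed 1"
        )
    probs = np.array(
        [
            [1.0 - p_pf_to_prog - p_pf_to_death, p_pf_to_prog, p_pf_to_death],
            [0.0, 1.0 - p_prog_to_death, p_prog_to_death],
            [0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(probs, arm=arm)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at cycle boundaries 0..N plus boundary times in years."""

    occupancy: np.ndarray
    cycle_times: np.ndarray
    arm: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        times = np.asarray(self.cycle_times, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "cycle_times", times)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ValueError("occupancy must have shape (n_boundaries, 3)")
        if occ.shape[0] != times.shape[0]:
            raise ValueError("occupancy and cycle_times lengths differ")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > _TRACE_TOL):
            raise ValueError("every occupancy row must sum to 1")
        if np.any(occ < -_TRACE_TOL) or np.any(occ > 1 + _TRACE_TOL):
            raise ValueError("occupancy fractions must lie in [0, 1]")
        if np.any(np.diff(occ[:, DEATH]) < -_TRACE_TOL):
            raise ValueError("death occupancy must be non-decreasing")
        if not np.allclose(occ[0], [1.0, 0.0, 0.0], atol=_TRACE_TOL):
            raise ValueError("cohort must start fully progression-free")

    @property
    def n_cycles(self) -> int:
        """Number of complete cycles (boundaries minus one)."""
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_LABELS)
        df.insert(0, "time_years", self.cycle_times)
        df.insert(0, "cycle", np.arange(len(df)))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm: str = "") -> "CohortTrace":
        df = pd.read_csv(path)
        return cls(
            occupancy=df[list(STATE_LABELS)].to_numpy(),
            cycle_times=df["time_years"].to_numpy(),
            arm=arm,
        )


MatrixLike = Union[TransitionMatrix, Sequence[TransitionMatrix]]


def run_cohort(matrix: MatrixLike, plan: CyclePlan, arm: str = "") -> CohortTrace:
    """Run the cohort forward through the transition structure.

    ``matrix`` is either a single :class:`TransitionMatrix` (time-constant
    transitions, the default model) or a sequence of matrices, one per
    cycle, for age-varying background mortality. Iteration stops at
    ``plan.max_cycles`` or once death occupancy reaches
    ``1 - plan.stop_epsilon``, whichever comes first.
    """
    time_varying = not isinstance(matrix, TransitionMatrix)
    if time_varying and len(matrix) == 0:
        raise ValueError("matrix sequence must not be empty")

    rows = [np.array([1.0, 0.0, 0.0])]
    for k in range(plan.max_cycles):
        if time_varying:
            m = matrix[min(k, len(matrix) - 1)]
        else:
            m = matrix
        rows.append(rows[-1] @ m.probs)
        if rows[-1][DEATH] >= 1.0 - plan.stop_epsilon:
            break
    occ = np.array(rows)
    times = np.arange(occ.shape[0]) * plan.cycle_length_years
    if not arm and not time_varying:
        arm = matrix.arm
    return CohortTrace(occupancy=occ, cycle_times=times, arm=arm)


def half_cycle_weights(
    trace: CohortTrace, half_cycle_correction: bool = True
) -> np.ndarray:
    """Effective per-cycle occupancy, shape ``(n_cycles, 3)``.

    With the correction on, cycle ``k``'s effective occupancy is the mean
    of boundary rows ``k`` and ``k+1`` (trapezoidal rule: transitions are
    treated as occurring mid-cycle). With it off, state membership is
    counted at the cycle start (boundary row ``k``).
    """
    if trace.occupancy.shape[0] < 2:
        raise ValueError("trace needs at least two boundary rows (one cycle)")
    if half_cycle_correction:
        return 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
    return trace.occupancy[:-1].copy()


def discount_factor(time_years, annual_rate: float):
    """Discrete-annual-compounding discount multiplier ``(1+r)^(-t)``.

    Accepts scalar or array ``time_years``; negative times are rejected.
    """
    t = np.asarray(time_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    out = (1.0 + annual_rate) ** (-t)
    return float(out) if np.isscalar(time_years) else out
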