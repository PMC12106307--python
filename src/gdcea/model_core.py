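"""Cohort state-transition engine.

A Markov cohort model propagates a probability distribution over health
states through discrete cycles using a row-stochastic transition matrix
with an absorbing death state.  This module is disease-agnostic: it knows
nothing about Gaucher disease, drugs or prices — only about traces,
rewards, discounting and the half-cycle correction.

Conventions
-----------
* ``occupancy[t]`` is the state distribution at the *start* of cycle
  ``t + 1`` (``occupancy[0]`` is the initial distribution).
* Discount factors are evaluated at cycle end: cycle ``t`` (1-based) is
  discounted by ``(1 + r) ** (-t / cycles_per_year)``.
* The half-cycle correction is trapezoidal: the effective membership for
  cycle ``t`` is the mean of the cycle-start and cycle-end occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: absolute tolerance for row-stochasticity checks
ROW_TOL = 1e-9


@dataclass(frozen=True)
class TimeGrid:
    """Discretisation of the model horizon into monthly cycles."""

    cycle_length_months: int = 1
    horizon_years: float = 6.0

    def __post_init__(self) -> None:
        if self.cycle_length_months < 1:
            raise ValueError("cycle_length_months must be >= 1")
        if 12 % self.cycle_length_months != 0:
            raise ValueError("cycle_length_months must divide 12")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        n = self.horizon_years * self.cycles_per_year
        if abs(n - round(n)) > 1e-12:
            raise ValueError("horizon must be a whole number of cycles")

    @property
    def cycles_per_year(self) -> int:
        return 12 // self.cycle_length_months

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years * self.cycles_per_year)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied to both costs and health effects."""

    annual_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("annual_rate must be >= 0")


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-cycle transition probabilities over an ordered state list.

    Parameters
    ----------
    states
        Ordered state identifiers; row/column ``i`` of ``probs`` refers to
        ``states[i]``.
    probs
        Square array, ``probs[i, j]`` = probability of moving from state
        ``i`` to state ``j`` in one cycle.  Every row must sum to 1.
    absorbing
        States whose rows must be unit self-vectors (typically death).
    """

    states: tuple[str, ...]
    probs: np.ndarray
    absorbing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "absorbing", tuple(self.absorbing))
        n = len(self.states)
        if probs.shape != (n, n):
            raise ValueError(
                f"probs shape {probs.shape} does not match {n} states"
            )
        if np.any(probs < -ROW_TOL) or np.any(probs > 1 + ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsum = probs.sum(axis=1)
        bad = np.abs(rowsum - 1.0) > ROW_TOL
        if np.any(bad):
            names = [self.states[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"rows do not sum to 1: {names}")
        for name in self.absorbing:
            i = self.index(name)
            unit = np.zeros(n)
            unit[i] = 1.0
            if not np.allclose(probs[i], unit, atol=ROW_TOL):
                raise ValueError(f"state {name!r} is not absorbing")

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy over cycles; row ``t`` is the start of cycle ``t+1``."""

    states: tuple[str, ...]
    occupancy: np.ndarray
    absorbing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "absorbing", tuple(self.absorbing))
        if occ.ndim != 2 or occ.shape[1] != len(self.states):
            raise ValueError("occupancy must be (n_cycles+1, n_states)")
        if np.any(occ < -ROW_TOL) or np.any(occ > 1 + ROW_TOL):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > ROW_TOL):
            raise ValueError("trace rows must sum to 1")
        for name in self.absorbing:
            col = occ[:, self.states.index(name)]
            if np.any(np.diff(col) < -ROW_TOL):
                raise ValueError(f"occupancy of absorbing state {name!r} decreases")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Trace as a DataFrame with a ``cycle`` column (0..n_cycles)."""
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CycleRewards:
    """Per-state monthly cost (¥) and annual utility weight.

    QALYs accrue as ``utility × cycle_length / 12`` per cycle, so the
    utilities are annualised weights in [0, 1].  Absorbing death carries
    zero cost and zero utility.
    """

    states: tuple[str, ...]
    state_cost_per_cycle: np.ndarray
    state_utility: np.ndarray

    def __post_init__(self) -> None:
        cost = np.asarray(self.state_cost_per_cycle, dtype=float)
        util = np.asarray(self.state_utility, dtype=float)
        object.__setattr__(self, "state_cost_per_cycle", cost)
        object.__setattr__(self, "state_utility", util)
        object.__setattr__(self, "states", tuple(self.states))
        n = len(self.states)
        if cost.shape != (n,) or util.shape != (n,):
            raise ValueError("reward vectors must match the state list")
        if np.any(cost < 0):
            raise ValueError("state costs must be non-negative")
        if np.any(util < 0) or np.any(util > 1):
            raise ValueError("utilities must lie in [0, 1]")


def build_transition_matrix(
    entries: Iterable[tuple[str, str, float]],
    adjacency,
    states: Sequence[str],
    absorbing: Sequence[str] = ("death",),
) -> TransitionMatrix:
    """Assemble a row-stochastic matrix from sparse off-diagonal entries.

    The diagonal of each non-absorbing row is closed to
    ``1 - sum(off-diagonal entries)`` ("remain in state"), so a single
    perturbed entry never breaks row-stochasticity.  Absorbing rows are
    forced to unit self-vectors.

    Parameters
    ----------
    entries
        ``(from_state, to_state, probability)`` triples; off-diagonal only.
    adjacency
        Either an object with an ``allowed`` set of ``(from, to)`` pairs or
        such a set directly; entries outside it are rejected.
    states
        Ordered state list defining matrix dimensions.
    absorbing
        States forced absorbing (their rows may carry no entries).

    Raises
    ------
    ValueError
        On unknown states, duplicate entries, adjacency violations, or a
        row whose off-diagonal entries sum above 1.
    """
    states = tuple(states)
    allowed = getattr(adjacency, "allowed", adjacency)
    n = len(states)
    idx = {s: i for i, s in enumerate(states)}
    probs = np.zeros((n, n))
    seen: set[tuple[str, str]] = set()
    for frm, to, p in entries:
        if frm not in idx or to not in idx:
            raise ValueError(f"unknown state in entry ({frm!r}, {to!r})")
        if (frm, to) in seen:
            raise ValueError(f"duplicate transition entry ({frm!r}, {to!r})")
        seen.add((frm, to))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} for ({frm}, {to}) outside [0, 1]")
        if frm == to:
            raise ValueError(
                f"diagonal entry ({frm!r}) is implied by closure; do not specify it"
            )
        if allowed is not None and (frm, to) not in allowed:
            raise ValueError(f"transition ({frm!r} -> {to!r}) violates adjacency")
        if frm in absorbing:
            raise ValueError(f"absorbing state {frm!r} may not have outgoing entries")
        probs[idx[frm], idx[to]] = p
    for i, s in enumerate(states):
        if s in absorbing:
            probs[i] = 0.0
            probs[i, i] = 1.0
            continue
        off = probs[i].sum()
        if off > 1.0 + ROW_TOL:
            raise ValueError(
                f"row {s!r} over-specified: off-diagonal sum {off:.6g} exceeds 1"
            )
        probs[i, i] = max(1.0 - off, 0.0)
    return TransitionMatrix(states=states, probs=probs, absorbing=tuple(absorbing))


def run_cohort(
    matrix: TransitionMatrix,
    initial: np.ndarray,
    grid: TimeGrid,
) -> CohortTrace:
    """Propagate an initial distribution for ``grid.n_cycles`` cycles."""
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (matrix.n_states,):
        raise ValueError("initial distribution dimension mismatch")
    if np.any(initial < 0) or abs(initial.sum() - 1.0) > ROW_TOL:
        raise ValueError("initial occupancy must be a probability distribution")
    occ = np.empty((grid.n_cycles + 1, matrix.n_states))
    occ[0] = initial
    for t in range(1, grid.n_cycles + 1):
        occ[t] = occ[t - 1] @ matrix.probs
    return CohortTrace(states=matrix.states, occupancy=occ, absorbing=matrix.absorbing)


def discount_factors(spec: DiscountSpec, grid: TimeGrid) -> np.ndarray:
    """Cycle-end discount factors ``(1+r)^(-t/cycles_per_year)``, t = 1..n."""
    t = np.arange(1, grid.n_cycles + 1, dtype=float)
    return (1.0 + spec.annual_rate) ** (-t / grid.cycles_per_year)


def _effective_occupancy(occ: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "half_cycle":
        return 0.5 * (occ[:-1] + occ[1:])
    if weighting == "cycle_start":
        return occ[:-1]
    if weighting == "cycle_end":
        return occ[1:]
    raise ValueError(f"unknown weighting {weighting!r}")


def accumulate_outcomes(
    trace: CohortTrace,
    rewards: CycleRewards,
    spec: DiscountSpec,
    grid: TimeGrid,
    half_cycle: bool = True,
    *,
    weighting: str | None = None,
) -> tuple[float, float]:
    """Discounted total cost and QALYs for a cohort trace.

    With the half-cycle correction on (the default) the membership counted
    for cycle ``t`` is the trapezoidal mean of rows ``t-1`` and ``t``;
    otherwise cycle-end membership is used.  ``weighting`` overrides the
    flag for bracketing diagnostics (``"cycle_start"``, ``"cycle_end"``,
    ``"half_cycle"``).

    Returns
    -------
    (total_cost, total_qalys)
        Both discounted at ``spec.annual_rate`` per year, evaluated at
        cycle end.
    """
    if trace.states != rewards.states:
        raise ValueError("trace and rewards refer to different state lists")
    if trace.n_cycles != grid.n_cycles:
        raise ValueError("trace length does not match the time grid")
    if weighting is None:
        weighting = "half_cycle" if half_cycle else "cycle_end"
    eff = _effective_occupancy(trace.occupancy, weighting)
    d = discount_factors(spec, grid)
    cost = float(d @ (eff @ rewards.state_cost_per_cycle))
    qaly_per_cycle = grid.cycle_length_months / 12.0
    qalys = float(d @ (eff @ rewards.state_utility)) * qaly_per_cycle
    return cost, qalys
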