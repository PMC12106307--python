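"""Deterministic cost-effectiveness statistics.

Base-case totals per arm, incremental cost and QALYs, the incremental
cost-effectiveness ratio (ICER = Δcost / ΔQALY), net monetary benefit and
dominance classification for a two-strategy comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gd_model import (
    ARM_COMBO,
    ARM_MONO,
    STATE_NO_COMPLICATIONS,
    STATES,
    GDParameters,
    StrategyDefinition,
    build_strategy,
)
from .model_core import (
    DiscountSpec,
    TimeGrid,
    accumulate_outcomes,
    run_cohort,
)

DOMINANCE_NONE = "none"
DOMINANCE_DOMINANT = "intervention_dominant"
DOMINANCE_DOMINATED = "intervention_dominated"


@dataclass(frozen=True)
class EconomicResult:
    """Per-arm discounted totals and incremental quantities.

    ``icer`` is NaN when incremental QALYs are zero or when one strategy
    dominates (then ``dominance`` carries the classification instead of a
    misleading ratio).
    """

    cost_mono: float
    qalys_mono: float
    cost_combo: float
    qalys_combo: float

    @property
    def incr_cost(self) -> float:
        return self.cost_combo - self.cost_mono

    @property
    def incr_qalys(self) -> float:
        return self.qalys_combo - self.qalys_mono

    @property
    def icer_defined(self) -> bool:
        return self.incr_qalys != 0.0 and self.dominance == DOMINANCE_NONE

    @property
    def icer(self) -> float:
        if not self.icer_defined:
            return math.nan
        return self.incr_cost / self.incr_qalys

    @property
    def dominance(self) -> str:
        if self.incr_qalys > 0 and self.incr_cost < 0:
            return DOMINANCE_DOMINANT
        if self.incr_qalys < 0 and self.incr_cost > 0:
            return DOMINANCE_DOMINATED
        return DOMINANCE_NONE

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per arm, incremental columns on the combo row."""
        return pd.DataFrame(
            {
                "arm": [ARM_MONO, ARM_COMBO],
                "cost": [self.cost_mono, self.cost_combo],
                "incr_cost": [np.nan, self.incr_cost],
                "qalys": [self.qalys_mono, self.qalys_combo],
                "incr_qalys": [np.nan, self.incr_qalys],
                "icer": [np.nan, self.icer],
            }
        )


def compute_icer(
    cost_mono: float, qalys_mono: float, cost_combo: float, qalys_combo: float
) -> EconomicResult:
    """Assemble an :class:`EconomicResult` from per-arm totals."""
    for v in (cost_mono, qalys_mono, cost_combo, qalys_combo):
        if not math.isfinite(v):
            raise ValueError("economic totals must be finite")
    if qalys_mono < 0 or qalys_combo < 0:
        raise ValueError("QALY totals must be non-negative")
    return EconomicResult(cost_mono, qalys_mono, cost_combo, qalys_combo)


def net_monetary_benefit(cost: float, qalys: float, wtp: float) -> float:
    """NMB = WTP × QALYs − cost (¥); positive incremental NMB ⇔ cost-effective."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * qalys - cost


@dataclass(frozen=True)
class WTPGrid:
    """Willingness-to-pay thresholds as multiples of GDP per capita."""

    gdp_per_capita: float = 89_358.0
    multipliers: tuple[float, ...] = (1.0, 2.0, 3.0)

    @property
    def thresholds(self) -> tuple[float, ...]:
        t = tuple(m * self.gdp_per_capita for m in self.multipliers)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        return t

    def grid(self, n_points: int = 21) -> np.ndarray:
        """Equally spaced WTP values from the lowest to the highest threshold."""
        lo, hi = min(self.thresholds), max(self.thresholds)
        return np.linspace(lo, hi, n_points)


def run_strategy(
    strategy: StrategyDefinition,
    grid: TimeGrid,
    discount: DiscountSpec,
    half_cycle: bool = True,
) -> tuple[float, float]:
    """Discounted (cost, QALYs) for one arm, cohort starting uncomplicated."""
    initial = np.zeros(len(STATES))
    initial[STATES.index(STATE_NO_COMPLICATIONS)] = 1.0
    trace = run_cohort(strategy.matrix, initial, grid)
    return accumulate_outcomes(trace, strategy.rewards, discount, grid, half_cycle)


def run_base_case(params: GDParameters, half_cycle: bool = True) -> EconomicResult:
    """Run both arms from the all-uncomplicated initial state and compare."""
    mono = build_strategy(ARM_MONO, params)
    combo = build_strategy(ARM_COMBO, params)
    cost_m, q_m = run_strategy(mono, params.grid, params.discount, half_cycle)
    cost_c, q_c = run_strategy(combo, params.grid, params.discount, half_cycle)
    return compute_icer(cost_m, q_m, cost_c, q_c)
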