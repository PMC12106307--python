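"""Gaucher-disease model: state space, structural adjacency, dosing, defaults.

The model compares lifelong imiglucerase enzyme-replacement monotherapy
against imiglucerase plus oral ambroxol (a pharmacological chaperone) in
neuronopathic Gaucher disease.  Eight health states capture the disease
course: an uncomplicated state, five single-complication states, a
multiple-complication state, and absorbing death.  Everyone enters the
model without complications; the uncomplicated state can progress to any
other state, and every live state can die.

Costs are drug-acquisition only (the dominant cost of enzyme replacement
therapy); utilities are annual preference weights per state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import (
    CycleRewards,
    DiscountSpec,
    TimeGrid,
    TransitionMatrix,
)

STATE_NO_COMPLICATIONS = "state_without_complications"
STATE_MULTIPLE_COMPLICATIONS = "state_with_multiple_complications"
STATE_TRACHEOSTOMY = "necessary_tracheostomy"
STATE_ENTERAL_FEEDING = "necessary_enteral_feeding"
STATE_EPILEPSY = "epilepsy"
STATE_ILD = "interstitial_lung_disease"
STATE_MAJOR_BLEEDING = "major_bleeding"
STATE_DEATH = "death"

#: canonical state order; matrix and reward indices follow it
STATES: tuple[str, ...] = (
    STATE_NO_COMPLICATIONS,
    STATE_MULTIPLE_COMPLICATIONS,
    STATE_TRACHEOSTOMY,
    STATE_ENTERAL_FEEDING,
    STATE_EPILEPSY,
    STATE_ILD,
    STATE_MAJOR_BLEEDING,
    STATE_DEATH,
)
LIVE_STATES: tuple[str, ...] = STATES[:-1]
COMPLICATION_STATES: tuple[str, ...] = STATES[1:-1]

ARM_MONO = "imiglucerase_mono"
ARM_COMBO = "imiglucerase_plus_ambroxol"
ARMS = (ARM_MONO, ARM_COMBO)

#: 2023 Chinese GDP per capita (¥); WTP thresholds are 1-3 multiples of it
GDP_PER_CAPITA = 89_358

#: state utility weights (annual, 0 = death .. 1 = perfect health)
DEFAULT_UTILITIES: dict[str, float] = {
    STATE_NO_COMPLICATIONS: 0.86,
    STATE_MULTIPLE_COMPLICATIONS: 0.44,
    STATE_TRACHEOSTOMY: 0.68,
    STATE_ENTERAL_FEEDING: 0.50,
    STATE_EPILEPSY: 0.55,
    STATE_ILD: 0.55,
    STATE_MAJOR_BLEEDING: 0.52,
    STATE_DEATH: 0.0,
}

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0
WEEKS_PER_MONTH = DAYS_PER_YEAR / 7.0 / 12.0


@dataclass(frozen=True)
class StructuralAdjacency:
    """Allowed directed transitions between states (self-loops included)."""

    allowed: frozenset[tuple[str, str]]
    states: tuple[str, ...] = STATES
    death_state: str = STATE_DEATH

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed", frozenset(self.allowed))
        for s in self.states:
            if (s, s) not in self.allowed:
                raise ValueError(f"self-loop ({s!r}, {s!r}) must be allowed")
            if s != self.death_state and (s, self.death_state) not in self.allowed:
                raise ValueError(f"({s!r} -> death) must be allowed")
        for frm, to in self.allowed:
            if frm == self.death_state and to != self.death_state:
                raise ValueError("death may not have outgoing transitions")

    def permits(self, frm: str, to: str) -> bool:
        return (frm, to) in self.allowed


def default_adjacency(extra_edges: tuple[tuple[str, str], ...] = ()) -> StructuralAdjacency:
    """Structural adjacency of the default model.

    Self-loops everywhere; the uncomplicated state may move to every other
    state; every live state may die; no direct moves between complication
    states (overridable through ``extra_edges`` since published figures of
    such models sometimes carry additional arrows).
    """
    allowed = {(s, s) for s in STATES}
    allowed |= {(STATE_NO_COMPLICATIONS, s) for s in STATES}
    allowed |= {(s, STATE_DEATH) for s in LIVE_STATES}
    allowed |= set(extra_edges)
    return StructuralAdjacency(allowed=frozenset(allowed))


@dataclass(frozen=True)
class DoseSchedule:
    """Dosing rule for one drug; exactly one of weekly/daily regimens."""

    drug_name: str
    pack_size: float  # U or mg per priced pack
    pack_price: float  # ¥ per pack
    dose_per_admin_per_kg: float | None = None  # U/kg (or mg/kg) per administration
    admins_per_week: float | None = None
    daily_dose_per_kg: float | None = None  # mg/kg/day

    def __post_init__(self) -> None:
        if self.pack_size <= 0 or self.pack_price <= 0:
            raise ValueError("pack size and price must be positive")
        weekly = self.dose_per_admin_per_kg is not None or self.admins_per_week is not None
        daily = self.daily_dose_per_kg is not None
        if weekly == daily:
            raise ValueError("specify exactly one of a weekly or a daily regimen")
        if weekly and (
            self.dose_per_admin_per_kg is None
            or self.admins_per_week is None
            or self.dose_per_admin_per_kg <= 0
            or self.admins_per_week <= 0
        ):
            raise ValueError("weekly regimen needs positive dose and frequency")
        if daily and self.daily_dose_per_kg <= 0:
            raise ValueError("daily dose must be positive")

    @property
    def price_per_unit(self) -> float:
        return self.pack_price / self.pack_size


def default_imiglucerase() -> DoseSchedule:
    """Imiglucerase: 2.5 U/kg i.v. three times weekly, ¥21,870 per 400 U."""
    return DoseSchedule(
        drug_name="imiglucerase",
        pack_size=400.0,
        pack_price=21_870.0,
        dose_per_admin_per_kg=2.5,
        admins_per_week=3.0,
    )


def default_ambroxol() -> DoseSchedule:
    """Ambroxol: 25 mg/kg/day orally, ¥5.25 per 600 mg."""
    return DoseSchedule(
        drug_name="ambroxol",
        pack_size=600.0,
        pack_price=5.25,
        daily_dose_per_kg=25.0,
    )


def monthly_drug_cost(schedule: DoseSchedule, weight_kg: float) -> float:
    """Expected drug cost (¥) per one-month cycle for a patient of given weight.

    A month is 365.25/12 days (365.25/7/12 weeks); fractional packs are
    allowed because the cohort expectation is continuous in dose.
    """
    if weight_kg <= 0:
        raise ValueError("patient weight must be positive")
    if schedule.daily_dose_per_kg is not None:
        monthly_amount = schedule.daily_dose_per_kg * weight_kg * DAYS_PER_MONTH
    else:
        monthly_amount = (
            schedule.dose_per_admin_per_kg
            * weight_kg
            * schedule.admins_per_week
            * WEEKS_PER_MONTH
        )
    return monthly_amount * schedule.price_per_unit


@dataclass(frozen=True)
class StrategyDefinition:
    """One arm: its transition matrix plus per-state rewards."""

    arm_name: str
    matrix: TransitionMatrix
    rewards: CycleRewards

    def __post_init__(self) -> None:
        if self.arm_name not in ARMS:
            raise ValueError(f"unknown arm {self.arm_name!r}")
        if self.matrix.states != self.rewards.states:
            raise ValueError("matrix and rewards use different state lists")


@dataclass
class GDParameters:
    """Complete parameter set for one model run (both arms).

    ``drug_cost_multipliers`` scale the per-state drug-cost accrual per arm
    (default 1 = full lifelong accrual in every live state); calibration may
    fit them when published totals imply partial accrual.
    ``transition_entries`` hold the sparse off-diagonal probabilities per
    arm, keyed ``"mono"`` / ``"combo"``.
    """

    utilities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UTILITIES))
    imiglucerase: DoseSchedule = field(default_factory=default_imiglucerase)
    ambroxol: DoseSchedule = field(default_factory=default_ambroxol)
    patient_weight_kg: float = 20.0
    grid: TimeGrid = field(default_factory=TimeGrid)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    adjacency: StructuralAdjacency = field(default_factory=default_adjacency)
    transition_entries: dict[str, list[tuple[str, str, float]]] = field(
        default_factory=lambda: {"mono": [], "combo": []}
    )
    drug_cost_multipliers: dict[str, float] = field(
        default_factory=lambda: {"mono": 1.0, "combo": 1.0}
    )
    gdp_per_capita: float = float(GDP_PER_CAPITA)
    wtp_multipliers: tuple[float, ...] = (1.0, 2.0, 3.0)

    def copy(self) -> "GDParameters":
        return copy.deepcopy(self)

    def validate(self) -> None:
        if set(self.utilities) != set(STATES):
            raise ValueError("utilities must cover exactly the eight model states")
        for s, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for {s!r} outside [0, 1]: {u}")
        if self.utilities[STATE_DEATH] != 0.0:
            raise ValueError("death utility must be 0")
        if self.patient_weight_kg <= 0:
            raise ValueError("patient weight must be positive")
        for key in ("mono", "combo"):
            if key not in self.transition_entries:
                raise ValueError(f"missing transition entries for arm {key!r}")
            self.transition_matrix(key)  # raises on structural violation
        for key, m in self.drug_cost_multipliers.items():
            if m < 0:
                raise ValueError(f"drug cost multiplier for {key!r} must be >= 0")

    # -- derived quantities -------------------------------------------------

    def transition_matrix(self, arm_key: str) -> TransitionMatrix:
        from .model_core import build_transition_matrix

        return build_transition_matrix(
            self.transition_entries[arm_key],
            self.adjacency,
            STATES,
            absorbing=(STATE_DEATH,),
        )

    @property
    def wtp_thresholds(self) -> tuple[float, ...]:
        return tuple(m * self.gdp_per_capita for m in self.wtp_multipliers)


def default_parameters() -> GDParameters:
    """Default tabulated inputs: utilities, prices, dosing, horizon, discount.

    Transition probabilities are not part of the published tables; the
    returned set carries empty transition entries (identity dynamics) and
    is meant to be completed from a config or a calibration.
    """
    return GDParameters()


def build_strategy(arm_name: str, params: GDParameters) -> StrategyDefinition:
    """Assemble one arm's strategy from a full parameter set.

    The monotherapy arm accrues the monthly imiglucerase cost in every live
    state; the combination arm additionally accrues ambroxol.  Utilities are
    identical across arms.  Death accrues nothing.
    """
    if arm_name == ARM_MONO:
        key = "mono"
        drug_cost = monthly_drug_cost(params.imiglucerase, params.patient_weight_kg)
    elif arm_name == ARM_COMBO:
        key = "combo"
        drug_cost = monthly_drug_cost(
            params.imiglucerase, params.patient_weight_kg
        ) + monthly_drug_cost(params.ambroxol, params.patient_weight_kg)
    else:
        raise ValueError(f"unknown arm {arm_name!r}")
    drug_cost *= params.drug_cost_multipliers.get(key, 1.0)
    cost = np.array([drug_cost if s != STATE_DEATH else 0.0 for s in STATES])
    util = np.array([params.utilities[s] for s in STATES])
    rewards = CycleRewards(states=STATES, state_cost_per_cycle=cost, state_utility=util)
    return StrategyDefinition(
        arm_name=arm_name, matrix=params.transition_matrix(key), rewards=rewards
    )


def validate_structure(
    matrix: TransitionMatrix, adjacency: StructuralAdjacency
) -> list[tuple[str, str, float]]:
    """Report nonzero entries the structural adjacency forbids.

    Returns an empty list iff the matrix respects the adjacency.
    """
    violations = []
    for i, frm in enumerate(matrix.states):
        for j, to in enumerate(matrix.states):
            p = matrix.probs[i, j]
            if p != 0.0 and not adjacency.permits(frm, to):
                violations.append((frm, to, float(p)))
    return violations
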