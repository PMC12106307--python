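"""One-way deterministic sensitivity analysis (tornado).

Each named scalar parameter is perturbed by ±10% (multiplicatively) in
turn, the full base case is re-run at each endpoint, and parameters are
ranked by the width of the induced ICER interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .cea import run_base_case
from .gd_model import LIVE_STATES, GDParameters
from .model_core import DiscountSpec

logger = logging.getLogger(__name__)

PARAM_IMIGLUCERASE_PRICE = "imiglucerase_pack_price"
PARAM_AMBROXOL_PRICE = "ambroxol_pack_price"
PARAM_DISCOUNT_RATE = "discount_rate"


def utility_param(state: str) -> str:
    return f"utility.{state}"


def transition_param(arm_key: str, frm: str, to: str) -> str:
    return f"transition.{arm_key}.{frm}->{to}"


def default_parameter_list(include_transitions: bool = False) -> list[str]:
    """Default tornado roster: both drug prices, the seven live-state
    utilities, and the discount rate; transition probabilities opt-in."""
    names = [PARAM_IMIGLUCERASE_PRICE, PARAM_AMBROXOL_PRICE]
    names += [utility_param(s) for s in LIVE_STATES]
    names.append(PARAM_DISCOUNT_RATE)
    if include_transitions:
        names.append("transitions:*")
    return names


def _expand_wildcards(params: GDParameters, names: list[str]) -> list[str]:
    out: list[str] = []
    for name in names:
        if name == "transitions:*":
            for arm_key in ("mono", "combo"):
                for frm, to, _ in params.transition_entries[arm_key]:
                    out.append(transition_param(arm_key, frm, to))
        else:
            out.append(name)
    return out


@dataclass(frozen=True)
class OWSAConfig:
    perturbation_fraction: float = 0.10
    parameter_list: tuple[str, ...] = field(
        default_factory=lambda: tuple(default_parameter_list())
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.perturbation_fraction < 1.0:
            raise ValueError("perturbation_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_low: float  # ICER with the parameter scaled down
    icer_high: float  # ICER with the parameter scaled up

    @property
    def range(self) -> float:
        return abs(self.icer_high - self.icer_low)


def perturb_parameter(
    params: GDParameters,
    name: str,
    direction: int,
    fraction: float,
    clamp_utilities: bool = True,
) -> GDParameters:
    """Return a copy with one named scalar multiplied by ``1 + direction·fraction``.

    Utilities exceeding 1 after an upward perturbation are clamped to 1
    (with a warning) unless ``clamp_utilities`` is off, in which case they
    raise.  Transition-probability perturbations rely on diagonal
    re-closure; a row pushed past total probability 1 raises.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    scale = 1.0 + direction * fraction
    out = params.copy()
    if name == PARAM_IMIGLUCERASE_PRICE:
        out.imiglucerase = replace(out.imiglucerase, pack_price=out.imiglucerase.pack_price * scale)
    elif name == PARAM_AMBROXOL_PRICE:
        out.ambroxol = replace(out.ambroxol, pack_price=out.ambroxol.pack_price * scale)
    elif name == PARAM_DISCOUNT_RATE:
        out.discount = DiscountSpec(annual_rate=params.discount.annual_rate * scale)
    elif name.startswith("utility."):
        state = name.split(".", 1)[1]
        if state not in out.utilities:
            raise KeyError(f"unknown utility parameter {name!r}")
        value = out.utilities[state] * scale
        if value > 1.0:
            if not clamp_utilities:
                raise ValueError(f"perturbed utility for {state!r} exceeds 1: {value}")
            logger.warning("utility %s clamped from %.6g to 1.0", state, value)
            value = 1.0
        out.utilities[state] = value
    elif name.startswith("transition."):
        _, arm_key, edge = name.split(".", 2)
        frm, to = edge.split("->")
        entries = out.transition_entries[arm_key]
        for i, (f, t, p) in enumerate(entries):
            if f == frm and t == to:
                entries[i] = (f, t, p * scale)
                break
        else:
            raise KeyError(f"unknown transition parameter {name!r}")
        out.transition_matrix(arm_key)  # raises if the row became infeasible
    else:
        raise KeyError(f"unknown parameter {name!r}")
    return out


def tornado_analysis(params: GDParameters, config: OWSAConfig | None = None) -> list[TornadoEntry]:
    """Recompute the base-case ICER at ±perturbation for each parameter.

    Entries are sorted by ICER range, descending; ties broken by parameter
    name so the output is deterministic.
    """
    config = config or OWSAConfig()
    names = _expand_wildcards(params, list(config.parameter_list))
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameters in the OWSA list")
    entries = []
    for name in names:
        low = run_base_case(
            perturb_parameter(params, name, -1, config.perturbation_fraction)
        ).icer
        high = run_base_case(
            perturb_parameter(params, name, +1, config.perturbation_fraction)
        ).icer
        entries.append(TornadoEntry(parameter=name, icer_low=low, icer_high=high))
    entries.sort(key=lambda e: (-e.range, e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "range": [e.range for e in entries],
        }
    )
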