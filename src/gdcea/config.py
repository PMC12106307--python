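"""Model configuration: schema-validated YAML/JSON loading and dumping.

A config file holds the complete model description — states, structural
adjacency overrides, per-arm transition entries, utilities, drug dosing
and prices, economic settings, and sensitivity-analysis settings.  Unknown
keys are rejected; omitted blocks fall back to the packaged defaults.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import gd_model
from .gd_model import (
    DEFAULT_UTILITIES,
    GDP_PER_CAPITA,
    STATES,
    DoseSchedule,
    GDParameters,
    default_adjacency,
)
from .model_core import DiscountSpec, TimeGrid
from .owsa import OWSAConfig, default_parameter_list
from .psa import PSAConfig


class _Schema(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DrugSchema(_Schema):
    pack_size: float = Field(gt=0)
    pack_price: float = Field(gt=0)
    dose_per_admin_per_kg: Optional[float] = Field(default=None, gt=0)
    admins_per_week: Optional[float] = Field(default=None, gt=0)
    daily_dose_per_kg: Optional[float] = Field(default=None, gt=0)


class DrugsBlock(_Schema):
    patient_weight_kg: float = Field(default=20.0, gt=0)
    imiglucerase: DrugSchema = DrugSchema(
        pack_size=400.0, pack_price=21_870.0,
        dose_per_admin_per_kg=2.5, admins_per_week=3.0,
    )
    ambroxol: DrugSchema = DrugSchema(
        pack_size=600.0, pack_price=5.25, daily_dose_per_kg=25.0,
    )
    cost_multipliers: dict[str, float] = Field(
        default_factory=lambda: {"mono": 1.0, "combo": 1.0}
    )


class TransitionEntrySchema(_Schema):
    from_state: str = Field(alias="from")
    to: str
    p: float = Field(ge=0.0, le=1.0)


class TransitionsBlock(_Schema):
    mono: list[TransitionEntrySchema] = Field(default_factory=list)
    combo: list[TransitionEntrySchema] = Field(default_factory=list)


class AdjacencyBlock(_Schema):
    extra_edges: list[tuple[str, str]] = Field(default_factory=list)


class EconomicsBlock(_Schema):
    discount_rate: float = Field(default=0.05, ge=0.0)
    horizon_years: float = Field(default=6.0, gt=0.0)
    cycle_length_months: int = Field(default=1, ge=1)
    gdp_per_capita: float = Field(default=float(GDP_PER_CAPITA), gt=0.0)
    wtp_multipliers: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0])


class PSABlock(_Schema):
    n_draws: int = Field(default=1000, ge=1)
    seed: int = 0
    se_fraction: float = Field(default=0.10, ge=0.0)
    sample_costs: bool = True
    sample_utilities: bool = True
    sample_transitions: bool = True
    wtp_points: int = Field(default=21, ge=2)


class OWSABlock(_Schema):
    perturbation_fraction: float = Field(default=0.10, gt=0.0, lt=1.0)
    parameters: Optional[list[str]] = None


class ModelConfigSchema(_Schema):
    states: Optional[list[str]] = None
    adjacency: AdjacencyBlock = AdjacencyBlock()
    transitions: TransitionsBlock = TransitionsBlock()
    utilities: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_UTILITIES))
    drugs: DrugsBlock = DrugsBlock()
    economics: EconomicsBlock = EconomicsBlock()
    psa: PSABlock = PSABlock()
    owsa: OWSABlock = OWSABlock()


@dataclass
class ModelConfig:
    """Validated configuration: model parameters plus analysis settings."""

    params: GDParameters
    psa: PSAConfig
    owsa: OWSAConfig


class ConfigError(ValueError):
    pass


def _schema_to_config(schema: ModelConfigSchema) -> ModelConfig:
    if schema.states is not None and tuple(schema.states) != STATES:
        raise ConfigError(
            "states must list the eight canonical states in canonical order"
        )
    for s, u in schema.utilities.items():
        if s not in STATES:
            raise ConfigError(f"utilities: unknown state {s!r}")
        if not 0.0 <= u <= 1.0:
            raise ConfigError(f"utilities.{s}: value {u} outside [0, 1]")
    utilities = dict(DEFAULT_UTILITIES)
    utilities.update(schema.utilities)
    adjacency = default_adjacency(tuple(tuple(e) for e in schema.adjacency.extra_edges))
    entries = {
        key: [(e.from_state, e.to, e.p) for e in getattr(schema.transitions, key)]
        for key in ("mono", "combo")
    }
    d = schema.drugs
    params = GDParameters(
        utilities=utilities,
        imiglucerase=DoseSchedule(drug_name="imiglucerase", **d.imiglucerase.model_dump()),
        ambroxol=DoseSchedule(drug_name="ambroxol", **d.ambroxol.model_dump()),
        patient_weight_kg=d.patient_weight_kg,
        grid=TimeGrid(
            cycle_length_months=schema.economics.cycle_length_months,
            horizon_years=schema.economics.horizon_years,
        ),
        discount=DiscountSpec(annual_rate=schema.economics.discount_rate),
        adjacency=adjacency,
        transition_entries=entries,
        drug_cost_multipliers=dict(d.cost_multipliers),
        gdp_per_capita=schema.economics.gdp_per_capita,
        wtp_multipliers=tuple(schema.economics.wtp_multipliers),
    )
    params.validate()
    psa = PSAConfig(
        n_draws=schema.psa.n_draws,
        seed=schema.psa.seed,
        se_fraction=schema.psa.se_fraction,
        sample_costs=schema.psa.sample_costs,
        sample_utilities=schema.psa.sample_utilities,
        sample_transitions=schema.psa.sample_transitions,
        wtp_points=schema.psa.wtp_points,
    )
    owsa_params = schema.owsa.parameters
    owsa = OWSAConfig(
        perturbation_fraction=schema.owsa.perturbation_fraction,
        parameter_list=tuple(owsa_params) if owsa_params is not None
        else tuple(default_parameter_list()),
    )
    return ModelConfig(params=params, psa=psa, owsa=owsa)


def parse_config(data: dict) -> ModelConfig:
    """Validate a raw mapping against the schema and build parameters."""
    try:
        schema = ModelConfigSchema.model_validate(data)
    except ValidationError as err:
        raise ConfigError(str(err)) from err
    return _schema_to_config(schema)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML or JSON model configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)  # YAML is a JSON superset
        except yaml.YAMLError as err:
            raise ConfigError(f"cannot parse {path}: {err}") from err
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return parse_config(data)


def config_to_dict(cfg: ModelConfig) -> dict:
    """Serialisable mapping; round-trips through :func:`parse_config`."""
    p = cfg.params

    def drug(d: DoseSchedule) -> dict:
        out = {"pack_size": d.pack_size, "pack_price": d.pack_price}
        if d.daily_dose_per_kg is not None:
            out["daily_dose_per_kg"] = d.daily_dose_per_kg
        else:
            out["dose_per_admin_per_kg"] = d.dose_per_admin_per_kg
            out["admins_per_week"] = d.admins_per_week
        return out

    base_edges = default_adjacency().allowed
    extra = sorted(e for e in p.adjacency.allowed if e not in base_edges)
    return {
        "states": list(STATES),
        "adjacency": {"extra_edges": [list(e) for e in extra]},
        "transitions": {
            key: [
                {"from": frm, "to": to, "p": float(prob)}
                for frm, to, prob in p.transition_entries[key]
            ]
            for key in ("mono", "combo")
        },
        "utilities": dict(p.utilities),
        "drugs": {
            "patient_weight_kg": p.patient_weight_kg,
            "imiglucerase": drug(p.imiglucerase),
            "ambroxol": drug(p.ambroxol),
            "cost_multipliers": {k: float(v) for k, v in p.drug_cost_multipliers.items()},
        },
        "economics": {
            "discount_rate": p.discount.annual_rate,
            "horizon_years": p.grid.horizon_years,
            "cycle_length_months": p.grid.cycle_length_months,
            "gdp_per_capita": p.gdp_per_capita,
            "wtp_multipliers": list(p.wtp_multipliers),
        },
        "psa": {
            "n_draws": cfg.psa.n_draws,
            "seed": cfg.psa.seed,
            "se_fraction": cfg.psa.se_fraction,
            "sample_costs": cfg.psa.sample_costs,
            "sample_utilities": cfg.psa.sample_utilities,
            "sample_transitions": cfg.psa.sample_transitions,
            "wtp_points": cfg.psa.wtp_points,
        },
        "owsa": {
            "perturbation_fraction": cfg.owsa.perturbation_fraction,
            "parameters": list(cfg.owsa.parameter_list),
        },
    }


def dump_config(cfg: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def default_config() -> ModelConfig:
    """The packaged default configuration (tabulated inputs, no transitions)."""
    return parse_config({})


def _data_path(name: str):
    return importlib.resources.files("gdcea").joinpath("data", name)


def load_calibrated_fixture() -> ModelConfig:
    """The committed calibrated configuration reproducing published totals."""
    with importlib.resources.as_file(_data_path("calibrated_fixture.yaml")) as p:
        return load_config(p)


def calibrated_fixture_endpoints() -> dict:
    """Endpoint metadata recorded when the calibrated fixture was built."""
    import json

    with importlib.resources.as_file(
        _data_path("calibrated_fixture_endpoints.json")
    ) as p:
        return json.loads(Path(p).read_text())
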