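"""Scenario configuration files (YAML or JSON) with schema validation.

An empty file yields the defaults: the collaboration preset, a 1 kg object
placed 2 m from the target, dt = 0.01 s.  Unknown keys are rejected with the
offending field path.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .arm_plant import AgentParams, PlantConfig
from .behaviors import Behavior, BehaviorLabel, CostWeights
from .simulate import ScenarioConfig


class ConfigError(ValueError):
    """Schema violation, carrying the field path of the offender."""


class _AgentSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tau1: float = Field(0.03, gt=0)
    tau2: float = Field(0.04, gt=0)
    target: float = 0.0
    label: str | None = None


class _PlantSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mass: float = Field(1.0, gt=0)
    dt: float = Field(0.01, gt=0)
    discretization: str = "euler"


class _WeightsSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    w_err_self: float = 0.0
    w_vel_self: float = 0.0
    w_err_partner: float = 0.0
    w_vel_partner: float = 0.0
    w_force_partner: float = 0.0
    r_effort: float = Field(1.0, gt=0)


class _ScenarioSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    behavior: str = "collaboration"
    roles: tuple[str, str] | None = None
    weights: tuple[_WeightsSchema, _WeightsSchema] | None = None
    agents: tuple[_AgentSchema, _AgentSchema] = (_AgentSchema(), _AgentSchema())
    plant: _PlantSchema = _PlantSchema()
    initial_error: float = 2.0
    duration: float = Field(10.0, gt=0)
    reach_fraction: float = Field(0.9, gt=0, lt=1)
    seed: int = 0
    name: str = "scenario"


_DEFAULT_ROLES = {
    Behavior.ASSISTANCE: ("slave", "master"),
    Behavior.EDUCATION: ("teacher", "student"),
}


def _to_scenario(schema: _ScenarioSchema) -> ScenarioConfig:
    behavior = Behavior(schema.behavior)
    roles = schema.roles or _DEFAULT_ROLES.get(behavior, ("peer", "peer"))
    label = BehaviorLabel(behavior, tuple(roles))
    weights = None
    if schema.weights is not None:
        weights = tuple(CostWeights(**w.model_dump()) for w in schema.weights)
    agents = []
    for i, a in enumerate(schema.agents, start=1):
        agents.append(AgentParams(tau1=a.tau1, tau2=a.tau2, target=a.target,
                                  label=a.label or f"agent{i}"))
    plant = PlantConfig(M=schema.plant.mass, dt=schema.plant.dt,
                        discretization=schema.plant.discretization)
    return ScenarioConfig(
        label=label, weights=weights, agent1=agents[0], agent2=agents[1],
        plant=plant, initial_error=schema.initial_error,
        duration=schema.duration, reach_fraction=schema.reach_fraction,
        seed=schema.seed, name=schema.name)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario config from a YAML or JSON file."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) if raw.strip() else {}
    if data is None:
        data = {}
    return parse_config(data)


def parse_config(data: dict) -> ScenarioConfig:
    """Validate an already-parsed mapping."""
    try:
        schema = _ScenarioSchema.model_validate(data)
    except ValidationError as exc:
        err = exc.errors()[0]
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        raise ConfigError(f"invalid config at `{path}`: {err['msg']}") from exc
    try:
        return _to_scenario(schema)
    except (ValueError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: ScenarioConfig) -> dict:
    """Normalized mapping such that ``parse_config(dump_config(x))`` is ``x``."""
    w1, w2 = cfg.resolve_weights()
    return {
        "behavior": cfg.label.behavior.value,
        "roles": list(cfg.label.roles),
        "weights": [w1.__dict__.copy(), w2.__dict__.copy()],
        "agents": [
            {"tau1": a.tau1, "tau2": a.tau2, "target": a.target, "label": a.label}
            for a in (cfg.agent1, cfg.agent2)
        ],
        "plant": {"mass": cfg.plant.M, "dt": cfg.plant.dt,
                  "discretization": cfg.plant.discretization},
        "initial_error": cfg.initial_error,
        "duration": cfg.duration,
        "reach_fraction": cfg.reach_fraction,
        "seed": cfg.seed,
        "name": cfg.name,
    }


def config_hash(cfg: ScenarioConfig) -> str:
    """Deterministic content hash of a normalized config."""
    import hashlib

    blob = json.dumps(dump_config(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
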