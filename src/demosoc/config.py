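"""Strict run configuration: model blocks, task blocks, presets.

Configurations are plain YAML with a strict schema (unknown keys rejected,
the offending key path reported).  A :class:`RunConfig` round-trips
losslessly through serialization, and its canonical hash is embedded in
every output artifact so results can be traced to the exact configuration
that produced them.

Presets bundle the worked parameter sets of the built-in model families.
The ``altruism_model1`` / ``altruism_model2`` presets intentionally leave
``omega`` and ``mu`` unset: the reversal phenomenology depends on both, so
they must be chosen explicitly rather than defaulted silently.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .models import ModelSpec, make_model

__all__ = [
    "PRESETS",
    "ModelBlock",
    "TaskBlock",
    "RunConfig",
    "load_config",
    "resolve_model",
    "config_hash",
]

PRESETS: dict[str, dict[str, Any]] = {
    # death-rate social action, b = 3(1-n), m = 1 + nu*x1/n
    "death_altruism": {
        "family": "death_rate",
        "params": {"beta": 3.0, "d": 1.0, "nu": -0.95},
        "omega": 900.0,
        "mu": 0.006,
        "epsilon": 0.0,
    },
    "death_neutral": {
        "family": "death_rate",
        "params": {"beta": 3.0, "d": 1.0, "nu": 0.0},
        "omega": 900.0,
        "mu": 0.006,
        "epsilon": 0.0,
    },
    "death_spite": {
        "family": "death_rate",
        "params": {"beta": 3.0, "d": 1.0, "nu": 0.95},
        "omega": 900.0,
        "mu": 0.006,
        "epsilon": 0.0,
    },
    # birth-rate altruism at its optimal action level nu* = 0.75
    "birth_altruism_opt": {
        "family": "birth_altruism",
        "params": {"beta": 1.0, "d": 0.5, "nu": 0.75, "kappa1": 0.75, "kappa2": 0.01},
        "omega": 250.0,
        "mu": 0.01,
        "epsilon": 0.0,
    },
    # birth-rate spite at its optimal action level (~0.75)
    "birth_spite_opt": {
        "family": "birth_spite",
        "params": {"beta": 8.0, "d": 1.0, "nu": 0.75, "a": 0.05, "kappa1": 0.05, "kappa2": 0.2},
        "omega": 900.0,
        "mu": 0.005,
        "epsilon": 0.0,
    },
    # matched costly-altruism pair; omega and mu deliberately unset
    "altruism_model1": {
        "family": "altruism_model1",
        "params": {"r": 0.6, "kappa": 1.2, "nu": 1.0},
        "epsilon": 0.003,
    },
    "altruism_model2": {
        "family": "altruism_model2",
        "params": {"beta": 3.0, "d": 2.4, "kappa": 1.2, "nu": 1.0},
        "epsilon": 0.003,
    },
}


class ModelBlock(BaseModel):
    """Model family + parameters, or a preset with optional overrides."""

    model_config = ConfigDict(extra="forbid")

    preset: str | None = None
    family: str | None = None
    params: dict[str, float] = {}
    omega: float | None = None
    mu: float | None = None
    epsilon: float | None = None
    cost_on_birth: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ModelBlock":
        if self.preset is None and self.family is None:
            raise ValueError("model block needs either 'preset' or 'family'")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        return self


class TaskBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: Literal[
        "list-models",
        "manifold",
        "stationary",
        "simulate-ssa",
        "simulate-sde",
        "optimal-nu",
        "scan-reversal",
        "sweep-mu",
        "compare",
    ]
    settings: dict[str, Any] = {}


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: ModelBlock
    task: TaskBlock
    seed: int = 0
    out_prefix: str = "run"


def resolve_model(block: ModelBlock) -> ModelSpec:
    """Resolve a model block (preset merge, overrides) into a ModelSpec."""
    if block.preset is not None:
        base = PRESETS[block.preset]
        family = block.family or base["family"]
        params = dict(base["params"], **block.params)
        omega = block.omega if block.omega is not None else base.get("omega")
        mu = block.mu if block.mu is not None else base.get("mu")
        epsilon = block.epsilon if block.epsilon is not None else base.get("epsilon")
    else:
        family = block.family
        params = dict(block.params)
        omega, mu, epsilon = block.omega, block.mu, block.epsilon
    if omega is None:
        raise ValueError("model configuration is missing 'omega' (habitat size)")
    return make_model(
        family,
        params,
        omega=omega,
        mu=mu,
        epsilon=epsilon,
        cost_on_birth=block.cost_on_birth,
    )


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration (strict schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join("/".join(map(str, e["loc"])) + ": " + e["msg"] for e in err.errors())
        raise ValueError(f"invalid configuration ({path}): {locs}") from err


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific content (model, task, seed); output paths excluded."""
    payload = config.model_dump()
    payload.pop("out_prefix", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]
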