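"""Run configuration: validated schema, YAML round trip, provenance hash.

Defaults are the study baselines: surface tension 30 dyn/cm, liquid
viscosity 0.01 dyn s/cm^2, longitudinal tension 3000 dyn/cm, acinar
compliance 0.14 per cm H2O, maximal acinar volume 0.0778 cm^3, acinar
opening pressure 2 cm H2O, inflation interval 2.5 s, tidal volume 10 ml/kg
for a 70 kg body, damage threshold 10^3.5 dyn cm^-2 um^-1.  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .engine import Numerics, VentilatorProtocol
from .errors import SchemaError
from .metrics import DAMAGE_THRESHOLD_DEFAULT
from .network import LAMBDA_FLOOR_DEFAULT
from .reopening import FluidParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    v_t_per_kg: float = Field(10.0, ge=0.0, description="tidal volume, ml/kg")
    body_mass: float = Field(70.0, gt=0.0, description="kg")
    t_q: float = Field(2.5, gt=0.0, description="inflation interval, s")
    peep: float | None = Field(None, ge=0.0, description="cm H2O; None disables")
    subtree_count: int = Field(2048, ge=1)
    reference_c: float = Field(0.2, gt=0.0, le=1.0)

    def build(self) -> VentilatorProtocol:
        return VentilatorProtocol(**self.model_dump())


class FluidConfig(_Strict):
    gamma: float = Field(30.0, gt=0.0, description="surface tension, dyn/cm")
    mu: float = Field(0.01, gt=0.0, description="viscosity, dyn s/cm^2")
    tension_T: float = Field(3000.0, ge=0.0, description="dyn/cm")
    mobility_m0: float = Field(1.0, gt=0.0)
    stiffness_exponent_q: float = Field(1.0, ge=0.0)
    tip_width_factor: float = Field(0.01, gt=0.0)
    adhesion_coeff: float = Field(2.124, gt=0.0)
    elastic_release_beta: float = Field(0.2, ge=0.0)
    tension_coeff: float = Field(0.0, ge=0.0)
    tension_length: float = Field(1.0, gt=0.0)
    law_variant: str = "default"

    def build(self) -> FluidParams:
        return FluidParams(**self.model_dump())


class NetworkConfig(_Strict):
    collapse_c: float = Field(0.1, gt=0.0, le=1.0)
    heterogeneity_d: float = Field(0.2, ge=0.0)
    lambda_floor: float = Field(LAMBDA_FLOOR_DEFAULT, gt=0.0)


class NumericsConfig(_Strict):
    dt_scale: float = Field(1.0, gt=0.0)
    ds_cap: float = Field(0.1, gt=0.0)
    dp_cap_cmh2o: float = Field(0.05, gt=0.0)
    dt_max: float = Field(0.02, gt=0.0)
    dt_init: float = Field(1e-6, gt=0.0)
    dt_floor: float = Field(1e-11, gt=0.0)
    vol_tol: float = Field(1e-11, gt=0.0)
    max_steps: int = Field(200_000, ge=1)

    def build(self) -> Numerics:
        return Numerics(**self.model_dump())


class MetricsConfig(_Strict):
    damage_threshold: float = Field(DAMAGE_THRESHOLD_DEFAULT, gt=0.0)


class RunConfig(_Strict):
    protocol: ProtocolConfig = ProtocolConfig()
    fluid: FluidConfig = FluidConfig()
    network: NetworkConfig = NetworkConfig()
    numerics: NumericsConfig = NumericsConfig()
    metrics: MetricsConfig = MetricsConfig()

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        if self.protocol.v_t_per_kg == 0 and self.protocol.peep is None:
            raise ValueError("zero tidal volume requires an explicit PEEP")
        return self

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; an empty or missing body yields full defaults.

    Schema violations raise :class:`SchemaError` listing the offending keys.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise SchemaError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = ", ".join(
            "->".join(str(p) for p in err["loc"]) + f" ({err['msg']})"
            for err in exc.errors()
        )
        raise SchemaError(f"invalid configuration: {locs}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
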