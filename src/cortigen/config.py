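"""Schema-validated run configuration (JSON) and seed derivation.

Every stochastic operation receives an explicit seed; a single run seed is
expanded into per-module child seeds by a documented stable-hash scheme so
module runs are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from . import field as _field

__all__ = [
    "RunConfig",
    "canonical_json",
    "derive_seed",
    "load_validate_config",
    "to_field_config",
]


def derive_seed(seed: int, name: str) -> int:
    """Stable child seed: sha256 of ``"<seed>:<name>"`` reduced mod 2^31."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2 ** 31)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KernelParams(_Strict):
    form: Literal["exponential", "instantaneous"] = "exponential"
    tau: float = Field(2.0, gt=0)
    support: Optional[int] = Field(None, ge=1)


class ActivationParams(_Strict):
    theta: float = 0.0
    slope: float = Field(0.25, gt=0)
    qmax: float = Field(1.0, gt=0)
    form: Literal["logistic", "linear"] = "logistic"


class PlasticityParams(_Strict):
    enabled: bool = True
    eta_eps: float = Field(0.01, ge=0)
    T_eps: float = Field(10.0, gt=0)
    T_g: float = Field(2000.0, gt=0)
    T_rho: float = Field(10000.0, gt=0)
    T_bcm: float = Field(200.0, gt=0)
    bcm_target: float = Field(0.5, gt=0)
    g_cap_factor: float = Field(4.0, gt=0)
    norm_period: int = Field(100, ge=1)
    balance_mode: Literal["per_neuron", "population"] = "per_neuron"


class FieldParams(_Strict):
    n: int = Field(64, ge=2)
    domain: float = Field(10.0, gt=0)
    excitatory_fraction: float = Field(0.8, gt=0, lt=1)
    v: float = Field(2.0, gt=0)
    dt: float = Field(1.0, gt=0)
    connection_density: float = Field(0.3, gt=0, le=1)
    connection_scale: Optional[float] = Field(5.0, gt=0)
    connection_scale_inh: Optional[float] = Field(1.5, gt=0)
    gain_init: float = Field(0.5, gt=0)
    init_balanced: bool = False
    gain_sigma: float = Field(0.5, ge=0)
    target_flux: float = Field(3.0, gt=0)
    drive_amplitude: float = Field(0.4, ge=0)
    single_population: bool = False
    kernel: KernelParams = Field(default_factory=KernelParams)
    kernel_inh: Optional[KernelParams] = Field(
        default_factory=lambda: KernelParams(tau=6.0)
    )
    activation: ActivationParams = Field(default_factory=ActivationParams)
    plasticity: PlasticityParams = Field(default_factory=PlasticityParams)


class MetricsParams(_Strict):
    lag_range: Optional[int] = Field(None, ge=1)
    n_windows: int = Field(10, ge=3)
    normalized: bool = True
    max_lag: int = Field(15, ge=1)


class MorphParams(_Strict):
    n_patch: int = Field(100, ge=4)
    n_local: int = Field(100, ge=4)
    axon_scale_patch: float = Field(4.0, gt=0)
    axon_scale_local: float = Field(0.5, gt=0)
    w_synchrony: float = Field(1.0, ge=0)
    w_wiring: float = Field(1.0, ge=0)
    domain: float = Field(10.0, gt=0)
    max_iter: int = Field(4000, ge=1)


class MapParams(_Strict):
    p0: tuple[float, float] = (0.0, 0.0)
    k: float = Field(1.0, gt=0)
    chirality: Literal[1, -1] = 1


class OpmapParams(_Strict):
    maps: list[MapParams] = Field(default_factory=lambda: [MapParams()])
    extent: tuple[float, float, float, float] = (-2.0, 2.0, -2.0, 2.0)
    resolution: float = Field(0.05, gt=0)


class RunConfig(_Strict):
    """Top-level configuration for any cortigen run."""

    seed: int = Field(..., ge=0, description="master seed (required)")
    out_dir: Optional[str] = None
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"
    steps: int = Field(5000, ge=0)
    field: FieldParams = Field(default_factory=FieldParams)
    metrics: MetricsParams = Field(default_factory=MetricsParams)
    morph: MorphParams = Field(default_factory=MorphParams)
    opmap: OpmapParams = Field(default_factory=OpmapParams)


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(x) for x in loc)


def load_validate_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Unknown keys are errors (strict mode); a missing ``seed`` is an error
    (no silent nondeterminism).  Violations are reported with JSON-pointer
    paths.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config is not valid JSON: {exc}") from exc
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{_pointer(err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {msgs}") from exc


def canonical_json(config: RunConfig) -> str:
    """Canonical serialized form (sorted keys, defaults filled)."""
    return json.dumps(config.model_dump(), sort_keys=True, indent=2) + "\n"


def to_field_config(config: RunConfig) -> "_field.FieldConfig":
    """Materialize the field block as a simulator configuration."""
    f = config.field
    kernel = _field.DendriticKernel(**f.kernel.model_dump())
    kernel_inh = (
        _field.DendriticKernel(**f.kernel_inh.model_dump())
        if f.kernel_inh is not None else None
    )
    return _field.FieldConfig(
        n=f.n, domain=f.domain, excitatory_fraction=f.excitatory_fraction,
        v=f.v, dt=f.dt, connection_density=f.connection_density,
        connection_scale=f.connection_scale,
        connection_scale_inh=f.connection_scale_inh,
        gain_init=f.gain_init, init_balanced=f.init_balanced,
        gain_sigma=f.gain_sigma, target_flux=f.target_flux,
        drive_amplitude=f.drive_amplitude, kernel=kernel,
        kernel_inh=kernel_inh,
        activation=_field.ActivationFunction(**f.activation.model_dump()),
        plasticity=_field.PlasticityConfig(**f.plasticity.model_dump()),
        seed=derive_seed(config.seed, "field"),
        single_population=f.single_population,
    )
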