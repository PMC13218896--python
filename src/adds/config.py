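"""Schema-validated run configuration (YAML/JSON).

A :class:`RunConfig` bundles everything a run needs — network, DA-kernel,
protocol and decision-layer parameters plus output directory and global
seed — with strict validation: unknown keys are rejected by name, and an
empty file resolves to the full default configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .circuit import NetworkConfig
from .da_signal import CORTEX_KERNEL, NACC_KERNEL, DAKernelParams
from .decisions import (
    AgencyContext,
    DiscountParams,
    Gamble,
    ProbWeightParams,
    UtilityParams,
)
from .protocols import ProtocolSettings

__all__ = ["RunConfig", "ConfigSchemaError", "load_config", "save_config"]

SCHEMA_VERSION = 1


class ConfigSchemaError(ValueError):
    """Configuration file violates the schema; names offending keys."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSettings(_Strict):
    n_nacc: int = 100
    n_vp: int = 100
    n_da: int = 100
    vp_target_rate: float = 7.0
    da_target_rate: float = 4.5
    connection_probability: float = 0.25
    p_vp_da: float = 0.009
    da_gaba_reversal: float = -75.0
    da_nmda_mg: float = 1.0
    w_vsub: float = 250.0
    w_nacc_vp: float = 1.5
    w_vp_da: float = 8.0
    w_pptn: float = 10.0
    w_rmtn: float = 10.0
    weight_jitter: float = 0.5
    tau_vsub: float = 5.0
    tau_nacc_vp: float = 10.0
    tau_vp_da: float = 20.0
    tau_pptn: float = 10.0
    tau_rmtn: float = 10.0
    delay_ms: float = 1.0
    vsub_rate_max: float = 40.0
    n_vsub_afferents: int = 10
    pptn_rate_max: float = 10_000.0
    rmtn_rate_max: float = 120.0
    f_aversive: float = 0.08
    aversive_gain: float = 1.0
    da_bias_sd: float = 6.0
    msn_gain_spread: float = 0.5
    a_control: float = 0.35
    a_high: float = 0.85
    dt: float = 0.5
    duration: float = 12_000.0
    burn_in: float = 2_000.0

    def build(self, seed: int) -> NetworkConfig:
        return NetworkConfig(seed=seed, **self.model_dump())


class KernelSettings(_Strict):
    release_increment: float
    clearance_tau: float
    baseline: float
    region: str
    clearance: str = "exponential"
    vmax: float = 0.0
    km: float = 1.0
    detection_epsilon: float = 0.01

    @classmethod
    def from_params(cls, k: DAKernelParams) -> "KernelSettings":
        return cls(**k.__dict__)

    def build(self) -> DAKernelParams:
        return DAKernelParams(**self.model_dump())


class ProtocolSection(_Strict):
    n_seeds: int = 20
    pptn_activation_rate: float = 400.0
    n_permutations: int = 10_000
    stat_seed: int = 0
    method: str = "permutation"

    def build(self) -> ProtocolSettings:
        return ProtocolSettings(**self.model_dump())


class OutcomeSpec(_Strict):
    value: float
    probability: float
    delay: float = 0.0


class DecisionSection(_Strict):
    gain_exponent: float = 0.88
    loss_exponent: float = 0.88
    gain_anchor: tuple[float, float] = (79.0, 50.0)
    loss_anchor: tuple[float, float] = (48.0, 50.0)
    gain_multiplier_high: float = 69.0 / 50.0
    loss_multiplier_high: float = 53.0 / 50.0
    a_control: float = 0.35
    a_high: float = 0.85
    weighting_mode: str = "identity"
    distortion_gamma: float = 0.6
    da_modulation: float = 0.0
    alpha: float = 0.01
    da_optimum: float = 3.0
    curvature: float = 0.5
    alpha_min: float = 0.005
    gamble: list[OutcomeSpec] = [
        OutcomeSpec(value=79.0, probability=0.5),
        OutcomeSpec(value=-48.0, probability=0.5),
    ]

    def utility_params(self) -> UtilityParams:
        return UtilityParams.calibrated(
            self.gain_anchor, self.loss_anchor,
            self.gain_exponent, self.loss_exponent,
        )

    def weight_params(self) -> ProbWeightParams:
        return ProbWeightParams(self.distortion_gamma, self.da_modulation,
                                self.weighting_mode)

    def discount_params(self) -> DiscountParams:
        return DiscountParams(self.alpha, self.da_optimum,
                              self.curvature, self.alpha_min)

    def context(self, agency: float) -> AgencyContext:
        return AgencyContext.from_agency(
            agency, self.a_control, self.a_high,
            self.gain_multiplier_high, self.loss_multiplier_high,
        )

    def build_gamble(self) -> Gamble:
        return Gamble(tuple((o.value, o.probability, o.delay)
                            for o in self.gamble))


class RunConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    output_dir: str = "runs"
    network: NetworkSettings = NetworkSettings()
    nacc_kernel: KernelSettings = KernelSettings.from_params(NACC_KERNEL)
    cortex_kernel: KernelSettings = KernelSettings.from_params(CORTEX_KERNEL)
    protocol: ProtocolSection = ProtocolSection()
    decision: DecisionSection = DecisionSection()


def _format_errors(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    ``None`` or an empty file yields the full default configuration.
    Unknown keys raise :class:`ConfigSchemaError` naming each key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigSchemaError("config root must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigSchemaError(_format_errors(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration; format follows the suffix."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
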