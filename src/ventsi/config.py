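"""Run configuration: schema, validation, defaults and loading.

A run is described by a single YAML file with nested blocks
(``patient``, ``injury``, ``ventilator``, ``protocol``, ``gas``,
``seeds``, ``output``).  Every field has a default, so an empty file
yields the frozen default study configuration.  Unknown keys are
rejected, and the controller thresholds default to the published
protocol values (plateau target 30 cmH2O, stress-index band
0.95-1.05, pH rescue 7.15, respiratory-rate cap 35 bpm, PaCO2 band
35-65 mmHg, open-lung PEEP offset +2 cmH2O, CT significance 10%).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pydantic
import yaml

from .errors import ConfigurationError
from .gas import GasState, initial_gas_state
from .patient import VentSettings, VirtualPatient, apply_injury_and_iah, make_patient
from .protocol import ProtocolParams

logger = logging.getLogger("ventsi")

SCHEMA_VERSION = 1

_ARM_ALIASES = {
    "si": "si_target",
    "si_target": "si_target",
    "pplat": "pplat_target",
    "pplat_target": "pplat_target",
}


class _Block(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class PatientBlock(_Block):
    weight_kg: float = pydantic.Field(default=32.0, gt=0)
    n_units: int = pydantic.Field(default=500, ge=1)
    e1_cmh2o_per_l: float = pydantic.Field(default=21.5, gt=0)
    e2_cmh2o_per_l2: float = pydantic.Field(default=2.0, ge=0)
    raw_cmh2o_per_lps: float = pydantic.Field(default=10.0, gt=0)
    ecw_cmh2o_per_l: float = pydantic.Field(default=12.5, gt=0)
    frc_ml: float = pydantic.Field(default=900.0, gt=0)


class InjuryBlock(_Block):
    severity: float = pydantic.Field(default=1.0, ge=0.0, le=1.0)
    iap_mmhg: float = pydantic.Field(default=26.0, ge=0.0)


class VentilatorBlock(_Block):
    mode: str = "VCV"
    vt_ml_per_kg: float = pydantic.Field(default=8.0, gt=0)
    rr: float = pydantic.Field(default=22.0, gt=0)
    peep: float = pydantic.Field(default=5.0, ge=0)
    fio2: float = pydantic.Field(default=1.0, gt=0, le=1.0)

    @pydantic.field_validator("mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("VCV", "PCV"):
            raise ValueError("mode must be 'VCV' or 'PCV'")
        return v


class ProtocolBlock(_Block):
    arm: str = "si_target"
    duration_min: float = pydantic.Field(default=240.0, gt=0)
    tick_s: float = pydantic.Field(default=30.0, gt=0)
    vt_review_s: float = pydantic.Field(default=300.0, gt=0)
    rr_rescue_review_s: float = pydantic.Field(default=60.0, gt=0)
    rr_review_s: float = pydantic.Field(default=3600.0, gt=0)
    pplat_target: float = 30.0
    si_low: float = 0.95
    si_high: float = 1.05
    ph_rescue: float = 7.15
    rr_cap: float = 35.0
    paco2_low: float = 35.0
    paco2_high: float = 65.0
    ol_peep_offset: float = 2.0
    ct_threshold_pct: float = 10.0

    @pydantic.field_validator("arm")
    @classmethod
    def _check_arm(cls, v: str) -> str:
        if v not in _ARM_ALIASES:
            raise ValueError("arm must be one of 'si', 'si_target', 'pplat', 'pplat_target'")
        return _ARM_ALIASES[v]

    @pydantic.model_validator(mode="after")
    def _check_bands(self) -> "ProtocolBlock":
        if not self.si_low < self.si_high:
            raise ValueError("si_low must be < si_high")
        if not self.paco2_low < self.paco2_high:
            raise ValueError("paco2_low must be < paco2_high")
        return self


class GasBlock(_Block):
    vco2_ml_min: float = pydantic.Field(default=200.0, gt=0)
    vd_aw_ml: float = pydantic.Field(default=77.0, ge=0)
    hco3_mmol_l: float = pydantic.Field(default=24.0, gt=0)
    co2_capacity_ml_per_mmhg: float = pydantic.Field(default=64.0, gt=0)


class SeedsBlock(_Block):
    patient: int = pydantic.Field(default=1, ge=0)
    noise: int = pydantic.Field(default=1, ge=0)
    phantom: int = pydantic.Field(default=1, ge=0)


class OutputBlock(_Block):
    trace_csv: str | None = None
    snapshots_csv: str | None = None
    report_json: str | None = None


class RunConfig(_Block):
    """Validated, fully-defaulted description of one simulation run."""

    schema_version: int = SCHEMA_VERSION
    patient: PatientBlock = pydantic.Field(default_factory=PatientBlock)
    injury: InjuryBlock = pydantic.Field(default_factory=InjuryBlock)
    ventilator: VentilatorBlock = pydantic.Field(default_factory=VentilatorBlock)
    protocol: ProtocolBlock = pydantic.Field(default_factory=ProtocolBlock)
    gas: GasBlock = pydantic.Field(default_factory=GasBlock)
    seeds: SeedsBlock = pydantic.Field(default_factory=SeedsBlock)
    output: OutputBlock = pydantic.Field(default_factory=OutputBlock)

    @pydantic.field_validator("schema_version")
    @classmethod
    def _check_schema(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}; expected {SCHEMA_VERSION}")
        return v

    def config_hash(self) -> str:
        """Stable hash of the effective (defaults-resolved) configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _format_validation_error(exc: pydantic.ValidationError) -> str:
    parts = []
    for err in exc.errors():
        key = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{key}: {err['msg']}")
    return "; ".join(parts)


def validate_config(data: dict | None) -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig`.

    Raises :class:`ConfigurationError` naming the offending key and
    constraint on any schema violation.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(_format_validation_error(exc)) from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load, validate and echo a run configuration.

    ``path=None`` or an empty file yields the full default config.
    The effective configuration (all defaults resolved) and its hash
    are echoed to the run log.
    """
    data: dict | None = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        try:
            data = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"config file is not valid YAML: {exc}") from exc
    cfg = validate_config(data)
    from . import __version__  # deferred: avoids import cycle at package init

    logger.info(
        "effective config (version %s, hash %s): %s",
        __version__, cfg.config_hash(), json.dumps(cfg.model_dump(), sort_keys=True),
    )
    return cfg


def build_patient(cfg: RunConfig) -> VirtualPatient:
    """Construct the injured+IAH virtual patient a config describes."""
    p = cfg.patient
    g = cfg.gas
    patient = make_patient(
        {
            "weight": p.weight_kg,
            "n_units": p.n_units,
            "E1": p.e1_cmh2o_per_l,
            "E2": p.e2_cmh2o_per_l2,
            "Raw": p.raw_cmh2o_per_lps,
            "Ecw_base": p.ecw_cmh2o_per_l,
            "FRC_healthy": p.frc_ml,
            "vco2": g.vco2_ml_min,
            "vd_aw": g.vd_aw_ml,
            "hco3": g.hco3_mmol_l,
            "co2_capacity": g.co2_capacity_ml_per_mmhg,
        },
        seed=cfg.seeds.patient,
    )
    if cfg.injury.severity > 0 or cfg.injury.iap_mmhg > 0:
        patient = apply_injury_and_iah(patient, cfg.injury.severity, cfg.injury.iap_mmhg)
    return patient


def build_settings(cfg: RunConfig) -> VentSettings:
    """Ventilator settings from the config's ventilator block."""
    v = cfg.ventilator
    return VentSettings(
        mode=v.mode, vt_ml_per_kg=v.vt_ml_per_kg, rr=v.rr, peep=v.peep, fio2=v.fio2
    )


def build_protocol_params(cfg: RunConfig) -> ProtocolParams:
    """Controller thresholds/cadences from the config's protocol block."""
    pr = cfg.protocol
    return ProtocolParams(
        pplat_target=pr.pplat_target,
        si_low=pr.si_low,
        si_high=pr.si_high,
        ph_rescue=pr.ph_rescue,
        rr_cap=pr.rr_cap,
        paco2_low=pr.paco2_low,
        paco2_high=pr.paco2_high,
        vt_review_s=pr.vt_review_s,
        rr_rescue_review_s=pr.rr_rescue_review_s,
        rr_review_s=pr.rr_review_s,
    )


def build_gas_state(cfg: RunConfig, patient: VirtualPatient) -> GasState:
    """Initial steady-state blood-gas state for the configured ventilation."""
    return initial_gas_state(patient, build_settings(cfg))
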