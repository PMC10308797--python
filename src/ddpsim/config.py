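"""Configuration schema, loading and run manifests.

Runs are described by a hierarchical YAML config validated against a strict
schema (unknown keys are rejected) before any simulation starts.  All
defaults are materialized into the run manifest, so a manifest alone
suffices to reproduce a run.
"""
from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Annotated, List, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, TypeAdapter, ValidationError

from . import __version__
from .crm import DEFAULT_PRIOR_SD, DEFAULT_SKELETON, CrmDesign
from .enrichment import DEFAULT_CUTOFFS, EnrichmentDesign
from .scenarios import (
    BiomarkerScenario,
    DoseScenario,
    EnrollmentModel,
    make_default_dose_scenario,
)
from .segments import (
    MetricsTable,
    Phase3Rules,
    SegmentASpec,
    SegmentBSpec,
    SegmentCSpec,
    SegmentSpec,
)
from .single_arm import SingleArmDesign

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "validate_config_file",
    "config_to_spec",
    "build_manifest",
    "write_manifest",
]


class ConfigError(ValueError):
    """Schema violation, with field-level messages."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SingleArmBlock(_Strict):
    n2: int = Field(ge=1)
    orr0: float = Field(0.4, gt=0, lt=1)
    orr1_alt: float = Field(0.6, gt=0, le=1)
    alpha: float = Field(0.05, gt=0, lt=1)


class Phase3Block(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    target_power: float = Field(0.90, gt=0, lt=1)
    max_total: int = Field(400, ge=2)
    sizing: Literal["exact", "normal"] = "exact"


class ScenarioABlock(_Strict):
    true_orr1: float = Field(0.6, ge=0, le=1)
    true_orr0: float = Field(0.4, ge=0, le=1)


class CrmBlock(_Strict):
    n1: int = Field(ge=1)
    skeleton: List[float] = Field(default_factory=lambda: list(DEFAULT_SKELETON))
    tox_target: float = Field(0.25, gt=0, lt=1)
    prior_sd: float = Field(DEFAULT_PRIOR_SD, gt=0)
    start_dose: int = Field(3, ge=1)
    no_skip: bool = True


class SegmentBPhase2Block(_Strict):
    n: int = Field(42, ge=1)
    orr0: float = Field(0.4, gt=0, lt=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    tox_monitor_threshold: float = Field(0.25, ge=0, le=1)


class DoseScenarioBlock(_Strict):
    tox: List[float] = Field(default_factory=lambda: list(make_default_dose_scenario().tox))
    orr: List[float] = Field(default_factory=lambda: list(make_default_dose_scenario().orr))


class EnrichmentBlock(_Strict):
    n2: int = Field(ge=4)
    cutoffs: List[float] = Field(default_factory=lambda: list(DEFAULT_CUTOFFS))
    stage_fractions: Tuple[float, float, float] = (0.5, 0.25, 0.25)
    alpha: float = Field(0.05, gt=0, lt=1)
    min_subgroup_pairs: int = Field(5, ge=1)


class BiomarkerScenarioBlock(_Strict):
    orr0: float = Field(0.4, ge=0, le=1)
    slope: float = 4.0
    crossing: float = Field(0.6, gt=0, lt=1)


class EnrollmentBlock(_Strict):
    rate_phase_a: float = Field(4.0, gt=0)
    rate_phase_b: float = Field(10.0, gt=0)
    gap_months: float = Field(6.0, ge=0)
    followup_months_a: float = Field(6.0, ge=0)
    followup_months_b: float = Field(6.0, ge=0)


class OutputBlock(_Strict):
    csv: str = "metrics.csv"
    manifest: str = "manifest.json"


class _BaseRun(_Strict):
    n_reps: int = Field(1000, ge=1)
    seed: int = Field(0, ge=0)
    enrollment: EnrollmentBlock = EnrollmentBlock()
    output: OutputBlock = OutputBlock()


class SegmentAConfig(_BaseRun):
    segment: Literal["A"]
    phase2: SingleArmBlock
    phase3: Phase3Block = Phase3Block()
    scenario: ScenarioABlock = ScenarioABlock()


class SegmentBConfig(_BaseRun):
    segment: Literal["B"]
    phase1: CrmBlock
    phase2: SegmentBPhase2Block = SegmentBPhase2Block()
    scenario: DoseScenarioBlock = DoseScenarioBlock()


class SegmentCConfig(_BaseRun):
    segment: Literal["C"]
    phase2: EnrichmentBlock
    phase3: Phase3Block = Phase3Block()
    scenario: BiomarkerScenarioBlock = BiomarkerScenarioBlock()


RunConfig = Annotated[
    Union[SegmentAConfig, SegmentBConfig, SegmentCConfig],
    Field(discriminator="segment"),
]

_adapter: TypeAdapter = TypeAdapter(RunConfig)


def _format_validation_error(err: ValidationError) -> str:
    lines = ["invalid configuration:"]
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {loc}: {e['msg']}")
    return "\n".join(lines)


def load_config(path: Union[str, Path]):
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigError` with field-level messages on any schema
    violation, unknown key, or unreadable file.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except OSError as e:
        raise ConfigError(f"cannot read config {path}: {e}") from e
    except yaml.YAMLError as e:
        raise ConfigError(f"config {path} is not valid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    try:
        return _adapter.validate_python(raw)
    except ValidationError as e:
        raise ConfigError(_format_validation_error(e)) from e


def validate_config_file(path: Union[str, Path]) -> None:
    load_config(path)


def _enrollment(cfg: _BaseRun) -> EnrollmentModel:
    return EnrollmentModel(**cfg.enrollment.model_dump())


def config_to_spec(cfg) -> SegmentSpec:
    """Materialize a validated config into an executable segment spec."""
    if isinstance(cfg, SegmentAConfig):
        return SegmentASpec(
            phase2=SingleArmDesign(**cfg.phase2.model_dump()),
            phase3=Phase3Rules(**cfg.phase3.model_dump()),
            true_orr1=cfg.scenario.true_orr1,
            true_orr0=cfg.scenario.true_orr0,
            enrollment=_enrollment(cfg),
        )
    if isinstance(cfg, SegmentBConfig):
        block = cfg.phase1.model_dump()
        block["skeleton"] = tuple(block["skeleton"])
        return SegmentBSpec(
            phase1=CrmDesign(**block),
            scenario=DoseScenario(tox=tuple(cfg.scenario.tox), orr=tuple(cfg.scenario.orr)),
            phase2_n=cfg.phase2.n,
            phase2_orr0=cfg.phase2.orr0,
            phase2_alpha=cfg.phase2.alpha,
            tox_monitor_threshold=cfg.phase2.tox_monitor_threshold,
            enrollment=_enrollment(cfg),
        )
    if isinstance(cfg, SegmentCConfig):
        return SegmentCSpec(
            phase2=EnrichmentDesign(
                n2=cfg.phase2.n2,
                cutoffs=tuple(cfg.phase2.cutoffs),
                stage_fractions=cfg.phase2.stage_fractions,
                alpha=cfg.phase2.alpha,
                min_subgroup_pairs=cfg.phase2.min_subgroup_pairs,
            ),
            scenario=BiomarkerScenario.from_crossing(
                slope=cfg.scenario.slope,
                crossing=cfg.scenario.crossing,
                orr0=cfg.scenario.orr0,
            ),
            phase3=Phase3Rules(**cfg.phase3.model_dump()),
            enrollment=_enrollment(cfg),
        )
    raise TypeError(f"unsupported config type {type(cfg).__name__}")


def build_manifest(cfg, table: MetricsTable, wall_time_s: float) -> dict:
    """Self-contained run record: resolved config, seed, metrics, runtime."""
    return {
        "artifact": "ddpsim",
        "version": __version__,
        "config": _adapter.dump_python(cfg, mode="json"),
        "seed": table.seed,
        "n_reps": table.n_reps,
        "metrics": table.to_row(),
        "wall_time_s": wall_time_s,
        "created_unix": time.time(),
    }


def write_manifest(manifest: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
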