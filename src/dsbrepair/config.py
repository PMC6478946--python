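"""Workflow configuration schema and run manifests.

A single YAML file drives the end-to-end pipeline (damage generation ->
ensemble simulation -> curve export).  The schema is validated with pydantic
so violations are reported with their field paths.  A
:class:`RunManifest` snapshot (config, master seed, package version, output
paths) is written next to every simulation's outputs so a run can be
re-executed bit-identically.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .states import DEFAULT_TAU_TABLE

__all__ = [
    "ConfigError",
    "NucleusSection",
    "DamageSection",
    "SimulationSection",
    "RunSection",
    "CalibrationTarget",
    "WorkflowConfig",
    "load_config",
    "RunManifest",
]


class ConfigError(ValueError):
    """Configuration file violates the schema (message lists field paths)."""


class NucleusSection(BaseModel):
    shape: Literal["sphere", "ellipsoid"] = "sphere"
    radii_um: tuple[float, float, float] = (5.0, 5.0, 5.0)


class DamageSection(BaseModel):
    dose_gy: float = Field(2.0, ge=0)
    dsb_per_gy: float = Field(35.0, gt=0)
    nucleus: NucleusSection = NucleusSection()
    sdd_file: Optional[str] = None  # fixed exposure instead of per-repeat generation


class SimulationSection(BaseModel):
    t_end_s: float = Field(28_800.0, gt=0)
    record_dt_s: float = Field(30.0, gt=0)
    n_repeats: int = Field(50, ge=1)
    seed: int = 1
    diffusion_um2_per_s: float = Field(1e-5, ge=0)
    capture_radius_um: float = Field(0.25, gt=0)
    pairing_mode: Literal["any_eligible", "original_partner_only"] = "any_eligible"


class RunSection(BaseModel):
    scenarios: list[Literal["A", "B", "C", "D"]] = ["A", "B", "C", "D"]
    deficiencies: list[Literal["WT", "XLF", "Lig4"]] = ["WT", "XLF", "Lig4"]
    out_dir: str = "results"
    recruitment_proteins: list[str] = []


class CalibrationTarget(BaseModel):
    rule: str
    file: str
    model: Literal["exp_recruitment", "biphasic_decay"] = "exp_recruitment"
    bounds: tuple[float, float] = (1.0, 100_000.0)
    fixed_params: dict[str, float] = {}


class WorkflowConfig(BaseModel):
    run: RunSection = RunSection()
    damage: DamageSection = DamageSection()
    simulation: SimulationSection = SimulationSection()
    tau: dict[str, float] = {}
    tau_mode: Literal["override", "replace"] = "override"
    mechanisms: dict[str, bool] = {}
    end_cleaning: bool = True
    calibration: list[CalibrationTarget] = []

    @field_validator("tau")
    @classmethod
    def _known_rules(cls, v: dict[str, float], info) -> dict[str, float]:
        unknown = set(v) - set(DEFAULT_TAU_TABLE)
        if unknown:
            raise ValueError(f"unknown rule names: {sorted(unknown)}")
        bad = [k for k, tau in v.items() if tau <= 0]
        if bad:
            raise ValueError(f"tau must be > 0 for rules {bad}")
        return v

    @field_validator("mechanisms")
    @classmethod
    def _known_mechanisms(cls, v: dict[str, bool]) -> dict[str, bool]:
        allowed = {"mrn_colocalisation", "rnf138_removal", "mrn_independent_resection"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown mechanism toggles: {sorted(unknown)}")
        return v


def load_config(path: str | Path) -> WorkflowConfig:
    """Load and validate a workflow YAML file.

    Raises :class:`ConfigError` whose message lists each violated field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return WorkflowConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from None


class RunManifest:
    """Snapshot sufficient to re-run a simulation bit-identically."""

    def __init__(
        self,
        config: WorkflowConfig,
        master_seed: int,
        outputs: list[str],
    ) -> None:
        from . import __version__

        self.created_utc = datetime.datetime.now(datetime.timezone.utc).isoformat()
        self.package_version = __version__
        self.master_seed = master_seed
        self.config = config.model_dump()
        self.outputs = outputs

    def to_dict(self) -> dict:
        return {
            "created_utc": self.created_utc,
            "package_version": self.package_version,
            "master_seed": self.master_seed,
            "config": self.config,
            "outputs": self.outputs,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str) + "\n")
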