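"""Pipeline configuration: schema, validation, defaults."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from tempocode.sim_engine.defaults import (
    DEFAULT_COMPOUNDS,
    DEFAULT_LIGAND_SPECS,
    FULL_MODEL_PARAMETER_TABLE,
    default_model_params,
)
from tempocode.sim_engine.grid import TimeGrid
from tempocode.sim_engine.params import CoreModelParams, LigandInputSpec

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Schema violation; the message lists every violation with its key path."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Strict):
    n_points: int = Field(default=481, ge=2)
    dt: float = Field(default=1.0, gt=0)
    t_start: float = 0.0


class LigandSection(_Strict):
    ligand: str
    dose_level: str
    amplitude: float = Field(ge=0.0, le=1.0)
    rise_time: float = Field(gt=0.0)
    decay_time: float = Field(gt=0.0)
    plateau_fraction: float = Field(ge=0.0, le=1.0)


class LadderSection(_Strict):
    n_steps: int = Field(default=20, ge=1)
    exp_start: float = -0.15
    exp_stop: float = -3.0


class AnalysisSection(_Strict):
    duration_threshold: float = Field(default=0.05, ge=0.0)
    nonresponder_cutoff: float = Field(default=0.05, ge=0.0)
    spaces: list[str] = Field(default_factory=lambda: ["codon"])
    eps_grid: list[float] | None = None
    seed: int = 0
    normalize_per_regime: bool = False  # default: global min-max normalization


class PipelineConfig(_Strict):
    schema_version: int = SCHEMA_VERSION
    grid: GridSection = Field(default_factory=GridSection)
    model: dict[str, float] = Field(default_factory=dict)
    ligands: list[LigandSection] = Field(
        default_factory=lambda: [
            LigandSection(**{
                "ligand": s.ligand, "dose_level": s.dose_level,
                "amplitude": s.amplitude, "rise_time": s.rise_time,
                "decay_time": s.decay_time, "plateau_fraction": s.plateau_fraction,
            })
            for s in DEFAULT_LIGAND_SPECS
        ]
    )
    compounds: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COMPOUNDS.items()}
    )
    ladder: LadderSection = Field(default_factory=LadderSection)
    remap: dict[str, list[str]] = Field(
        default_factory=lambda: {
            k: list(v) for k, v in FULL_MODEL_PARAMETER_TABLE.items()
        }
    )
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)

    @field_validator("model")
    @classmethod
    def _check_model(cls, v: dict[str, float]) -> dict[str, float]:
        known = set(CoreModelParams.names())
        problems = []
        for key, value in v.items():
            if key not in known:
                problems.append(f"model.{key}: unknown parameter")
            elif value < 0:
                problems.append(f"model.{key}: must be >= 0, got {value}")
        if problems:
            raise ValueError("; ".join(problems))
        return v

    def time_grid(self) -> TimeGrid:
        return TimeGrid(
            n_points=self.grid.n_points, dt=self.grid.dt, t_start=self.grid.t_start
        )

    def model_params(self) -> CoreModelParams:
        return default_model_params().with_updates(**self.model)

    def ligand_specs(self) -> tuple[LigandInputSpec, ...]:
        return tuple(
            LigandInputSpec(
                ligand=s.ligand,
                dose_level=s.dose_level,
                amplitude=s.amplitude,
                rise_time=s.rise_time,
                decay_time=s.decay_time,
                plateau_fraction=s.plateau_fraction,
            )
            for s in self.ligands
        )

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a JSON config; defaults fill all missing sections.

    Raises ConfigError listing every violation with its key path.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config is not valid JSON: {exc}") from exc
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(lines)
        ) from exc
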