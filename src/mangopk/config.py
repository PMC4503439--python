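"""Pipeline configuration: validated, unit-annotated, YAML-loadable."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigError
from .simulate import IV_SCHEDULE, ORAL_SCHEDULE

__all__ = ["PipelineConfig", "load_config"]


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings. Unknown keys are rejected by name."""

    model_config = ConfigDict(extra="forbid")

    iv_doses: tuple[float, ...] = (5.0, 10.0, 20.0)  # mg/kg
    oral_doses: tuple[float, ...] = (10.0, 50.0, 100.0)  # mg/kg
    iv_schedule: tuple[float, ...] = IV_SCHEDULE  # min
    oral_schedule: tuple[float, ...] = ORAL_SCHEDULE  # min
    alpha: float = Field(0.05, gt=0, lt=1)
    lloq_ug_ml: float = Field(1e-3, gt=0)
    auc_method: str = "linear_up_log_down"
    lambda_z_min_points: int = Field(3, ge=3)
    mass_tolerance_da: float = Field(0.5, gt=0)
    fragment_tolerance_da: float = Field(0.5, gt=0)
    parent_mz: float = Field(411.21, gt=0)
    parent_rt_min: float = 27.6
    dilution_factor: float = Field(5.0, ge=1)
    gfr_ml_min_kg: float = Field(14.0, gt=0)
    output_dir: str = "."
    seed: int = 0


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; None yields the defaults.

    Raises ConfigError naming the offending key on unknown keys or
    out-of-range values.
    """
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"{path}: {details}") from exc
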