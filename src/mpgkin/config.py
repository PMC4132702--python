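"""Run configuration: YAML-loaded, schema-validated before any computation."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["NoiseConfig", "InputPaths", "RunConfig", "load_config"]


class NoiseConfig(BaseModel):
    """Measurement-noise settings applied to every simulated assay."""

    model_config = ConfigDict(extra="forbid")

    cv: float = Field(default=0.0, ge=0.0)
    floor_sd: float = Field(default=0.0, ge=0.0)


class InputPaths(BaseModel):
    """CSV inputs for analyze mode (any subset may be given)."""

    model_config = ConfigDict(extra="forbid")

    progress_curves: Optional[str] = None
    repair_timecourses: Optional[str] = None
    sensorgrams: Optional[str] = None
    mixing_standards: Optional[str] = None


class RunConfig(BaseModel):
    """Validated end-to-end run configuration.

    ``simulate`` mode draws every input from the packaged fixture catalog
    with the configured noise and seed; ``analyze`` mode reads the CSVs in
    ``inputs``. Unknown keys are rejected up front.
    """

    model_config = ConfigDict(extra="forbid")

    mode: Literal["simulate", "analyze"] = "simulate"
    seed: int = Field(default=0, ge=0, lt=2**31)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    inputs: InputPaths = Field(default_factory=InputPaths)
    stages: list[Literal["enzymology", "incell", "spr"]] = Field(
        default_factory=lambda: ["enzymology", "incell", "spr"]
    )
    t_half_method: Literal["exponential_fit", "linear_interpolation"] = (
        "exponential_fit"
    )
    bonferroni: bool = False  # off by default: single pooled test per table
    outdir: str = "mpgkin_out"
    time_units: Literal["min"] = "min"  # enzymology axis; in-cell is hours


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)
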