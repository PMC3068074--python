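"""Application configuration for the command-line interface.

A YAML config file can override the clinical defaults (velocity cut-off,
outcome thresholds, time units) and point at replacement risk-criteria,
Partin and guideline files; flags given on the command line win over the
config file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import LoadError
from .units import TimeUnit


class AppConfig(BaseModel):
    model_config = {"frozen": True}

    velocity_cutoff: float = Field(default=0.75, gt=0.0)  # ng/mL/yr
    surgery_threshold: float = Field(default=0.2, gt=0.0)  # ng/mL
    radiotherapy_threshold: float = Field(default=2.0, gt=0.0)  # ng/mL
    psav_unit: TimeUnit = TimeUnit.YEARS
    psadt_unit: TimeUnit = TimeUnit.MONTHS
    risk_criteria_file: Optional[Path] = None  # None = packaged table
    partin_file: Optional[Path] = None  # None = packaged synthetic fixture
    guideline_file: Optional[Path] = None  # None = packaged demo graph
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> AppConfig:
    """Load a YAML config file, or the defaults when *path* is None."""
    if path is None:
        return AppConfig()
    p = Path(path)
    if not p.exists():
        raise LoadError("config file not found", source=str(p))
    try:
        doc = yaml.safe_load(p.read_text(encoding="utf-8")) or {}
        return AppConfig(**doc)
    except (yaml.YAMLError, ValidationError, TypeError) as e:
        raise LoadError(f"invalid config: {e}", source=str(p)) from None
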