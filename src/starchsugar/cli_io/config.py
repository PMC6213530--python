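"""Pipeline configuration: schema-validated before any stage runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field

from ..synthetic_data import GeneratorConfig
from ..value_assignment import DEFAULT_CASCADE, DEFAULT_OVERSEAS_PRIORITY


class PipelineConfig(BaseModel):
    """Everything the end-to-end run needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # inputs (ignored when synthetic = True)
    composition: Optional[str] = None
    literature: Optional[str] = None
    links: Optional[str] = None
    recipes: Optional[str] = None
    overseas: Optional[str] = None
    records: Optional[str] = None
    persons: Optional[str] = None
    rules: Optional[str] = None  # free-sugar rules YAML; None = packaged default

    # synthetic mode
    synthetic: bool = True
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)

    # stage options
    cascade: Sequence[str] = DEFAULT_CASCADE
    overseas_priority: Sequence[str] = DEFAULT_OVERSEAS_PRIORITY
    aggregation: str = "median"
    energy_factor: float = 4.0
    thresholds: Sequence[float] = (10.0, 5.0)
    contribution_method: str = "mean_of_ratios"
    contribution_display_threshold: float = 7.0
    lambda_min: float = -2.0
    lambda_max: float = 2.0
    lambda_step: float = 0.01
    rounding: int = 1
    seed: int = 42
    verbose: bool = False

    def config_hash(self) -> str:
        """Stable hash of the canonical JSON form, stamped on every report."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path), "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)
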