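"""Tunable thresholds and pipeline run configuration (pydantic models)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field

__all__ = ["ScoreConfig", "TriageConfig", "RunConfig", "load_config"]


class ScoreConfig(BaseModel):
    """Severe-phenotype thresholds and score band definitions."""

    model_config = {"frozen": True}

    ef_severe_below_pct: float = 30.0
    lvh_severe_at_least_mm: float = 30.0
    qtc_severe_at_least_ms: float = 500.0
    age_cutoff_1pt: float = 30.0
    age_cutoff_2pt: float = 10.0
    age_strict_less_than: bool = True
    # minimum affected relatives beyond the proband for the 2 FH points
    fh_min_relatives: int = Field(default=1, ge=1)


class TriageConfig(BaseModel):
    model_config = {"frozen": True}

    require_non_frequency_criterion: bool = False
    # reassign a discordant LP/P to the gene's definitive disease (mirrors
    # multidisciplinary adjudication); off → flagged discordant_LPP
    allow_reassignment: bool = True


class RunConfig(BaseModel):
    """All-in-one pipeline run configuration."""

    probands: Path
    variants: Path
    registry: Path | None = None
    out_dir: Path = Path("report")
    seed: int = 0
    rounding: Literal["half_away", "half_even"] = "half_away"
    score: ScoreConfig = ScoreConfig()
    triage: TriageConfig = TriageConfig()
    verbosity: str = "INFO"


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
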