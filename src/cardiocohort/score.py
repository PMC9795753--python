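"""Monogenic disease score.

Additive, fixed-weight: positive family history 2 points, severe phenotype
1 point, onset < 30 years 1 point or < 10 years 2 points (max of the two
age bands, not their sum). Totals of 4-5 share the top bucket. Among
genetically unsolved probands a total >= 1 is read as likely monogenic,
0 as likely complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ScoreConfig
from .model import Proband, SchemaError, SevereFeatures

__all__ = [
    "ScoreBreakdown",
    "BUCKETS",
    "severe_phenotype",
    "age_points",
    "family_history_points",
    "compute_score",
    "likelihood_class",
]

BUCKETS = ("s0", "s1", "s2", "s3", "s4plus")


@dataclass(frozen=True)
class ScoreBreakdown:
    family_history_points: int
    severe_points: int
    age_points: int
    age_missing: bool = False

    def __post_init__(self) -> None:
        if self.family_history_points not in (0, 2):
            raise SchemaError("family_history_points must be 0 or 2")
        if self.severe_points not in (0, 1):
            raise SchemaError("severe_points must be 0 or 1")
        if self.age_points not in (0, 1, 2):
            raise SchemaError("age_points must be 0, 1 or 2")

    @property
    def total(self) -> int:
        return self.family_history_points + self.severe_points + self.age_points

    @property
    def bucket(self) -> str:
        return BUCKETS[min(self.total, 4)]


def severe_phenotype(flags: SevereFeatures, config: ScoreConfig | None = None) -> bool:
    """Severe phenotype: any ventricular-arrhythmia / heart-failure event
    flag, EF below 30%, LVH at or above 30 mm, or QTc at or above 500 ms.
    Missing continuous measures contribute false."""
    cfg = config or ScoreConfig()
    if flags.any_event_flag:
        return True
    ef = flags.ejection_fraction_pct
    if ef is not None and ef < cfg.ef_severe_below_pct:
        return True
    lvh = flags.max_lvh_mm
    if lvh is not None and lvh >= cfg.lvh_severe_at_least_mm:
        return True
    qtc = flags.qtc_ms
    if qtc is not None and qtc >= cfg.qtc_severe_at_least_ms:
        return True
    return False


def age_points(
    age_at_diagnosis: float | None, config: ScoreConfig | None = None
) -> int:
    """2 points below the young cutoff (default <10 y), 1 below the
    moderate cutoff (default <30 y), else 0. Missing age scores 0."""
    cfg = config or ScoreConfig()
    if age_at_diagnosis is None:
        return 0
    if not math.isfinite(age_at_diagnosis) or age_at_diagnosis < 0:
        raise SchemaError(f"age_at_diagnosis must be >= 0, got {age_at_diagnosis!r}")
    if cfg.age_strict_less_than:
        if age_at_diagnosis < cfg.age_cutoff_2pt:
            return 2
        if age_at_diagnosis < cfg.age_cutoff_1pt:
            return 1
    else:
        if age_at_diagnosis <= cfg.age_cutoff_2pt:
            return 2
        if age_at_diagnosis <= cfg.age_cutoff_1pt:
            return 1
    return 0


def family_history_points(
    n_affected_relatives: int, config: ScoreConfig | None = None
) -> int:
    """2 points when the family unit beyond the proband includes at least
    ``fh_min_relatives`` additional affected relatives (default 1)."""
    cfg = config or ScoreConfig()
    if n_affected_relatives < 0:
        raise SchemaError("n_affected_relatives must be >= 0")
    return 2 if n_affected_relatives >= cfg.fh_min_relatives else 0


def compute_score(proband: Proband, config: ScoreConfig | None = None) -> ScoreBreakdown:
    cfg = config or ScoreConfig()
    return ScoreBreakdown(
        family_history_points=family_history_points(proband.n_affected_relatives, cfg),
        severe_points=1 if severe_phenotype(proband.severe_flags, cfg) else 0,
        age_points=age_points(proband.age_at_diagnosis, cfg),
        age_missing=proband.age_at_diagnosis is None,
    )


def likelihood_class(score_total: int, solved_status: str) -> str:
    """Dichotomise an *unsolved* proband: ``likely_monogenic`` (total >= 1)
    vs ``likely_complex`` (total 0). Calling this for a solved proband is a
    contract violation."""
    if solved_status != "unsolved":
        raise SchemaError(
            f"likelihood_class applies to unsolved probands only, got {solved_status!r}"
        )
    if score_total < 0 or score_total > 5:
        raise SchemaError(f"score total out of range: {score_total}")
    return "likely_monogenic" if score_total >= 1 else "likely_complex"
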