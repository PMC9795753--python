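"""Seeded synthetic-cohort generator.

The generative model is deliberately simple: each proband's aetiology is
Bernoulli(monogenic_fraction); onset age, family history and severe
phenotype are drawn from aetiology-specific distributions; monogenic
probands carry a detectable causal variant with probability
``detect_prob``, which is classifiable LP/P with an ancestry-specific
probability (the reference-database inequity knob) and otherwise stalls
as a suspicious-grade VUS. Criteria sets come from a template library
validated against the combiner, so the triage stage is exercised
end-to-end rather than bypassed.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .model import (
    GeneRegistry,
    Proband,
    SevereFeatures,
    VariantObservation,
    base_diagnosis,
    default_registry,
    parse_criteria_field,
)
from .triage import combine_criteria

__all__ = [
    "AetiologyParams",
    "SimulationConfig",
    "simulate_cohort",
    "expected_lpp_yield",
    "score_discrimination_experiment",
]

_LP_TEMPLATES = ("PVS1;PM2", "PS1;PM2;PP3", "PM1;PM2;PP2;PP3", "PVS1;PS2;PM2")
_SVUS_TEMPLATES = ("PM2;PP3", "PM2;PP3;PS4_supporting", "PM2;PS4_moderate")
_BENIGN_TEMPLATES = ("BS1;BP4", "BA1")

DEFAULT_DIAGNOSIS_MIX = {
    "HCM": 0.66,
    "BrS": 0.06,
    "LQTS": 0.05,
    "DCM": 0.05,
    "ACM": 0.04,
    "LVNC": 0.04,
    "CPVT": 0.03,
    "possible_HCM": 0.04,
    "undiagnosed": 0.02,
    "unexplained_SCA": 0.01,
}

DEFAULT_ANCESTRY_MIX = {
    "European": 0.70,
    "EastAsian": 0.08,
    "SouthCentralAsian": 0.06,
    "MiddleEasternNorthAfrican": 0.08,
    "Other": 0.05,
    "Unknown": 0.03,
}

DEFAULT_LPP_GIVEN_DETECT = {
    "European": 0.85,
    "EastAsian": 0.60,
    "SouthCentralAsian": 0.60,
    "MiddleEasternNorthAfrican": 0.55,
    "Other": 0.60,
    "Unknown": 0.75,
}


class AetiologyParams(BaseModel):
    """Per-aetiology phenotype model (onset truncated-normal at 0)."""

    model_config = {"frozen": True}

    onset_mean: float
    onset_sd: float = Field(gt=0)
    fh_prob: float = Field(ge=0, le=1)
    severe_prob: float = Field(ge=0, le=1)


class SimulationConfig(BaseModel):
    model_config = {"frozen": True}

    n_probands: int = Field(default=1000, ge=0)
    monogenic_fraction: float = Field(default=0.45, ge=0, le=1)
    diagnosis_mix: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX)
    )
    monogenic: AetiologyParams = AetiologyParams(
        onset_mean=35.0, onset_sd=15.0, fh_prob=0.55, severe_prob=0.45
    )
    complex_aetiology: AetiologyParams = AetiologyParams(
        onset_mean=55.0, onset_sd=12.0, fh_prob=0.10, severe_prob=0.15
    )
    detect_prob: float = Field(default=0.8, ge=0, le=1)
    ancestry_mix: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_MIX)
    )
    lpp_given_detect: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_LPP_GIVEN_DETECT)
    )
    tier2_rescue: float = Field(default=0.10, ge=0, le=1)
    benign_variant_prob: float = Field(default=0.05, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_mixes(self) -> "SimulationConfig":
        problems = []
        for name, mix in (("diagnosis_mix", self.diagnosis_mix), ("ancestry_mix", self.ancestry_mix)):
            if any(p < 0 for p in mix.values()):
                problems.append(f"{name}: negative probability")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                problems.append(f"{name}: probabilities sum to {sum(mix.values())!r}, not 1")
        for anc, p in self.lpp_given_detect.items():
            if not (0.0 <= p <= 1.0):
                problems.append(f"lpp_given_detect[{anc}]: {p!r} outside [0, 1]")
        for anc in self.ancestry_mix:
            if anc not in self.lpp_given_detect:
                problems.append(f"lpp_given_detect missing ancestry {anc!r}")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))
        return self


def expected_lpp_yield(config: SimulationConfig) -> float:
    """Closed-form expected LP/P fraction implied by the config."""
    p_lpp_anc = sum(
        w * config.lpp_given_detect[anc] for anc, w in config.ancestry_mix.items()
    )
    return config.monogenic_fraction * config.detect_prob * p_lpp_anc


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0  # pragma: no cover - pathological config


def _causal_gene(diagnosis: str, registry: GeneRegistry, rng: np.random.Generator) -> str:
    base = base_diagnosis(diagnosis) or "DCM"
    candidates = sorted(
        g for g, e in registry.genes.items()
        if any(a.disease == base and a.validity == "definitive" for a in e.associations)
    )
    if not candidates:  # pragma: no cover - registry always covers bases
        candidates = sorted(registry.genes)
    return candidates[int(rng.integers(len(candidates)))]


def simulate_cohort(
    config: SimulationConfig,
    registry: GeneRegistry | None = None,
) -> tuple[list[Proband], list[VariantObservation]]:
    """Draw a cohort; fully reproducible from ``config.seed``."""
    registry = registry or default_registry()
    for t in _LP_TEMPLATES:
        assert combine_criteria(parse_criteria_field(t)).is_lp_p
    rng = np.random.default_rng(config.seed)

    diagnoses = sorted(config.diagnosis_mix)
    dx_p = np.array([config.diagnosis_mix[d] for d in diagnoses])
    ancestries = sorted(config.ancestry_mix)
    anc_p = np.array([config.ancestry_mix[a] for a in ancestries])

    probands: list[Proband] = []
    variants: list[VariantObservation] = []
    for i in range(config.n_probands):
        pid = f"S{i:05d}"
        monogenic = rng.random() < config.monogenic_fraction
        params = config.monogenic if monogenic else config.complex_aetiology
        diagnosis = diagnoses[int(rng.choice(len(diagnoses), p=dx_p / dx_p.sum()))]
        ancestry = ancestries[int(rng.choice(len(ancestries), p=anc_p / anc_p.sum()))]
        age = _truncated_normal(rng, params.onset_mean, params.onset_sd)
        fh = rng.random() < params.fh_prob
        severe = rng.random() < params.severe_prob
        flags = (
            SevereFeatures(sustained_vt=True)
            if severe
            else SevereFeatures(ejection_fraction_pct=55.0)
        )
        year_seen = int(rng.integers(2002, 2021))
        year_dx: int | None = None
        provenance = "clinical"

        if monogenic and rng.random() < config.detect_prob:
            gene = _causal_gene(diagnosis, registry, rng)
            if rng.random() < config.lpp_given_detect[ancestry]:
                template = _LP_TEMPLATES[int(rng.integers(len(_LP_TEMPLATES)))]
                consequence = ("missense", "nonsense", "frameshift")[
                    int(rng.integers(3))
                ]
                if rng.random() < config.tier2_rescue:
                    provenance = "research_tier2"
                year_dx = min(2020, year_seen + int(rng.integers(0, 6)))
            else:
                template = _SVUS_TEMPLATES[int(rng.integers(len(_SVUS_TEMPLATES)))]
                consequence = "missense"
            variants.append(
                VariantObservation(
                    proband_id=pid,
                    gene=gene,
                    variant_label=f"c.{i * 7 + 1}A>G",
                    consequence=consequence,
                    popmax_af=0.0,
                    criteria=parse_criteria_field(template),
                )
            )
        elif not monogenic and rng.random() < config.benign_variant_prob:
            variants.append(
                VariantObservation(
                    proband_id=pid,
                    gene="MYBPC3",
                    variant_label=f"c.{i * 7 + 2}C>T",
                    consequence="synonymous",
                    popmax_af=5e-3,
                    criteria=parse_criteria_field(
                        _BENIGN_TEMPLATES[int(rng.integers(len(_BENIGN_TEMPLATES)))]
                    ),
                )
            )

        probands.append(
            Proband(
                proband_id=pid,
                clinical_diagnosis=diagnosis,
                diagnosis_certainty=(
                    "uncertain"
                    if diagnosis in ("undiagnosed", "unexplained_SCA")
                    or diagnosis.startswith("possible_")
                    else "definite"
                ),
                age_at_diagnosis=age,
                n_affected_relatives=1 if fh else 0,
                severe_flags=flags,
                ancestry=ancestry,
                year_first_seen=year_seen,
                year_genetic_diagnosis=year_dx,
                testing_provenance=provenance,
            )
        )
    return probands, variants


def score_discrimination_experiment(
    config: SimulationConfig,
    n_reps: int,
    registry: GeneRegistry | None = None,
) -> dict:
    """Replicate the cohort, run the full pipeline, and summarise LP/P
    yield per score bucket.

    Returns per-bucket aggregate yields with binomial Monte-Carlo SE, the
    per-rep yield matrix, and a strict-monotonicity verdict on the
    aggregate yields.
    """
    from .adjudication import adjudicate_cohort
    from .score import BUCKETS

    registry = registry or default_registry()
    n = {b: 0 for b in BUCKETS}
    lpp = {b: 0 for b in BUCKETS}
    per_rep: list[dict[str, float | None]] = []
    for rep in range(n_reps):
        rep_config = config.model_copy(update={"seed": config.seed + rep})
        probands, variants = simulate_cohort(rep_config, registry)
        adjudicated = adjudicate_cohort(probands, variants, registry)
        rep_row: dict[str, float | None] = {}
        for b in BUCKETS:
            members = [a for a in adjudicated if a.score.bucket == b]
            k = sum(1 for a in members if a.has_lp_p)
            n[b] += len(members)
            lpp[b] += k
            rep_row[b] = k / len(members) if members else None
        per_rep.append(rep_row)

    yields = {b: (lpp[b] / n[b] if n[b] else None) for b in BUCKETS}
    se = {
        b: (
            math.sqrt(yields[b] * (1 - yields[b]) / n[b])
            if n[b] and yields[b] is not None
            else None
        )
        for b in BUCKETS
    }
    observed = [yields[b] for b in BUCKETS if yields[b] is not None]
    return {
        "n": n,
        "n_lpp": lpp,
        "yield": yields,
        "se": se,
        "per_rep": per_rep,
        "strictly_increasing": all(
            a < b for a, b in zip(observed, observed[1:])
        ),
    }
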