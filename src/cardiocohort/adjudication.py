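"""Final adjudication flow.

Each included proband is assigned exactly one category:

* ``solved_baseline`` — concordant LP/P found by clinical-provenance testing;
* ``solved_on_review`` — concordant LP/P requiring research-provenance effort;
* ``suspicious_vus`` — best variant a suspicious VUS (not counted unsolved);
* ``unsolved_likely_monogenic`` / ``unsolved_likely_complex`` — no LP/P and
  no suspicious VUS, split by monogenic score >= 1;
* ``discordant_LPP`` — LP/P discordant with the baseline phenotype and no
  reassignment rule applies (manual-review bucket, never silently solved);
* ``excluded_<reason>`` — excluded upstream, tabulated only.

Concordance: the gene carries a definitive or moderate association with the
baseline disease (``possible_X`` matches ``X``); for uncertain baselines
(undiagnosed / unexplained SCA / possible), any definitive association is
concordant — the genetic result supplies or refines the diagnosis, recorded
as ``clarified`` (same base disease) or ``changed`` (different disease).
For definite baselines, a discordant gene with a definitive association to
another disease is reassigned (``changed``) when ``allow_reassignment`` is
on, mirroring multidisciplinary review.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ScoreConfig, TriageConfig
from .model import (
    GeneRegistry,
    Proband,
    SchemaError,
    base_diagnosis,
    is_uncertain_diagnosis,
)
from .score import ScoreBreakdown, compute_score, likelihood_class
from .triage import ClassifiedVariant, classify_variant

__all__ = [
    "AdjudicatedProband",
    "select_best_variant",
    "concordant",
    "adjudicate",
    "adjudicate_cohort",
    "time_to_diagnosis",
    "ERA_SPLIT_YEAR",
]

IMPACT_TAGS = (
    "inheritance_risk",
    "family_screening",
    "investigation_frequency",
    "specialist_referral",
    "medication",
    "lifestyle",
)

ERA_SPLIT_YEAR = 2011  # first presentations 2002-2010 vs 2011-2020


@dataclass(frozen=True)
class AdjudicatedProband:
    proband: Proband
    best_variant: ClassifiedVariant | None
    score: ScoreBreakdown
    category: str
    diagnosis_change: str = "none"  # none | clarified | changed
    final_diagnosis: str | None = None
    impact_tags: frozenset[str] = frozenset()
    time_to_diagnosis_years: float | None = None
    era: str | None = None  # e2002_2010 | e2011_2020

    def __post_init__(self) -> None:
        if self.category == "suspicious_vus":
            if self.best_variant is None or not self.best_variant.suspicious_vus:
                raise SchemaError("suspicious_vus category requires a suspicious VUS")
        if self.category in ("solved_baseline", "solved_on_review"):
            if self.best_variant is None or not self.best_variant.classification.is_lp_p:
                raise SchemaError(f"{self.category} requires an LP/P best variant")
        if self.category.startswith("unsolved"):
            if self.best_variant is not None and (
                self.best_variant.classification.is_lp_p
                or self.best_variant.suspicious_vus
            ):
                raise SchemaError("unsolved category with causal-grade variant")
        unknown = self.impact_tags - set(IMPACT_TAGS)
        if unknown:
            raise SchemaError(f"unknown impact tags: {sorted(unknown)}")

    @property
    def has_lp_p(self) -> bool:
        return self.best_variant is not None and self.best_variant.classification.is_lp_p

    @property
    def has_suspicious_vus(self) -> bool:
        return self.best_variant is not None and self.best_variant.suspicious_vus


def select_best_variant(
    classified: list[ClassifiedVariant],
) -> ClassifiedVariant | None:
    """Deterministic, order-independent best-variant pick: highest
    classification, then suspicious flag, then lexicographic gene symbol."""
    if not classified:
        return None
    return min(
        classified,
        key=lambda cv: (
            -cv.classification.rank,
            not cv.suspicious_vus,
            cv.observation.gene,
            cv.observation.variant_label,
        ),
    )


def concordant(diagnosis: str, gene: str, registry: GeneRegistry) -> bool:
    """Clinical diagnosis / genetic finding concordance (see module doc)."""
    base = base_diagnosis(diagnosis)
    if base is not None:
        validity = registry.validity(gene, base)
        if validity in ("definitive", "moderate"):
            return True
    if is_uncertain_diagnosis(diagnosis):
        return bool(registry.definitive_diseases(gene))
    return False


def _resolve_solved(
    proband: Proband,
    gene: str,
    registry: GeneRegistry,
    allow_reassignment: bool,
) -> tuple[bool, str, str | None]:
    """Return (solved, diagnosis_change, final_diagnosis) for an LP/P gene."""
    dx = proband.clinical_diagnosis
    base = base_diagnosis(dx)
    uncertain = is_uncertain_diagnosis(dx)

    if base is not None and registry.validity(gene, base) in ("definitive", "moderate"):
        if uncertain:
            return True, "clarified", base  # possible_X confirmed as X
        return True, "none", base

    definitive = registry.definitive_diseases(gene)
    if not definitive:
        return False, "none", None
    new_dx = sorted(definitive)[0]
    if uncertain:
        # genetic result supplies the diagnosis
        change = "clarified" if base is not None and new_dx == base else "changed"
        return True, change, new_dx
    if allow_reassignment:
        return True, "changed", new_dx
    return False, "none", None


def time_to_diagnosis(proband: Proband) -> tuple[float | None, str | None]:
    """Years from first presentation to genetic diagnosis, and the era of
    first presentation. Missing years yield (None, era-if-known)."""
    era = (
        "e2002_2010" if proband.year_first_seen < ERA_SPLIT_YEAR else "e2011_2020"
    )
    if proband.year_genetic_diagnosis is None:
        return None, era
    return float(proband.year_genetic_diagnosis - proband.year_first_seen), era


def adjudicate(
    proband: Proband,
    best_variant: ClassifiedVariant | None,
    score: ScoreBreakdown,
    registry: GeneRegistry,
    *,
    triage_config: TriageConfig | None = None,
    impact_tags: frozenset[str] = frozenset(),
) -> AdjudicatedProband:
    cfg = triage_config or TriageConfig()

    if proband.excluded_reason is not None:
        return AdjudicatedProband(
            proband, None, score, f"excluded_{proband.excluded_reason}"
        )

    ttd, era = time_to_diagnosis(proband)

    if best_variant is not None and best_variant.classification.is_lp_p:
        solved, change, final_dx = _resolve_solved(
            proband, best_variant.observation.gene, registry, cfg.allow_reassignment
        )
        if solved:
            category = (
                "solved_on_review"
                if proband.testing_provenance == "research_tier2"
                else "solved_baseline"
            )
            return AdjudicatedProband(
                proband,
                best_variant,
                score,
                category,
                diagnosis_change=change,
                final_diagnosis=final_dx,
                impact_tags=impact_tags,
                time_to_diagnosis_years=ttd,
                era=era,
            )
        return AdjudicatedProband(
            proband,
            best_variant,
            score,
            "discordant_LPP",
            impact_tags=impact_tags,
            era=era,
        )

    if best_variant is not None and best_variant.suspicious_vus:
        change = "clarified" if is_uncertain_diagnosis(proband.clinical_diagnosis) else "none"
        return AdjudicatedProband(
            proband,
            best_variant,
            score,
            "suspicious_vus",
            diagnosis_change=change,
            final_diagnosis=base_diagnosis(proband.clinical_diagnosis),
            impact_tags=impact_tags,
            era=era,
        )

    category = f"unsolved_{likelihood_class(score.total, 'unsolved')}"
    return AdjudicatedProband(proband, best_variant, score, category, era=era)


def adjudicate_cohort(
    probands: list[Proband],
    observations,
    registry: GeneRegistry,
    *,
    score_config: ScoreConfig | None = None,
    triage_config: TriageConfig | None = None,
) -> list[AdjudicatedProband]:
    """Run triage -> score -> adjudication over a whole cohort.

    Variant observations are linked by proband_id; probands may carry any
    number of variants. The category partition invariant (every included
    proband in exactly one category) is asserted before returning.
    """
    cfg = triage_config or TriageConfig()
    by_proband: dict[str, list] = {}
    for obs in observations:
        by_proband.setdefault(obs.proband_id, []).append(obs)

    out: list[AdjudicatedProband] = []
    for proband in probands:
        classified = [
            classify_variant(
                obs,
                proband.clinical_diagnosis,
                registry,
                require_non_frequency_criterion=cfg.require_non_frequency_criterion,
            )
            for obs in by_proband.get(proband.proband_id, [])
        ]
        best = select_best_variant(classified)
        score = compute_score(proband, score_config)
        out.append(
            adjudicate(proband, best, score, registry, triage_config=cfg)
        )

    included = [a for a in out if not a.category.startswith("excluded")]
    assert len(included) == sum(
        1 for p in probands if p.excluded_reason is None
    ), "category partition violated"
    for a in included:
        if a.has_suspicious_vus and a.category == "suspicious_vus":
            assert a.best_variant.classification.value == "VUS"
    return out
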