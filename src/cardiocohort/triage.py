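"""Evidence combination and suspicious-VUS triage.

:func:`combine_criteria` implements the categorical ACMG/AMP combining
rules over strength-counted evidence, with strength-shifted codes counted
at their shifted strength (so ``PS4_moderate`` contributes one moderate,
``PVS1_moderate`` one moderate, ``PM1_supporting`` one supporting).

A variant classified VUS is additionally flagged *suspicious* when it is
rare below the disease-specific maximum credible popmax frequency, lies in
a gene with a definitive association to the proband's baseline phenotype,
is predicted to alter the protein sequence, and carries at least one
pathogenic-direction criterion without stand-alone/strong benign evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import (
    EvidenceCriterion,
    GeneRegistry,
    SchemaError,
    Strength,
    VariantObservation,
    base_diagnosis,
)

__all__ = [
    "Classification",
    "ClassifiedVariant",
    "combine_criteria",
    "meets_rarity",
    "is_protein_altering",
    "assess_suspicious_vus",
    "classify_variant",
]

# Total order, benign < ... < pathogenic.
_CLASS_ORDER = {
    "benign": 0,
    "likely_benign": 1,
    "VUS": 2,
    "likely_pathogenic": 3,
    "pathogenic": 4,
}


@dataclass(frozen=True, order=False)
class Classification:
    value: str

    def __post_init__(self) -> None:
        if self.value not in _CLASS_ORDER:
            raise SchemaError(f"unknown classification {self.value!r}")

    @property
    def rank(self) -> int:
        return _CLASS_ORDER[self.value]

    @property
    def is_lp_p(self) -> bool:
        return self.value in ("pathogenic", "likely_pathogenic")

    def __lt__(self, other: "Classification") -> bool:
        return self.rank < other.rank

    def __le__(self, other: "Classification") -> bool:
        return self.rank <= other.rank

    def __str__(self) -> str:
        return self.value


PATHOGENIC = Classification("pathogenic")
LIKELY_PATHOGENIC = Classification("likely_pathogenic")
VUS = Classification("VUS")
LIKELY_BENIGN = Classification("likely_benign")
BENIGN = Classification("benign")


@dataclass(frozen=True)
class ClassifiedVariant:
    observation: VariantObservation
    classification: Classification
    suspicious_vus: bool = False
    triage_reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.suspicious_vus and self.classification != VUS:
            raise SchemaError("suspicious_vus requires a VUS classification")


def _strength_counts(criteria: frozenset[EvidenceCriterion]):
    seen = Counter(c.base_code for c in criteria)
    dupes = [code for code, n in seen.items() if n > 1]
    if dupes:
        raise SchemaError(
            f"criteria applied at multiple strengths: {', '.join(sorted(dupes))}"
        )
    path = Counter(c.strength for c in criteria if c.is_pathogenic_direction)
    benign = Counter(c.strength for c in criteria if c.is_benign_direction)
    return path, benign


def _pathogenic_tier(path: Counter) -> str:
    """Categorical pathogenic-direction combination: P, LP or VUS."""
    vs = path[Strength.very_strong] + path[Strength.stand_alone]
    s = path[Strength.strong]
    m = path[Strength.moderate]
    p = path[Strength.supporting]

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or vs >= 2
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    if pathogenic:
        return "pathogenic"
    likely = (
        (vs >= 1 and m >= 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    return "likely_pathogenic" if likely else "VUS"


def _benign_tier(benign: Counter) -> str:
    """Categorical benign-direction combination: B, LB or VUS.

    Benign codes are canonically stand-alone (BA1), strong (BS) or
    supporting (BP); shifted strengths are binned conservatively
    (very_strong→strong, moderate→supporting).
    """
    sa = benign[Strength.stand_alone]
    s = benign[Strength.strong] + benign[Strength.very_strong]
    p = benign[Strength.supporting] + benign[Strength.moderate]
    if sa >= 1 or s >= 2:
        return "benign"
    if (s == 1 and p >= 1) or p >= 2:
        return "likely_benign"
    return "VUS"


def combine_criteria(criteria: frozenset[EvidenceCriterion]) -> Classification:
    """Combine applied criteria into a five-tier classification.

    Conflicting pathogenic- and benign-direction combinations resolve to
    VUS (never an error); insufficient evidence is VUS.
    """
    path, benign = _strength_counts(criteria)
    p_tier = _pathogenic_tier(path)
    b_tier = _benign_tier(benign)
    if p_tier != "VUS" and b_tier != "VUS":
        return VUS
    if p_tier != "VUS":
        return Classification(p_tier)
    if b_tier != "VUS":
        return Classification(b_tier)
    return VUS


def meets_rarity(popmax_af: float, disease: str, registry: GeneRegistry) -> bool:
    """True iff strictly below the disease's maximum credible popmax AF."""
    return popmax_af < registry.threshold(disease)


_NON_PROTEIN_ALTERING = frozenset({"synonymous"})


def is_protein_altering(consequence: str) -> bool:
    """Predicted to alter the protein sequence; plain synonymous is not,
    but predicted-splice subtypes (incl. synonymous ones) are."""
    return consequence not in _NON_PROTEIN_ALTERING


def _has_strong_benign(criteria: frozenset[EvidenceCriterion]) -> bool:
    return any(
        c.is_benign_direction and c.strength >= Strength.strong for c in criteria
    )


def assess_suspicious_vus(
    classification: Classification,
    observation: VariantObservation,
    baseline_diagnosis: str,
    registry: GeneRegistry,
    *,
    require_non_frequency_criterion: bool = False,
) -> tuple[bool, list[str]]:
    """Suspicious-VUS rule; returns (verdict, reasons consulted).

    With ``require_non_frequency_criterion`` the "some evidence for
    causation" clause demands a pathogenic-direction criterion other than
    the rarity code PM2.
    """
    reasons: list[str] = []

    if classification != VUS:
        reasons.append(f"classification={classification}: only VUS eligible")
        return False, reasons
    reasons.append("classification=VUS")

    base = base_diagnosis(baseline_diagnosis)
    if base is None:
        reasons.append(
            f"baseline diagnosis {baseline_diagnosis!r} has no base phenotype to match"
        )
        return False, reasons

    if not meets_rarity(observation.popmax_af, base, registry):
        reasons.append(
            f"popmax_af {observation.popmax_af:g} not below "
            f"{base} threshold {registry.threshold(base):g}"
        )
        return False, reasons
    reasons.append(f"rare below {base} max credible AF")

    validity = registry.validity(observation.gene, base)
    if validity != "definitive":
        reasons.append(
            f"gene {observation.gene} lacks definitive association with {base}"
            + (f" (validity={validity})" if validity else "")
        )
        return False, reasons
    reasons.append(f"gene {observation.gene} definitively associated with {base}")

    if not is_protein_altering(observation.consequence):
        reasons.append(f"consequence {observation.consequence} not protein-altering")
        return False, reasons
    reasons.append(f"protein-altering consequence ({observation.consequence})")

    path_criteria = [c for c in observation.criteria if c.is_pathogenic_direction]
    if require_non_frequency_criterion:
        path_criteria = [c for c in path_criteria if c.base_code != "PM2"]
    if not path_criteria:
        reasons.append("no pathogenic-direction evidence present")
        return False, reasons
    reasons.append(
        "pathogenic-direction evidence: "
        + ";".join(sorted(c.render() for c in path_criteria))
    )

    if _has_strong_benign(observation.criteria):
        reasons.append("strong/stand-alone benign evidence blocks suspicious flag")
        return False, reasons

    reasons.append("suspicious VUS")
    return True, reasons


def classify_variant(
    observation: VariantObservation,
    baseline_diagnosis: str,
    registry: GeneRegistry,
    *,
    require_non_frequency_criterion: bool = False,
) -> ClassifiedVariant:
    """Combine criteria (or honour an asserted classification) and apply the
    suspicious-VUS rules."""
    reasons: list[str] = []
    if observation.asserted_classification is not None:
        classification = Classification(observation.asserted_classification)
        reasons.append(f"asserted classification {classification} (provenance: input)")
    else:
        classification = combine_criteria(observation.criteria)
        reasons.append(f"combined criteria -> {classification}")
    suspicious, rule_reasons = assess_suspicious_vus(
        classification,
        observation,
        baseline_diagnosis,
        registry,
        require_non_frequency_criterion=require_non_frequency_criterion,
    )
    reasons.extend(rule_reasons)
    return ClassifiedVariant(
        observation=observation,
        classification=classification,
        suspicious_vus=suspicious,
        triage_reasons=tuple(reasons),
    )
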