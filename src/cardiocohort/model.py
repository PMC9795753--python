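"""Domain model and table I/O for the cohort adjudication pipeline.

The pipeline consumes three plain-text inputs:

* a per-proband phenotype table (TSV, ``.`` = missing),
* a per-variant observation table (TSV; criteria are semicolon-separated
  ACMG/AMP codes such as ``PM2;PP3;PS4_moderate``),
* a gene registry with per-disease maximum credible popmax allele
  frequencies (JSON or YAML).

All readers are strict: unknown enum values, malformed numbers and
invariant violations raise :class:`SchemaError` with the offending row.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "Strength",
    "EvidenceCriterion",
    "SevereFeatures",
    "Proband",
    "VariantObservation",
    "GeneAssociation",
    "GeneEntry",
    "GeneRegistry",
    "BASE_DIAGNOSES",
    "base_diagnosis",
    "is_uncertain_diagnosis",
    "parse_criterion",
    "parse_criteria_field",
    "read_proband_table",
    "write_proband_table",
    "read_variant_table",
    "write_variant_table",
    "ingest_vcf",
    "load_gene_registry",
    "default_registry",
]

MISSING = "."


class SchemaError(ValueError):
    """Raised for malformed input tables, rows, or registry documents."""


# --------------------------------------------------------------------------
# Controlled vocabularies
# --------------------------------------------------------------------------

#: Definite clinical diagnoses recognised by the pipeline. Uncertain
#: diagnoses are ``undiagnosed``, ``unexplained_SCA`` and ``possible_<dx>``.
BASE_DIAGNOSES = frozenset(
    {"HCM", "DCM", "LVNC", "ACM", "BrS", "LQTS", "CPVT", "RCM", "NoonanLVH", "SSS"}
)

_UNCERTAIN_SPECIALS = frozenset({"undiagnosed", "unexplained_SCA"})

ANCESTRIES = (
    "European",
    "EastAsian",
    "SouthCentralAsian",
    "MiddleEasternNorthAfrican",
    "Other",
    "Unknown",
)

PROVENANCES = ("clinical", "research_tier2", "none")

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "canonical_splice",
    "splice_region_predicted",
    "deep_intronic_splice_predicted",
    "synonymous",
    "synonymous_splice_predicted",
    "inframe_indel",
    "structural",
)

VALIDITIES = ("definitive", "moderate", "limited")

CLASSIFICATION_VALUES = (
    "pathogenic",
    "likely_pathogenic",
    "VUS",
    "likely_benign",
    "benign",
)


def is_uncertain_diagnosis(diagnosis: str) -> bool:
    """True for undiagnosed / unexplained-SCA / possible_* baselines."""
    return diagnosis in _UNCERTAIN_SPECIALS or diagnosis.startswith("possible_")


def base_diagnosis(diagnosis: str) -> str | None:
    """Strip the ``possible_`` prefix; ``None`` when no base disease exists."""
    if diagnosis in BASE_DIAGNOSES:
        return diagnosis
    if diagnosis.startswith("possible_"):
        base = diagnosis[len("possible_") :]
        if base in BASE_DIAGNOSES:
            return base
    return None


def _validate_diagnosis(diagnosis: str) -> None:
    if diagnosis in BASE_DIAGNOSES or diagnosis in _UNCERTAIN_SPECIALS:
        return
    if diagnosis.startswith("possible_") and base_diagnosis(diagnosis) is not None:
        return
    raise SchemaError(f"unknown clinical diagnosis {diagnosis!r}")


# --------------------------------------------------------------------------
# ACMG/AMP evidence criteria
# --------------------------------------------------------------------------


class Strength(enum.IntEnum):
    """Evidence strength, ordered weakest to strongest."""

    supporting = 1
    moderate = 2
    strong = 3
    very_strong = 4
    stand_alone = 5


#: Canonical (unmodified) strength per code prefix.
_CANONICAL_BY_PREFIX = {
    "PVS": Strength.very_strong,
    "PS": Strength.strong,
    "PM": Strength.moderate,
    "PP": Strength.supporting,
    "BA": Strength.stand_alone,
    "BS": Strength.strong,
    "BP": Strength.supporting,
}

PATHOGENIC_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_CODES = frozenset(
    {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
)
KNOWN_CODES = PATHOGENIC_CODES | BENIGN_CODES


def canonical_strength(base_code: str) -> Strength:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if base_code.startswith(prefix):
            return _CANONICAL_BY_PREFIX[prefix]
    raise SchemaError(f"unknown criterion code {base_code!r}")


@dataclass(frozen=True, order=True)
class EvidenceCriterion:
    """One applied ACMG/AMP criterion, possibly at a shifted strength."""

    base_code: str
    strength: Strength

    def __post_init__(self) -> None:
        if self.base_code not in KNOWN_CODES:
            raise SchemaError(f"unknown criterion code {self.base_code!r}")

    @property
    def is_pathogenic_direction(self) -> bool:
        return self.base_code in PATHOGENIC_CODES

    @property
    def is_benign_direction(self) -> bool:
        return self.base_code in BENIGN_CODES

    def render(self) -> str:
        """Canonical string form, e.g. ``PS4_moderate`` or ``PM2``."""
        if self.strength == canonical_strength(self.base_code):
            return self.base_code
        return f"{self.base_code}_{self.strength.name}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_criterion(token: str) -> EvidenceCriterion:
    """Parse one code token such as ``PM2`` or ``PVS1_moderate``."""
    token = token.strip()
    if not token:
        raise SchemaError("empty criterion token")
    code, _, suffix = token.partition("_")
    code = code.upper()
    if code not in KNOWN_CODES:
        raise SchemaError(f"unknown criterion code {token!r}")
    if suffix:
        suffix = suffix.lower()
        if suffix == "standalone":
            suffix = "stand_alone"
        try:
            strength = Strength[suffix]
        except KeyError:
            raise SchemaError(f"unknown strength modifier in {token!r}") from None
    else:
        strength = canonical_strength(code)
    return EvidenceCriterion(code, strength)


def parse_criteria_field(text: str) -> frozenset[EvidenceCriterion]:
    """Parse a semicolon-separated criteria field; ``.``/empty → no criteria."""
    text = text.strip()
    if not text or text == MISSING:
        return frozenset()
    crits = [parse_criterion(tok) for tok in text.split(";") if tok.strip()]
    seen: dict[str, EvidenceCriterion] = {}
    for c in crits:
        if c.base_code in seen and seen[c.base_code] != c:
            raise SchemaError(
                f"criterion {c.base_code} applied at two strengths in {text!r}"
            )
        seen[c.base_code] = c
    return frozenset(seen.values())


def render_criteria(criteria: Iterable[EvidenceCriterion]) -> str:
    toks = sorted(c.render() for c in criteria)
    return ";".join(toks) if toks else MISSING


# --------------------------------------------------------------------------
# Probands
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SevereFeatures:
    """Event flags and continuous measures feeding the severe-phenotype rule."""

    scd_or_resuscitated_arrest: bool = False
    sustained_vt: bool = False
    appropriate_icd_shock: bool = False
    cardiac_transplant: bool = False
    lvad: bool = False
    ejection_fraction_pct: float | None = None
    max_lvh_mm: float | None = None
    qtc_ms: float | None = None

    def __post_init__(self) -> None:
        for name in ("ejection_fraction_pct", "max_lvh_mm", "qtc_ms"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise SchemaError(f"{name} must be a non-negative number, got {v!r}")
        ef = self.ejection_fraction_pct
        if ef is not None and ef > 100:
            raise SchemaError(f"ejection_fraction_pct must be in [0, 100], got {ef!r}")

    @property
    def any_event_flag(self) -> bool:
        return (
            self.scd_or_resuscitated_arrest
            or self.sustained_vt
            or self.appropriate_icd_shock
            or self.cardiac_transplant
            or self.lvad
        )


@dataclass(frozen=True)
class Proband:
    """One clinic proband: phenotype, family history, ancestry, provenance."""

    proband_id: str
    clinical_diagnosis: str
    diagnosis_certainty: str
    age_at_diagnosis: float | None
    n_affected_relatives: int
    severe_flags: SevereFeatures
    ancestry: str
    year_first_seen: int
    year_genetic_diagnosis: int | None = None
    testing_provenance: str = "clinical"
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        _validate_diagnosis(self.clinical_diagnosis)
        if self.diagnosis_certainty not in ("definite", "uncertain"):
            raise SchemaError(
                f"diagnosis_certainty must be definite|uncertain, "
                f"got {self.diagnosis_certainty!r}"
            )
        uncertain = is_uncertain_diagnosis(self.clinical_diagnosis)
        if uncertain != (self.diagnosis_certainty == "uncertain"):
            raise SchemaError(
                f"proband {self.proband_id}: certainty {self.diagnosis_certainty!r} "
                f"inconsistent with diagnosis {self.clinical_diagnosis!r}"
            )
        if self.age_at_diagnosis is not None and (
            not math.isfinite(self.age_at_diagnosis) or self.age_at_diagnosis < 0
        ):
            raise SchemaError(
                f"proband {self.proband_id}: age_at_diagnosis must be >= 0, "
                f"got {self.age_at_diagnosis!r}"
            )
        if self.n_affected_relatives < 0:
            raise SchemaError(
                f"proband {self.proband_id}: n_affected_relatives must be >= 0"
            )
        if self.ancestry not in ANCESTRIES:
            raise SchemaError(
                f"proband {self.proband_id}: unknown ancestry {self.ancestry!r}"
            )
        if self.testing_provenance not in PROVENANCES:
            raise SchemaError(
                f"proband {self.proband_id}: unknown testing_provenance "
                f"{self.testing_provenance!r}"
            )
        if (
            self.year_genetic_diagnosis is not None
            and self.year_genetic_diagnosis < self.year_first_seen
        ):
            raise SchemaError(
                f"proband {self.proband_id}: year_genetic_diagnosis "
                f"{self.year_genetic_diagnosis} precedes year_first_seen "
                f"{self.year_first_seen}"
            )


# --------------------------------------------------------------------------
# Variant observations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantObservation:
    """A reported variant with its applied evidence codes.

    ``popmax_af`` codes "absent from the reference database" as 0; when that
    zero was imputed (e.g. a VCF record lacking the AF key) the
    ``af_assumed_absent`` flag records it.
    """

    proband_id: str
    gene: str
    variant_label: str
    consequence: str
    popmax_af: float = 0.0
    criteria: frozenset[EvidenceCriterion] = frozenset()
    asserted_classification: str | None = None
    af_assumed_absent: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise SchemaError(f"unknown consequence {self.consequence!r}")
        if not (0.0 <= self.popmax_af <= 1.0):
            raise SchemaError(
                f"popmax_af must be in [0, 1], got {self.popmax_af!r}"
            )
        if (
            self.asserted_classification is not None
            and self.asserted_classification not in CLASSIFICATION_VALUES
        ):
            raise SchemaError(
                f"unknown asserted_classification {self.asserted_classification!r}"
            )


# --------------------------------------------------------------------------
# Gene registry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAssociation:
    disease: str
    validity: str

    def __post_init__(self) -> None:
        if self.validity not in VALIDITIES:
            raise SchemaError(f"unknown validity {self.validity!r}")


@dataclass(frozen=True)
class GeneEntry:
    tier: str
    associations: tuple[GeneAssociation, ...]

    def __post_init__(self) -> None:
        if self.tier not in ("tier1", "tier2"):
            raise SchemaError(f"unknown tier {self.tier!r}")


#: Default maximum credible popmax allele frequency: 4e-5 for HCM, more
#: stringent 1e-5 for all less prevalent diseases.
DEFAULT_MAX_CREDIBLE_AF = {"HCM": 4e-5}
DEFAULT_OTHER_DISEASE_AF = 1e-5


@dataclass
class GeneRegistry:
    """Gene → tier and disease-validity associations, plus per-disease
    maximum credible popmax allele-frequency thresholds."""

    genes: dict[str, GeneEntry]
    max_credible_popmax_af: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        thresholds = dict(DEFAULT_MAX_CREDIBLE_AF)
        thresholds.update(self.max_credible_popmax_af)
        for disease in self.diseases():
            thresholds.setdefault(disease, DEFAULT_OTHER_DISEASE_AF)
        for disease in BASE_DIAGNOSES:
            thresholds.setdefault(
                disease, DEFAULT_MAX_CREDIBLE_AF.get(disease, DEFAULT_OTHER_DISEASE_AF)
            )
        self.max_credible_popmax_af = thresholds
        self.validate()

    def diseases(self) -> set[str]:
        return {a.disease for e in self.genes.values() for a in e.associations}

    def validate(self) -> None:
        for gene, entry in self.genes.items():
            if entry.tier == "tier1" and not any(
                a.validity == "definitive" for a in entry.associations
            ):
                raise SchemaError(
                    f"tier1 gene {gene} has no definitive disease association"
                )
        for disease, af in self.max_credible_popmax_af.items():
            if not (0.0 < af <= 1.0):
                raise SchemaError(
                    f"max_credible_popmax_af for {disease} must be in (0, 1]"
                )

    # -- queries ----------------------------------------------------------

    def entry(self, gene: str) -> GeneEntry:
        try:
            return self.genes[gene]
        except KeyError:
            raise SchemaError(f"gene {gene!r} absent from registry") from None

    def threshold(self, disease: str) -> float:
        try:
            return self.max_credible_popmax_af[disease]
        except KeyError:
            raise SchemaError(
                f"no max_credible_popmax_af threshold for disease {disease!r}"
            ) from None

    def validity(self, gene: str, disease: str) -> str | None:
        """Validity of the gene's association with ``disease``, if any."""
        for assoc in self.entry(gene).associations:
            if assoc.disease == disease:
                return assoc.validity
        return None

    def definitive_diseases(self, gene: str) -> tuple[str, ...]:
        return tuple(
            a.disease
            for a in self.entry(gene).associations
            if a.validity == "definitive"
        )


# --------------------------------------------------------------------------
# TSV readers / writers
# --------------------------------------------------------------------------

PROBAND_COLUMNS = [
    "proband_id",
    "clinical_diagnosis",
    "diagnosis_certainty",
    "age_at_diagnosis",
    "n_affected_relatives",
    "scd_or_resuscitated_arrest",
    "sustained_vt",
    "appropriate_icd_shock",
    "cardiac_transplant",
    "lvad",
    "ejection_fraction_pct",
    "max_lvh_mm",
    "qtc_ms",
    "ancestry",
    "year_first_seen",
    "year_genetic_diagnosis",
    "testing_provenance",
    "excluded_reason",
]

VARIANT_COLUMNS = [
    "proband_id",
    "gene",
    "variant_label",
    "consequence",
    "popmax_af",
    "criteria",
    "asserted_classification",
    "af_assumed_absent",
]

_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False}


def _opt_float(value: str, column: str, row: int) -> float | None:
    if value == MISSING or value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"row {row}: column {column}: not a number: {value!r}")


def _opt_int(value: str, column: str, row: int) -> int | None:
    if value == MISSING or value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise SchemaError(f"row {row}: column {column}: not an integer: {value!r}")


def _bool(value: str, column: str, row: int) -> bool:
    try:
        return _BOOL_TOKENS[value.strip().lower()]
    except KeyError:
        raise SchemaError(f"row {row}: column {column}: not a boolean: {value!r}")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_proband_table(path: str | Path, schema_config: Mapping | None = None) -> list[Proband]:
    """Read a proband TSV.

    Row numbers in error messages are 1-based data rows (header excluded).
    ``schema_config`` may rename columns via ``{"columns": {canonical: actual}}``.
    """
    colmap = dict((schema_config or {}).get("columns", {}))
    required = [colmap.get(c, c) for c in PROBAND_COLUMNS if c != "excluded_reason"]
    df = _read_tsv(path, required)

    def col(row: pd.Series, name: str) -> str:
        actual = colmap.get(name, name)
        return str(row[actual]).strip() if actual in row.index else MISSING

    probands: list[Proband] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            age = _opt_float(col(row, "age_at_diagnosis"), "age_at_diagnosis", i)
            flags = SevereFeatures(
                scd_or_resuscitated_arrest=_bool(
                    col(row, "scd_or_resuscitated_arrest"), "scd_or_resuscitated_arrest", i
                ),
                sustained_vt=_bool(col(row, "sustained_vt"), "sustained_vt", i),
                appropriate_icd_shock=_bool(
                    col(row, "appropriate_icd_shock"), "appropriate_icd_shock", i
                ),
                cardiac_transplant=_bool(
                    col(row, "cardiac_transplant"), "cardiac_transplant", i
                ),
                lvad=_bool(col(row, "lvad"), "lvad", i),
                ejection_fraction_pct=_opt_float(
                    col(row, "ejection_fraction_pct"), "ejection_fraction_pct", i
                ),
                max_lvh_mm=_opt_float(col(row, "max_lvh_mm"), "max_lvh_mm", i),
                qtc_ms=_opt_float(col(row, "qtc_ms"), "qtc_ms", i),
            )
            n_rel = _opt_int(col(row, "n_affected_relatives"), "n_affected_relatives", i)
            year_seen = _opt_int(col(row, "year_first_seen"), "year_first_seen", i)
            if n_rel is None or year_seen is None:
                raise SchemaError(
                    f"row {i}: n_affected_relatives and year_first_seen are required"
                )
            excl = col(row, "excluded_reason")
            probands.append(
                Proband(
                    proband_id=col(row, "proband_id"),
                    clinical_diagnosis=col(row, "clinical_diagnosis"),
                    diagnosis_certainty=col(row, "diagnosis_certainty"),
                    age_at_diagnosis=age,
                    n_affected_relatives=n_rel,
                    severe_flags=flags,
                    ancestry=col(row, "ancestry"),
                    year_first_seen=year_seen,
                    year_genetic_diagnosis=_opt_int(
                        col(row, "year_genetic_diagnosis"), "year_genetic_diagnosis", i
                    ),
                    testing_provenance=col(row, "testing_provenance"),
                    excluded_reason=None if excl in (MISSING, "") else excl,
                )
            )
        except SchemaError as err:
            raise SchemaError(f"{path}: row {i}: {err}") from None
    return probands


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    return str(value)


def write_proband_table(probands: Iterable[Proband], path: str | Path) -> None:
    rows = []
    for p in probands:
        f = p.severe_flags
        rows.append(
            {
                "proband_id": p.proband_id,
                "clinical_diagnosis": p.clinical_diagnosis,
                "diagnosis_certainty": p.diagnosis_certainty,
                "age_at_diagnosis": _fmt(p.age_at_diagnosis),
                "n_affected_relatives": _fmt(p.n_affected_relatives),
                "scd_or_resuscitated_arrest": _fmt(f.scd_or_resuscitated_arrest),
                "sustained_vt": _fmt(f.sustained_vt),
                "appropriate_icd_shock": _fmt(f.appropriate_icd_shock),
                "cardiac_transplant": _fmt(f.cardiac_transplant),
                "lvad": _fmt(f.lvad),
                "ejection_fraction_pct": _fmt(f.ejection_fraction_pct),
                "max_lvh_mm": _fmt(f.max_lvh_mm),
                "qtc_ms": _fmt(f.qtc_ms),
                "ancestry": p.ancestry,
                "year_first_seen": _fmt(p.year_first_seen),
                "year_genetic_diagnosis": _fmt(p.year_genetic_diagnosis),
                "testing_provenance": p.testing_provenance,
                "excluded_reason": _fmt(p.excluded_reason),
            }
        )
    pd.DataFrame(rows, columns=PROBAND_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[VariantObservation]:
    """Read a variant observation TSV; criteria parsed to canonical codes."""
    df = _read_tsv(path, [c for c in VARIANT_COLUMNS if c != "af_assumed_absent"])
    out: list[VariantObservation] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            af = _opt_float(str(row["popmax_af"]).strip(), "popmax_af", i)
            asserted = str(row["asserted_classification"]).strip()
            flagged = str(row.get("af_assumed_absent", "0")).strip()
            out.append(
                VariantObservation(
                    proband_id=str(row["proband_id"]).strip(),
                    gene=str(row["gene"]).strip(),
                    variant_label=str(row["variant_label"]).strip(),
                    consequence=str(row["consequence"]).strip(),
                    popmax_af=0.0 if af is None else af,
                    criteria=parse_criteria_field(str(row["criteria"])),
                    asserted_classification=(
                        None if asserted in (MISSING, "") else asserted
                    ),
                    af_assumed_absent=(
                        af is None
                        if flagged in (MISSING, "")
                        else _bool(flagged, "af_assumed_absent", i)
                    ),
                )
            )
        except SchemaError as err:
            raise SchemaError(f"{path}: row {i}: {err}") from None
    return out


def write_variant_table(observations: Iterable[VariantObservation], path: str | Path) -> None:
    rows = []
    for v in observations:
        rows.append(
            {
                "proband_id": v.proband_id,
                "gene": v.gene,
                "variant_label": v.variant_label,
                "consequence": v.consequence,
                "popmax_af": _fmt(v.popmax_af) if v.popmax_af else "0",
                "criteria": render_criteria(v.criteria),
                "asserted_classification": _fmt(v.asserted_classification),
                "af_assumed_absent": _fmt(v.af_assumed_absent),
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# VCF ingestion
# --------------------------------------------------------------------------

DEFAULT_INFO_KEY_MAP = {
    "gene": "GENE",
    "consequence": "CSQ_CLASS",
    "popmax_af": "POPMAX_AF",
    "criteria": "ACMG",
}


def ingest_vcf(
    path: str | Path,
    info_key_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantObservation], int]:
    """Ingest variant observations from an annotated VCF.

    INFO keys (names configurable through ``info_key_map``) supply gene,
    consequence, popmax AF and criteria; each sample carrying a non-reference
    genotype yields one observation with that sample name as proband_id.
    Coordinates are folded into an opaque ``chrom:pos:ref>alt`` label only.

    Returns ``(observations, n_skipped)`` where skipped records lacked a
    mapped gene/consequence key.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    keys = dict(DEFAULT_INFO_KEY_MAP)
    keys.update(info_key_map or {})
    try:
        vcf = VCF(str(path))
    except Exception as err:  # cyvcf2 raises bare exceptions on bad input
        raise SchemaError(f"{path}: malformed VCF: {err}") from None

    samples = list(vcf.samples)
    observations: list[VariantObservation] = []
    skipped = 0
    try:
        for record in vcf:
            gene = record.INFO.get(keys["gene"])
            consequence = record.INFO.get(keys["consequence"])
            if gene is None or consequence is None:
                skipped += 1
                continue
            raw_af = record.INFO.get(keys["popmax_af"])
            criteria = parse_criteria_field(str(record.INFO.get(keys["criteria"]) or ""))
            alt = record.ALT[0] if record.ALT else "."
            label = f"{record.CHROM}:{record.POS}:{record.REF}>{alt}"
            if samples:
                carriers = [
                    samples[i]
                    for i, gt in enumerate(record.genotypes)
                    if any(a not in (0, -1) for a in gt[:-1])
                ]
            else:
                carriers = []
            for proband_id in carriers:
                observations.append(
                    VariantObservation(
                        proband_id=proband_id,
                        gene=str(gene),
                        variant_label=label,
                        consequence=str(consequence),
                        popmax_af=0.0 if raw_af is None else float(raw_af),
                        criteria=criteria,
                        af_assumed_absent=raw_af is None,
                    )
                )
    except Exception as err:
        if isinstance(err, SchemaError):
            raise
        raise SchemaError(f"{path}: malformed VCF: {err}") from None
    return observations, skipped


# --------------------------------------------------------------------------
# Registry loading
# --------------------------------------------------------------------------


def load_gene_registry(path: str | Path) -> GeneRegistry:
    """Load a gene registry from a JSON or YAML document.

    Expected shape::

        genes:
          MYBPC3:
            tier: tier1
            associations: [{disease: HCM, validity: definitive}]
        max_credible_popmax_af:
          HCM: 4.0e-5
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "genes" not in doc:
        raise SchemaError(f"{path}: registry document must contain a 'genes' mapping")
    genes: dict[str, GeneEntry] = {}
    for gene, spec in doc["genes"].items():
        assocs = tuple(
            GeneAssociation(str(a["disease"]), str(a["validity"]))
            for a in spec.get("associations", [])
        )
        genes[str(gene)] = GeneEntry(tier=str(spec["tier"]), associations=assocs)
    thresholds = {
        str(k): float(v) for k, v in (doc.get("max_credible_popmax_af") or {}).items()
    }
    return GeneRegistry(genes=genes, max_credible_popmax_af=thresholds)


def registry_to_dict(registry: GeneRegistry) -> dict:
    return {
        "genes": {
            gene: {
                "tier": entry.tier,
                "associations": [
                    {"disease": a.disease, "validity": a.validity}
                    for a in entry.associations
                ],
            }
            for gene, entry in sorted(registry.genes.items())
        },
        "max_credible_popmax_af": dict(sorted(registry.max_credible_popmax_af.items())),
    }


def default_registry() -> GeneRegistry:
    """Illustrative default registry covering the diseases this pipeline
    recognises. Not an authoritative curation; override in production."""

    def e(tier: str, *assocs: tuple[str, str]) -> GeneEntry:
        return GeneEntry(tier, tuple(GeneAssociation(d, v) for d, v in assocs))

    genes = {
        "MYBPC3": e("tier1", ("HCM", "definitive")),
        "MYH7": e("tier1", ("HCM", "definitive"), ("LVNC", "definitive"), ("DCM", "moderate")),
        "TNNT2": e("tier1", ("HCM", "definitive"), ("DCM", "moderate")),
        "TNNI3": e("tier1", ("HCM", "definitive"), ("RCM", "definitive")),
        "TPM1": e("tier1", ("HCM", "definitive")),
        "MYL2": e("tier1", ("HCM", "definitive")),
        "MYL3": e("tier1", ("HCM", "definitive")),
        "ACTC1": e("tier1", ("HCM", "definitive")),
        "PRKAG2": e("tier1", ("HCM", "definitive")),
        "GLA": e("tier1", ("FabryDisease", "definitive")),
        "LAMP2": e("tier1", ("DanonDisease", "definitive")),
        "PTPN11": e("tier1", ("NoonanLVH", "definitive")),
        "TTN": e("tier1", ("DCM", "definitive")),
        "LMNA": e("tier1", ("DCM", "definitive")),
        "DES": e("tier1", ("MyofibrillarMyopathy", "definitive"), ("DCM", "definitive")),
        "DSP": e("tier1", ("ACM", "definitive"), ("DCM", "definitive")),
        "PKP2": e("tier1", ("ACM", "definitive")),
        "TMEM43": e("tier1", ("ACM", "definitive")),
        "SCN5A": e(
            "tier1",
            ("BrS", "definitive"),
            ("LQTS", "definitive"),
            ("DCM", "moderate"),
            ("SSS", "moderate"),
        ),
        "KCNQ1": e("tier1", ("LQTS", "definitive")),
        "KCNH2": e("tier1", ("LQTS", "definitive")),
        "RYR2": e("tier1", ("CPVT", "definitive")),
        "CASQ2": e("tier1", ("CPVT", "definitive")),
        "CACNA1C": e("tier1", ("LQTS", "definitive"), ("BrS", "limited")),
        "FLNC": e("tier2", ("DCM", "moderate"), ("HCM", "moderate")),
        "FHOD3": e("tier2", ("HCM", "moderate")),
        "ACTN2": e("tier2", ("HCM", "moderate"), ("DCM", "limited")),
        "FHL1": e("tier2", ("EmeryDreifussCardiomyopathy", "definitive")),
        "NDUFB11": e("tier2", ("HistiocytoidCardiomyopathy", "definitive")),
        "TBX5": e("tier2", ("HoltOramSyndrome", "definitive")),
        "ALPK3": e("tier2", ("HCM", "moderate")),
    }
    return GeneRegistry(genes=genes)
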