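from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiocohort import (
    Classification,
    EvidenceCriterion,
    SchemaError,
    Strength,
    VariantObservation,
    assess_suspicious_vus,
    classify_variant,
    combine_criteria,
    is_protein_altering,
    meets_rarity,
)
from cardiocohort.triage import VUS

from .oracles import OBSERVED_CODE_POOL, oracle_combine


def crits(*tokens):
    from cardiocohort.model import parse_criterion

    return frozenset(parse_criterion(t) for t in tokens)


class TestCombineCriteria:
    def test_no_evidence_is_vus(self):
        assert combine_criteria(frozenset()).value == "VUS"

    # expected values frozen from the pattern-enumeration oracle
    @pytest.mark.parametrize(
        "tokens,expected",
        [
            (("PVS1", "PM2"), "likely_pathogenic"),
            (("PVS1_moderate", "PM2", "PP3"), "VUS"),
            (("PM2", "PP3"), "VUS"),
            (("PVS1", "PS2", "PM2"), "pathogenic"),
            (("PS1", "PM2", "PP3"), "likely_pathogenic"),
            (("PM1", "PM2", "PP2", "PP3"), "likely_pathogenic"),
            (("PM2", "PP3", "PS4_supporting"), "VUS"),
            (("PM2", "PS4_moderate"), "VUS"),
            (("BA1",), "benign"),
            (("BS1", "BS2"), "benign"),
            (("BS1", "BP4"), "likely_benign"),
            (("BP4", "BP7"), "likely_benign"),
            (("PVS1", "PS1"), "pathogenic"),
            (("PS1", "PS2"), "pathogenic"),
            (("PVS1",), "VUS"),
        ],
    )
    def test_frozen_examples(self, tokens, expected):
        assert combine_criteria(crits(*tokens)).value == expected
        assert oracle_combine(crits(*tokens)) == expected

    def test_conflicting_evidence_is_vus_not_error(self):
        assert combine_criteria(crits("PVS1", "PS1", "BA1")).value == "VUS"

    def test_duplicate_base_code_rejected(self):
        dup = frozenset(
            {
                EvidenceCriterion("PS4", Strength.strong),
                EvidenceCriterion("PS4", Strength.moderate),
            }
        )
        with pytest.raises(SchemaError, match="PS4"):
            combine_criteria(dup)

    def test_exhaustive_oracle_equivalence_up_to_size_5(self):
        """All distinct-code multisets of size <= 5 from the observed pool."""
        n_checked = 0
        for size in range(6):
            for combo in combinations(OBSERVED_CODE_POOL, size):
                cs = frozenset(combo)
                assert combine_criteria(cs).value == oracle_combine(cs), sorted(
                    c.render() for c in cs
                )
                n_checked += 1
        assert n_checked == sum(
            1
            for size in range(6)
            for _ in combinations(OBSERVED_CODE_POOL, size)
        )


_pathogenic_codes = sorted({c.base_code for c in OBSERVED_CODE_POOL if c.is_pathogenic_direction})
_strengths = [Strength.supporting, Strength.moderate, Strength.strong, Strength.very_strong]


@st.composite
def criteria_sets(draw, max_size=5):
    codes = draw(
        st.lists(st.sampled_from(_pathogenic_codes), unique=True, max_size=max_size)
    )
    return frozenset(
        EvidenceCriterion(code, draw(st.sampled_from(_strengths))) for code in codes
    )


class TestMonotonicity:
    @settings(max_examples=300, deadline=None)
    @given(criteria_sets(), st.sampled_from(_strengths))
    def test_adding_pathogenic_criterion_never_lowers(self, cs, strength):
        new_code = next(
            (c for c in ("PP2", "PM4", "PS2", "PM5") if c not in {x.base_code for x in cs}),
        )
        before = combine_criteria(cs)
        after = combine_criteria(cs | {EvidenceCriterion(new_code, strength)})
        assert after.rank >= before.rank

    @settings(max_examples=300, deadline=None)
    @given(criteria_sets())
    def test_raising_strength_never_lowers(self, cs):
        for target in sorted(cs):
            if target.strength == Strength.very_strong:
                continue
            raised = EvidenceCriterion(
                target.base_code, Strength(target.strength + 1)
            )
            before = combine_criteria(cs)
            after = combine_criteria((cs - {target}) | {raised})
            assert after.rank >= before.rank


class TestRarity:
    def test_absent_is_rare(self, registry):
        assert meets_rarity(0.0, "HCM", registry)

    def test_above_threshold_fails(self, registry):
        assert not meets_rarity(1e-4, "HCM", registry)

    def test_boundary_is_strict(self, registry):
        assert not meets_rarity(4e-5, "HCM", registry)

    def test_unknown_disease_is_error(self, registry):
        with pytest.raises(SchemaError, match="NotADisease"):
            meets_rarity(0.0, "NotADisease", registry)


class TestProteinAltering:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("missense", True),
            ("nonsense", True),
            ("frameshift", True),
            ("canonical_splice", True),
            ("inframe_indel", True),
            ("structural", True),
            ("synonymous", False),
            ("synonymous_splice_predicted", True),
            ("deep_intronic_splice_predicted", True),
        ],
    )
    def test_rule(self, consequence, expected):
        assert is_protein_altering(consequence) is expected


def _obs(gene="MYBPC3", consequence="missense", af=0.0, criteria=("PM2", "PP3"), **kw):
    from cardiocohort.model import parse_criteria_field

    return VariantObservation(
        proband_id="P1",
        gene=gene,
        variant_label="c.100G>A",
        consequence=consequence,
        popmax_af=af,
        criteria=parse_criteria_field(";".join(criteria)),
        **kw,
    )


class TestSuspiciousVus:
    def test_canonical_suspicious_case(self, registry):
        verdict, reasons = assess_suspicious_vus(VUS, _obs(), "HCM", registry)
        assert verdict
        assert any("suspicious" in r for r in reasons)

    def test_lp_not_eligible(self, registry):
        verdict, _ = assess_suspicious_vus(
            Classification("likely_pathogenic"), _obs(), "HCM", registry
        )
        assert not verdict

    def test_non_definitive_gene_fails(self, registry):
        # FLNC carries only moderate validity for HCM
        verdict, reasons = assess_suspicious_vus(VUS, _obs(gene="FLNC"), "HCM", registry)
        assert not verdict
        assert any("definitive" in r for r in reasons)

    def test_common_variant_fails(self, registry):
        verdict, _ = assess_suspicious_vus(VUS, _obs(af=1e-3), "HCM", registry)
        assert not verdict

    def test_synonymous_fails_but_predicted_splice_passes(self, registry):
        v1, _ = assess_suspicious_vus(VUS, _obs(consequence="synonymous"), "HCM", registry)
        v2, _ = assess_suspicious_vus(
            VUS, _obs(consequence="synonymous_splice_predicted"), "HCM", registry
        )
        assert not v1
        assert v2

    def test_possible_diagnosis_matches_base(self, registry):
        verdict, _ = assess_suspicious_vus(VUS, _obs(), "possible_HCM", registry)
        assert verdict

    def test_undiagnosed_has_no_base_phenotype(self, registry):
        verdict, _ = assess_suspicious_vus(VUS, _obs(), "undiagnosed", registry)
        assert not verdict

    def test_no_pathogenic_evidence_fails(self, registry):
        verdict, _ = assess_suspicious_vus(VUS, _obs(criteria=()), "HCM", registry)
        assert not verdict

    def test_strong_benign_blocks(self, registry):
        verdict, _ = assess_suspicious_vus(
            VUS, _obs(criteria=("PM2", "PP3", "BS2")), "HCM", registry
        )
        assert not verdict

    def test_pm2_only_counts_unless_configured(self, registry):
        obs = _obs(criteria=("PM2",))
        v_default, _ = assess_suspicious_vus(VUS, obs, "HCM", registry)
        v_strict, _ = assess_suspicious_vus(
            VUS, obs, "HCM", registry, require_non_frequency_criterion=True
        )
        assert v_default
        assert not v_strict

    def test_unknown_gene_error_names_gene(self, registry):
        with pytest.raises(SchemaError, match="NOTAGENE"):
            assess_suspicious_vus(VUS, _obs(gene="NOTAGENE"), "HCM", registry)


class TestClassifyVariant:
    def test_asserted_classification_wins(self, registry):
        cv = classify_variant(
            _obs(asserted_classification="pathogenic"), "HCM", registry
        )
        assert cv.classification.value == "pathogenic"
        assert not cv.suspicious_vus
        assert any("asserted" in r for r in cv.triage_reasons)

    def test_suspicious_pipeline_case(self, registry):
        cv = classify_variant(_obs(gene="MYH7"), "HCM", registry)
        assert cv.classification.value == "VUS"
        assert cv.suspicious_vus

    def test_lp_combination_not_suspicious(self, registry):
        cv = classify_variant(_obs(criteria=("PVS1", "PM2")), "HCM", registry)
        assert cv.classification.value == "likely_pathogenic"
        assert not cv.suspicious_vus

    def test_suspicious_invariant_enforced(self):
        from cardiocohort.triage import ClassifiedVariant

        with pytest.raises(SchemaError):
            ClassifiedVariant(_obs(), Classification("likely_pathogenic"), True)

    def test_classification_total_order(self):
        order = ["benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic"]
        classes = [Classification(v) for v in order]
        assert sorted(classes, key=lambda c: c.rank) == classes
        assert classes[0] < classes[-1]
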