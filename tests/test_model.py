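import textwrap

import pytest

from cardiocohort import (
    EvidenceCriterion,
    Proband,
    SchemaError,
    SevereFeatures,
    Strength,
    VariantObservation,
    build_paper_fixture,
    read_proband_table,
    read_variant_table,
    write_proband_table,
    write_variant_table,
)
from cardiocohort.model import (
    GeneRegistry,
    load_gene_registry,
    parse_criteria_field,
    parse_criterion,
    registry_to_dict,
)

PROBAND_HEADER = (
    "proband_id\tclinical_diagnosis\tdiagnosis_certainty\tage_at_diagnosis\t"
    "n_affected_relatives\tscd_or_resuscitated_arrest\tsustained_vt\t"
    "appropriate_icd_shock\tcardiac_transplant\tlvad\tejection_fraction_pct\t"
    "max_lvh_mm\tqtc_ms\tancestry\tyear_first_seen\tyear_genetic_diagnosis\t"
    "testing_provenance\texcluded_reason"
)


def _proband_row(pid="P1", dx="HCM", certainty="definite", age="45"):
    return (
        f"{pid}\t{dx}\t{certainty}\t{age}\t0\t0\t0\t0\t0\t0\t55\t.\t.\t"
        "European\t2010\t.\tclinical\t."
    )


class TestProbandTable:
    def test_three_row_identity_parse(self, tmp_path):
        path = tmp_path / "p.tsv"
        rows = [_proband_row(f"P{i}") for i in range(3)]
        path.write_text(PROBAND_HEADER + "\n" + "\n".join(rows) + "\n")
        probands = read_proband_table(path)
        assert len(probands) == 3
        assert probands[0].proband_id == "P0"
        assert probands[0].age_at_diagnosis == 45.0
        assert probands[2].severe_flags.ejection_fraction_pct == 55.0

    def test_negative_age_is_row_level_error(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(PROBAND_HEADER + "\n" + _proband_row(age="-4") + "\n")
        with pytest.raises(SchemaError, match="row 1"):
            read_proband_table(path)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("proband_id\tclinical_diagnosis\nP1\tHCM\n")
        with pytest.raises(SchemaError, match="diagnosis_certainty"):
            read_proband_table(path)

    def test_unknown_enum_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            PROBAND_HEADER + "\n" + _proband_row(dx="HOCUS", certainty="definite") + "\n"
        )
        with pytest.raises(SchemaError, match="HOCUS"):
            read_proband_table(path)

    def test_certainty_must_match_diagnosis(self):
        with pytest.raises(SchemaError, match="inconsistent"):
            Proband(
                proband_id="X",
                clinical_diagnosis="undiagnosed",
                diagnosis_certainty="definite",
                age_at_diagnosis=40,
                n_affected_relatives=0,
                severe_flags=SevereFeatures(),
                ancestry="European",
                year_first_seen=2010,
            )

    def test_year_ordering_invariant(self):
        with pytest.raises(SchemaError, match="precedes"):
            Proband(
                proband_id="X",
                clinical_diagnosis="HCM",
                diagnosis_certainty="definite",
                age_at_diagnosis=40,
                n_affected_relatives=0,
                severe_flags=SevereFeatures(),
                ancestry="European",
                year_first_seen=2015,
                year_genetic_diagnosis=2010,
            )

    def test_fixture_cohort_has_888_probands(self, tmp_path, fixture_cohort):
        probands, _ = fixture_cohort
        path = tmp_path / "cohort.tsv"
        write_proband_table(probands, path)
        assert len(read_proband_table(path)) == 888

    def test_round_trip_identity(self, tmp_path, fixture_cohort):
        probands, _ = fixture_cohort
        path = tmp_path / "p.tsv"
        write_proband_table(probands, path)
        assert read_proband_table(path) == probands


class TestCriteria:
    def test_canonical_strengths(self):
        crits = parse_criteria_field("PM2;PP3")
        assert crits == {
            EvidenceCriterion("PM2", Strength.moderate),
            EvidenceCriterion("PP3", Strength.supporting),
        }

    def test_modified_strength(self):
        (c,) = parse_criteria_field("PS4_moderate")
        assert c.base_code == "PS4"
        assert c.strength == Strength.moderate

    def test_unknown_code_rejected(self):
        with pytest.raises(SchemaError, match="PX9"):
            parse_criteria_field("PX9")

    def test_duplicate_base_at_two_strengths_rejected(self):
        with pytest.raises(SchemaError, match="PS4"):
            parse_criteria_field("PS4;PS4_moderate")

    @pytest.mark.parametrize(
        "token",
        ["PM2", "PS4_moderate", "PVS1_moderate", "PM1_supporting", "BA1", "PS3_supporting"],
    )
    def test_parse_render_round_trip(self, token):
        assert parse_criterion(token).render() == token

    def test_default_strengths_by_prefix(self):
        assert parse_criterion("PVS1").strength == Strength.very_strong
        assert parse_criterion("PS2").strength == Strength.strong
        assert parse_criterion("PM4").strength == Strength.moderate
        assert parse_criterion("PP5").strength == Strength.supporting
        assert parse_criterion("BA1").strength == Strength.stand_alone


class TestVariantTable:
    def test_round_trip(self, tmp_path, fixture_cohort):
        _, variants = fixture_cohort
        path = tmp_path / "v.tsv"
        write_variant_table(variants, path)
        assert read_variant_table(path) == variants

    def test_error_names_code_and_row(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "proband_id\tgene\tvariant_label\tconsequence\tpopmax_af\tcriteria\t"
            "asserted_classification\nP1\tMYH7\tc.1A>G\tmissense\t0\tPX9\t.\n"
        )
        with pytest.raises(SchemaError, match="row 1.*PX9"):
            read_variant_table(path)

    def test_popmax_af_bounds(self):
        with pytest.raises(SchemaError, match="popmax_af"):
            VariantObservation("P1", "MYH7", "c.1A>G", "missense", popmax_af=1.5)


class TestRegistry:
    def test_load_yaml_and_defaults(self, tmp_path):
        doc = textwrap.dedent(
            """
            genes:
              MYBPC3:
                tier: tier1
                associations:
                  - {disease: HCM, validity: definitive}
            """
        )
        path = tmp_path / "reg.yaml"
        path.write_text(doc)
        reg = load_gene_registry(path)
        assert reg.validity("MYBPC3", "HCM") == "definitive"
        # default HCM threshold 4e-5 unless overridden
        assert reg.threshold("HCM") == pytest.approx(4e-5)

    def test_threshold_override_accepted(self, tmp_path):
        path = tmp_path / "reg.yaml"
        path.write_text(
            "genes:\n  MYBPC3:\n    tier: tier1\n    associations:\n"
            "      - {disease: HCM, validity: definitive}\n"
            "max_credible_popmax_af:\n  HCM: 0.00004\n"
        )
        assert load_gene_registry(path).threshold("HCM") == pytest.approx(4e-5)

    def test_tier1_without_definitive_is_invalid(self, tmp_path):
        path = tmp_path / "reg.yaml"
        path.write_text(
            "genes:\n  FHOD3:\n    tier: tier1\n    associations: []\n"
        )
        with pytest.raises(SchemaError, match="FHOD3"):
            load_gene_registry(path)

    def test_json_round_trip(self, tmp_path, registry):
        import json

        path = tmp_path / "reg.json"
        path.write_text(json.dumps(registry_to_dict(registry)))
        reloaded = load_gene_registry(path)
        assert registry_to_dict(reloaded) == registry_to_dict(registry)

    def test_other_diseases_default_more_stringent(self, registry):
        assert registry.threshold("DCM") == pytest.approx(1e-5)
        assert registry.threshold("LQTS") == pytest.approx(1e-5)


VCF_TEMPLATE = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=POPMAX_AF,Number=1,Type=Float,Description="Popmax AF">
##INFO=<ID=ACMG,Number=1,Type=String,Description="Applied criteria">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=249250621>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1
{records}
"""


class TestVcfIngest:
    def test_two_record_toy_vcf(self, tmp_path):
        from cardiocohort import ingest_vcf

        records = (
            "1\t100\t.\tA\tG\t.\t.\tGENE=MYH7;CSQ_CLASS=missense;"
            "POPMAX_AF=1e-05;ACMG=PM2;PP3\tGT\t0/1\n"
            "1\t200\t.\tC\tT\t.\t.\tGENE=MYBPC3;CSQ_CLASS=nonsense;"
            "POPMAX_AF=0.0;ACMG=PVS1;PM2\tGT\t1/1"
        )
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEMPLATE.format(records=records))
        obs, skipped = ingest_vcf(path)
        assert skipped == 0
        assert len(obs) == 2
        assert obs[0].proband_id == "P1"
        assert obs[0].gene == "MYH7"
        assert obs[0].popmax_af == pytest.approx(1e-5)
        assert EvidenceCriterion("PVS1", Strength.very_strong) in obs[1].criteria

    def test_missing_af_flagged_assumed_absent(self, tmp_path):
        from cardiocohort import ingest_vcf

        records = (
            "1\t100\t.\tA\tG\t.\t.\tGENE=MYH7;CSQ_CLASS=missense;ACMG=PM2\tGT\t0/1"
        )
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEMPLATE.format(records=records))
        obs, _ = ingest_vcf(path)
        assert obs[0].popmax_af == 0.0
        assert obs[0].af_assumed_absent

    def test_record_missing_gene_key_skipped_and_counted(self, tmp_path):
        from cardiocohort import ingest_vcf

        records = (
            "1\t100\t.\tA\tG\t.\t.\tCSQ_CLASS=missense;ACMG=PM2\tGT\t0/1\n"
            "1\t200\t.\tC\tT\t.\t.\tGENE=MYH7;CSQ_CLASS=missense;ACMG=PM2\tGT\t0/1"
        )
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEMPLATE.format(records=records))
        obs, skipped = ingest_vcf(path)
        assert len(obs) == 1
        assert skipped == 1

    def test_truncated_file_is_parse_error(self, tmp_path):
        from cardiocohort import ingest_vcf

        path = tmp_path / "broken.vcf"
        path.write_text("##fileformat=VCFv4.2\n#CHROM\tPOS")
        with pytest.raises(SchemaError, match="malformed VCF"):
            ingest_vcf(path)
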