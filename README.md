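# cardiocohort

Cohort adjudication pipeline for genetic testing in inherited cardiac
conditions (cardiomyopathies, arrhythmia syndromes, unexplained cardiac
arrest). Given a per-proband phenotype table and a per-variant observation
table, the pipeline:

1. **Triage** — combines applied ACMG/AMP evidence codes (including
   strength-shifted forms such as `PS4_moderate` or `PVS1_moderate`) into a
   five-tier classification, and flags *suspicious VUS*: rare below the
   disease-specific maximum credible popmax allele frequency, in a gene
   with a definitive association to the baseline phenotype,
   protein-altering, with some but insufficient pathogenic evidence.
2. **Monogenic disease score** — additive points: positive family history
   (2), severe phenotype (1), onset < 30 years (1) or < 10 years (2);
   buckets 0/1/2/3/≥4.
3. **Adjudication** — solved at baseline vs solved on review (research
   provenance), suspicious VUS, and unsolved likely-monogenic (score ≥ 1)
   vs likely-complex (score 0); diagnosis changed/clarified tracking;
   time-to-diagnosis by presentation era.
4. **Report** — yield tables stratified by score × diagnostic certainty,
   feature combination, and ancestry, with 2×2 chi-squared and Student's
   t-test (raw or summary-statistic) comparisons.

A seeded synthetic-cohort generator (`simulate`) and a deterministic
888-proband benchmark cohort (`fixture`, reconstructed from published
stratum margins) make the whole pipeline testable without clinical data.

## CLI

```sh
# synthetic cohort
cardiocohort simulate --seed 1 --n 2000 --out-dir scratch/sim

# deterministic benchmark cohort + default gene registry
cardiocohort fixture --out-dir scratch/fixture

# full pipeline: triage -> score -> adjudicate -> report
cardiocohort run \
    --probands scratch/fixture/probands.tsv \
    --variants scratch/fixture/variants.tsv \
    --registry scratch/fixture/registry.json \
    --out scratch/report
```

The report directory contains `yield_by_score.tsv`, `yield_by_feature.tsv`,
`yield_by_ancestry.tsv`, `flow_counts.json`, `tests.json`,
`adjudication.tsv` and a run manifest. `triage` and `score` run single
stages; `--age-cutoff`, `--fh-min-relatives`, `--rounding` and a YAML
`--config` expose the documented threshold knobs.

## File formats

- Proband and variant tables: UTF-8 TSV with header, `.` for missing;
  criteria are semicolon-separated codes (`PM2;PP3;PS4_moderate`).
- Gene registry: JSON or YAML mapping genes to tier (1/2) and
  disease-validity associations, plus per-disease maximum credible popmax
  AF (default 4e-5 for HCM, 1e-5 otherwise). The packaged default registry
  is illustrative, not an authoritative curation.
- Annotated VCF 4.x ingestion via configurable INFO keys
  (`cardiocohort.ingest_vcf`).

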