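# burdenscan

Rare-variant candidate-gene case/control association analysis as a reusable
pipeline:

* **Composite phenotype** — a subject is a case when they self-report the
  condition, carry an ICD-10 code under a configured prefix (default `G43`,
  dot-insensitive), or take a configured condition-specific medication.
* **Weighted burden test** — each qualifying rare variant (minor allele
  frequency ≤ 0.01 in both cases and controls) gets an overall weight =
  functional weight × MAF weight (linear from 10 at MAF 0 down to 1 at MAF
  0.01; defaults anchor stop-gained at 100 and missense at 5). Per-subject
  weighted burden scores are tested by logistic regression with sex and 20
  principal components as covariates; the likelihood-ratio p-value is reported
  as a signed log10 p-value (SLP), positive when the burden is higher in cases.
* **Variant-category tests** — per gene, a joint logistic regression on the
  counts of each variant category (LOF, protein-altering, splice-site,
  synonymous, intronic) with the same covariates; Wald p-values, falling back
  to Fisher's exact test for categories with fewer than 50 occurrences.
* **Carrier contingency tests** — single-variant Pearson chi-squared tests
  (1 df, no continuity correction) for literature-reported variants carried by
  ≥ 20 subjects, per-gene pooling (carrier-deduplicated) of rarer ones, and a
  per-gene frameshift carrier aggregation.
* **Synthetic cohorts** — a fully parameterized simulator (sample size,
  prevalence, female case excess, per-gene variant catalogs, burden/category
  liability effects, PC confounding, missingness) that emits VCF + annotation
  TSV + cohort TSV consumable by the pipeline unchanged, so every stage is
  testable without external data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes Monte Carlo calibration tests (type-I error of the burden
SLP over 500 null cohorts at n = 20,000; effect recovery over 200 replicates
at n = 50,000) and takes a few minutes on one CPU.

## CLI

```sh
# generate a synthetic study
burdenscan simulate --config sim.yaml --out demo/

# derive case/control status and print the phenotype summary
burdenscan classify --cohort demo/cohort.tsv

# burden + category tests
burdenscan gene-test --vcf demo/genotypes.vcf --anno demo/annotations.tsv \
    --cohort demo/cohort.tsv --out results/

# literature-variant and frameshift carrier tests
burdenscan variant-test --vcf demo/genotypes.vcf --anno demo/annotations.tsv \
    --cohort demo/cohort.tsv --variants literature_variants.tsv \
    --frameshift-genes KCNK18 --out results/

# everything in one run (writes gene/category/variant TSVs + manifest.json)
burdenscan all --vcf ... --anno ... --cohort ... --out results/
```

A minimal `sim.yaml`:

```yaml
n_subjects: 20000
seed: 1
target_prevalence: 0.036
genes:
  - name: GENEA
    n_variants: 20
burden_beta: 0.0
```

Weight tables, the medication list, gene panels and the literature-variant
list are plain YAML/JSON/TSV files; see the docstrings in
`burdenscan.cohort_io` for the expected columns.

## Input formats

* **Genotypes**: VCF v4.x, biallelic records only (multiallelic sites are
  rejected and counted). Missing genotypes are kept distinct from reference
  calls; they contribute 0 to burden scores and count as non-carriers.
* **Annotations**: TSV with `chrom pos ref alt gene transcript consequence`
  (+ optional `aa_change`), joined by exact key; `chr` prefixes are stripped.
* **Cohort**: TSV with `subject_id sex PC1..PC20 self_report_migraine
  icd10_codes medication_codes` (+ optional `age`); code lists are
  `;`-delimited.
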