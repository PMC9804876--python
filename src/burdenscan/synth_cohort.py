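"""Synthetic case/control cohort generator.

Produces genotypes, annotations, covariates and phenotype indicators with the
statistical structure the analysis assumes: rare variants (MAF <= 0.01) of
mixed consequence types per gene, Hardy-Weinberg dosages with no LD, a
heavily imbalanced case/control split with a female case excess, and a
configurable burden -> liability effect. The logistic intercept is solved
numerically so the expected prevalence matches the target.

All randomness flows through a single ``numpy`` Generator keyed by the
mandatory seed; draws happen in a fixed documented order (covariates, then
per-gene variant catalogs, then genotypes, then status, then indicators,
then missingness), so outputs are byte-identical across runs with the same
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from burdenscan.model import CohortTable, MISSING, VariantRecord, WeightConfig
from burdenscan.phenotype import DEFAULT_MEDICATION_CODES
from burdenscan.weighting import maf_weight

# decoy codes that must NOT classify a subject as a case
DECOY_ICD = ("G44.2", "R51", "I10")
DECOY_MEDS = ("PARACETAMOL", "IBUPROFEN", "ASPIRIN")


@dataclass
class GeneSpec:
    """Variant catalog parameters for one simulated gene."""

    name: str
    n_variants: int = 20
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense_variant": 0.5,
            "synonymous_variant": 0.2,
            "intron_variant": 0.15,
            "stop_gained": 0.05,
            "frameshift_variant": 0.05,
            "splice_region_variant": 0.05,
        }
    )
    # MAF ~ maf_cap * Beta(a, b), floored at maf_floor
    maf_beta_a: float = 0.5
    maf_beta_b: float = 4.0
    maf_floor: float = 1e-5


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort."""

    n_subjects: int
    seed: int
    target_prevalence: float = 0.036
    female_fraction: float = 0.5
    female_case_odds_multiplier: float = 3.0
    genes: list[GeneSpec] = field(default_factory=lambda: [GeneSpec("GENE1")])
    burden_beta: float = 0.0
    category_betas: dict[str, float] = field(default_factory=dict)
    pc_effect: float = 0.0
    missing_rate: float = 0.0
    # P(indicator | case) for self-report / ICD-10 / medication; a case with
    # no indicator drawn is forced to self-report so classification is exact
    indicator_probs: tuple[float, float, float] = (0.7, 0.3, 0.3)
    decoy_rate: float = 0.05
    maf_cap: float = 0.01

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        for p in (self.female_fraction, self.missing_rate, self.decoy_rate, *self.indicator_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        self.genes = [g if isinstance(g, GeneSpec) else GeneSpec(**g) for g in self.genes]

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + eta)) equal to the target prevalence."""

    def gap(c: float) -> float:
        return float(expit(c + eta).mean() - target)

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"target prevalence {target} unattainable given effects")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def simulate_cohort(
    config: SimConfig, weight_config: Optional[WeightConfig] = None
) -> tuple[list[VariantRecord], CohortTable, pd.DataFrame, pd.DataFrame]:
    """Simulate genotypes, covariates and phenotype for a full synthetic cohort.

    Returns ``(records, cohort, annotations, truth)`` where ``annotations`` is
    the variant annotation table consumable by ``cohort_io`` and ``truth``
    records the generating MAFs/weights per variant plus the liability
    parameters actually used.
    """
    wcfg = weight_config or WeightConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # 1. covariates
    sex = (rng.random(n) < config.female_fraction).astype(np.int8)  # 1 = female
    pcs = rng.standard_normal((n, 20))
    age = np.round(rng.normal(56.0, 8.0, n), 1)

    # 2. variant catalogs + genotypes
    records: list[VariantRecord] = []
    truth_rows = []
    score = np.zeros(n)
    cat_counts: dict[str, np.ndarray] = {c: np.zeros(n) for c in wcfg.categories}
    for g_idx, gene in enumerate(config.genes):
        cons_terms = list(gene.consequence_mix)
        cons_probs = np.array([gene.consequence_mix[c] for c in cons_terms], dtype=float)
        cons_probs /= cons_probs.sum()
        chrom = str(g_idx + 1)
        for v_idx in range(gene.n_variants):
            maf = float(
                np.clip(
                    config.maf_cap * rng.beta(gene.maf_beta_a, gene.maf_beta_b),
                    gene.maf_floor,
                    config.maf_cap,
                )
            )
            consequence = cons_terms[rng.choice(len(cons_terms), p=cons_probs)]
            dosage = rng.binomial(2, maf, n).astype(np.int8)
            rec = VariantRecord(
                chrom=chrom,
                pos=10_000 + 100 * v_idx,
                ref="A",
                alt="G",
                genotypes=dosage,
                gene=gene.name,
                transcript=f"ENST_{gene.name}",
                consequence=consequence,
                aa_change=f"p.(Sim{v_idx})" if consequence == "missense_variant" else None,
            )
            records.append(rec)
            fw = wcfg.functional_weight[consequence]
            mw = maf_weight(maf, wcfg)
            score += dosage * fw * mw
            cat_counts[wcfg.category_of[consequence]] += dosage
            truth_rows.append(
                {
                    "chrom": chrom, "pos": rec.pos, "ref": "A", "alt": "G",
                    "gene": gene.name, "consequence": consequence,
                    "true_maf": maf, "functional_weight": fw,
                    "maf_weight": mw, "overall_weight": fw * mw,
                }
            )

    # 3. liability and case status
    eta = (
        config.burden_beta * score
        + np.log(config.female_case_odds_multiplier) * sex
        + config.pc_effect * pcs[:, 0]
    )
    for cat, beta in config.category_betas.items():
        eta += beta * cat_counts[cat]
    intercept = solve_intercept(eta, config.target_prevalence)
    is_case = rng.random(n) < expit(intercept + eta)

    # 4. phenotype indicators — cases get >=1 true indicator, controls none;
    # decoy codes exercise the classifier without flipping anyone
    p_sr, p_icd, p_med = config.indicator_probs
    ind = np.zeros((n, 3), dtype=bool)
    draws = rng.random((n, 3))
    ind[:, 0] = draws[:, 0] < p_sr
    ind[:, 1] = draws[:, 1] < p_icd
    ind[:, 2] = draws[:, 2] < p_med
    ind[~is_case] = False
    none_drawn = is_case & ~ind.any(axis=1)
    ind[none_drawn, 0] = True

    med_list = sorted(DEFAULT_MEDICATION_CODES)
    icd_subcodes = ["G43.0", "G43.1", "G43.9", "G431"]
    icd_pick = rng.choice(len(icd_subcodes), n)
    med_pick = rng.choice(len(med_list), n)
    decoy_draws = rng.random((n, 2))
    decoy_icd_pick = rng.choice(len(DECOY_ICD), n)
    decoy_med_pick = rng.choice(len(DECOY_MEDS), n)

    icd_codes: list[list[str]] = []
    med_codes: list[list[str]] = []
    for i in range(n):
        icds = [icd_subcodes[icd_pick[i]]] if ind[i, 1] else []
        meds = [med_list[med_pick[i]]] if ind[i, 2] else []
        if decoy_draws[i, 0] < config.decoy_rate:
            icds.append(DECOY_ICD[decoy_icd_pick[i]])
        if decoy_draws[i, 1] < config.decoy_rate:
            meds.append(DECOY_MEDS[decoy_med_pick[i]])
        icd_codes.append(icds)
        med_codes.append(meds)

    # 5. genotype missingness
    if config.missing_rate > 0:
        for rec in records:
            mask = rng.random(n) < config.missing_rate
            rec.genotypes[mask] = MISSING

    cohort = CohortTable(
        subject_id=np.array([f"S{i:07d}" for i in range(n)], dtype=object),
        sex=sex,
        pcs=pcs,
        self_report_migraine=ind[:, 0],
        icd10_codes=icd_codes,
        medication_codes=med_codes,
        is_case=is_case,
        age=age,
    )

    annotations = pd.DataFrame(
        [
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "gene": r.gene, "transcript": r.transcript,
                "consequence": r.consequence, "aa_change": r.aa_change,
            }
            for r in records
        ]
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["intercept"] = intercept
    truth.attrs["burden_beta"] = config.burden_beta
    truth.attrs["true_score"] = score
    return records, cohort, annotations, truth


def write_vcf(records: Sequence[VariantRecord], cohort: CohortTable, path: str | Path) -> None:
    """Write records as an uncompressed VCF v4.2 with per-subject GT columns."""
    gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, cohort.subject_id))
            + "\n"
        )
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            gts = "\t".join(gt_str[int(g)] for g in r.genotypes)
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_cohort_tsv(cohort: CohortTable, path: str | Path) -> None:
    cols: dict[str, object] = {
        "subject_id": cohort.subject_id,
        "sex": np.where(cohort.sex == 1, "F", "M"),
    }
    if cohort.age is not None:
        cols["age"] = cohort.age
    for j in range(20):
        cols[f"PC{j + 1}"] = cohort.pcs[:, j]
    cols["self_report_migraine"] = cohort.self_report_migraine.astype(int)
    cols["icd10_codes"] = [";".join(c) for c in cohort.icd10_codes]
    cols["medication_codes"] = [";".join(c) for c in cohort.medication_codes]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def render_fixture(
    records: Sequence[VariantRecord],
    cohort: CohortTable,
    out_dir: str | Path,
    annotations: Optional[pd.DataFrame] = None,
    truth: Optional[pd.DataFrame] = None,
) -> dict[str, Path]:
    """Write VCF + annotation TSV + cohort TSV (+ truth TSV) consumable unchanged."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "annotations": out / "annotations.tsv",
        "cohort": out / "cohort.tsv",
    }
    write_vcf(records, cohort, paths["vcf"])
    if annotations is None:
        annotations = pd.DataFrame(
            [
                {
                    "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                    "gene": r.gene, "transcript": r.transcript,
                    "consequence": r.consequence, "aa_change": r.aa_change,
                }
                for r in records
            ]
        )
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    write_cohort_tsv(cohort, paths["cohort"])
    if truth is not None:
        paths["truth"] = out / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
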