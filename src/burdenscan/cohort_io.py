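"""Input/output: VCF genotypes, annotation/cohort TSVs, config files, result tables.

Conventions
-----------
* VCF is 1-based; the internal variant key is ``(chrom, pos, ref, alt)`` with
  chromosome names normalized by stripping any ``chr`` prefix.
* Dosage is counted against ALT regardless of sample-wide frequency; folding
  to the minor allele happens in the weighting module.
* Multiallelic VCF records are rejected (and counted), not split.
* Annotation joining is by exact key; unannotated variants and variants whose
  consequence is not in the weight table are excluded and counted.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from burdenscan.model import (
    CategoryResult,
    CohortTable,
    GeneResult,
    MISSING,
    VariantRecord,
    VariantResult,
    WeightConfig,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "transcript", "consequence"]
PC_COLUMNS = [f"PC{i}" for i in range(1, 21)]
CODE_DELIMITER = ";"

_SEX_CODES = {"f": 1, "female": 1, "1": 1, "m": 0, "male": 0, "0": 0}


def read_genotypes(
    vcf_path: str | Path,
    subject_order: Sequence[str],
    report: Optional[dict] = None,
) -> list[VariantRecord]:
    """Read biallelic variant dosages from a VCF, aligned to ``subject_order``.

    Parameters
    ----------
    vcf_path
        Path to a VCF (v4.x) with GT fields for every subject.
    subject_order
        Required subject ordering; must match the VCF sample set exactly.
    report
        Optional dict filled with ``n_total``, ``n_accepted`` and
        ``n_multiallelic_rejected`` counts.

    Returns
    -------
    list of VariantRecord
        One record per biallelic site, genotypes as ALT dosage with missing
        calls encoded as -1.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    wanted = list(subject_order)
    missing = [s for s in wanted if s not in set(samples)]
    extra = [s for s in samples if s not in set(wanted)]
    if missing or extra:
        raise ValueError(
            f"VCF sample mismatch: missing from VCF {missing!r}; "
            f"unknown in VCF header {extra!r}"
        )
    order = np.array([samples.index(s) for s in wanted])

    records: list[VariantRecord] = []
    n_total = n_multi = 0
    for v in vcf:
        n_total += 1
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = v.genotype.array()  # (n_samples, ploidy+1); last col is phasing
        alleles = gts[:, :-1]
        dosage = (alleles == 1).sum(axis=1).astype(np.int8)
        dosage[(alleles < 0).any(axis=1)] = MISSING
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                genotypes=dosage[order],
            )
        )
    vcf.close()
    if n_multi:
        logger.warning("rejected %d multiallelic record(s)", n_multi)
    if report is not None:
        report.update(
            n_total=n_total, n_accepted=len(records), n_multiallelic_rejected=n_multi
        )
    return records


def read_annotations(tsv_path: str | Path) -> pd.DataFrame:
    """Read the variant annotation table (TSV keyed by chrom/pos/ref/alt)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")
    if "aa_change" not in df.columns:
        df["aa_change"] = None
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    return df


def annotate_records(
    records: Iterable[VariantRecord],
    annotations: pd.DataFrame,
    weight_config: WeightConfig,
    report: Optional[dict] = None,
) -> list[VariantRecord]:
    """Join annotations onto variant records by exact key.

    Unannotated variants and variants whose consequence term is not in the
    weight table are excluded; counts go to ``report`` and the log.
    """
    by_key = {
        (r.chrom, int(r.pos), r.ref, r.alt): r
        for r in (
            annotations.itertuples(index=False)
        )
    }
    annotated: list[VariantRecord] = []
    n_unannotated = n_bad_consequence = 0
    for rec in records:
        row = by_key.get(rec.key)
        if row is None:
            n_unannotated += 1
            continue
        if row.consequence not in weight_config.functional_weight:
            n_bad_consequence += 1
            logger.warning(
                "variant %s: unknown consequence %r rejected", rec.key, row.consequence
            )
            continue
        rec.gene = row.gene
        rec.transcript = row.transcript
        rec.consequence = row.consequence
        aa = getattr(row, "aa_change", None)
        rec.aa_change = None if aa is None or (isinstance(aa, float) and np.isnan(aa)) else aa
        annotated.append(rec)
    if n_unannotated:
        logger.warning("excluded %d unannotated variant(s)", n_unannotated)
    if report is not None:
        report.update(
            n_unannotated=n_unannotated, n_unknown_consequence=n_bad_consequence
        )
    return annotated


def _parse_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return []
    return [c for c in str(cell).split(CODE_DELIMITER) if c]


def read_cohort(tsv_path: str | Path) -> CohortTable:
    """Read the cohort TSV into a typed :class:`CohortTable`.

    Required columns: ``subject_id``, ``sex``, ``PC1``..``PC20``,
    ``self_report_migraine``, ``icd10_codes``, ``medication_codes``;
    optional ``age``. Code lists are ``;``-delimited cells.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"subject_id": str, "sex": str})
    required = ["subject_id", "sex", "self_report_migraine", "icd10_codes", "medication_codes"]
    missing = [c for c in required + PC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {', '.join(missing)}")

    pcs = np.empty((len(df), 20), dtype=float)
    for j, col in enumerate(PC_COLUMNS):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "subject_id"].iloc[0]
            raise ValueError(f"non-numeric {col} for subject {bad}")
        pcs[:, j] = vals.to_numpy()

    try:
        sex = np.array([_SEX_CODES[str(s).strip().lower()] for s in df["sex"]], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unrecognised sex code {exc.args[0]!r}") from None

    return CohortTable(
        subject_id=df["subject_id"].to_numpy(dtype=object),
        sex=sex,
        pcs=pcs,
        self_report_migraine=df["self_report_migraine"].astype(int).to_numpy(dtype=bool),
        icd10_codes=[_parse_codes(c) for c in df["icd10_codes"]],
        medication_codes=[_parse_codes(c) for c in df["medication_codes"]],
        age=df["age"].to_numpy(dtype=float) if "age" in df.columns else None,
    )


def _load_structured(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_weight_config(path: Optional[str | Path] = None) -> WeightConfig:
    """Load a weight configuration from YAML/JSON, or the defaults when None."""
    if path is None:
        return WeightConfig()
    raw = _load_structured(path)
    kwargs = {}
    for key in ("functional_weight", "category_of", "maf_cap", "maf_weight_max", "maf_weight_min"):
        if key in raw:
            kwargs[key] = raw[key]
    return WeightConfig(**kwargs)


def load_gene_panel(path: str | Path) -> list[str]:
    raw = _load_structured(path)
    genes = raw["genes"] if isinstance(raw, dict) else raw
    return [str(g) for g in genes]


def load_literature_variants(tsv_path: str | Path) -> pd.DataFrame:
    """Read the literature-variant list (TSV: gene, transcript, aa_change[, coords])."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    for col in ("gene", "aa_change"):
        if col not in df.columns:
            raise ValueError(f"literature-variant list missing column {col!r}")
    if "transcript" not in df.columns:
        df["transcript"] = None
    return df


def _fmt(x, spec: str) -> str:
    return "" if x is None else format(x, spec)


def write_results(
    gene_results: Sequence[GeneResult],
    category_results: Sequence[CategoryResult],
    variant_results: Sequence[VariantResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three result tables as TSVs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene": out / "gene_results.tsv",
        "category": out / "category_results.tsv",
        "variant": out / "variant_results.tsv",
    }

    with open(paths["gene"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene", "SLP", "beta", "p", "n_qualifying_variants",
             "score_mean_cases", "score_mean_controls", "degenerate", "converged"]
        )
        for r in gene_results:
            w.writerow(
                [r.gene, f"{r.slp:.2f}", f"{r.beta:.6g}", f"{r.p_value:.4g}",
                 r.n_qualifying_variants, f"{r.score_mean_cases:.6g}",
                 f"{r.score_mean_controls:.6g}", int(r.degenerate), int(r.converged)]
            )

    with open(paths["category"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "category", "OR", "se_log_OR", "SLP", "test", "occurrences"])
        for r in category_results:
            w.writerow(
                [r.gene, r.category,
                 _fmt(r.odds_ratio, ".4g"), _fmt(r.se_log_or, ".4g"),
                 _fmt(r.slp, ".2f"), r.test_used or "NA", r.occurrences]
            )

    with open(paths["variant"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene", "transcript", "aa_change", "case_carriers", "case_freq",
             "control_carriers", "control_freq", "chi2", "p", "pooled"]
        )
        for r in variant_results:
            w.writerow(
                [r.gene, r.transcript or "", r.aa_change or "",
                 r.case_carriers, f"{r.case_freq:.5f}",
                 r.control_carriers, f"{r.control_freq:.5f}",
                 f"{r.chi2:.2f}", f"{r.p_value:.2g}", int(r.pooled)]
            )
    return paths
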