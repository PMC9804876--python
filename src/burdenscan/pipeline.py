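"""End-to-end orchestration: validate -> read -> classify -> weight -> test -> report.

Manifest-first execution: every referenced input is checked (and hashed) before
any computation, so failures are early and attributable. Given identical inputs
the run is deterministic and result files are hash-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from burdenscan import __version__
from burdenscan.burden_assoc import gene_burden_test
from burdenscan.cohort_io import (
    annotate_records,
    load_gene_panel,
    load_literature_variants,
    load_weight_config,
    read_annotations,
    read_cohort,
    read_genotypes,
    write_results,
)
from burdenscan.phenotype import PhenotypeConfig, assign_case_status, phenotype_summary
from burdenscan.variant_tests import (
    category_regression,
    frameshift_aggregate,
    literature_variant_tests,
)
from burdenscan.weighting import weight_variants

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: Path
    annotations: Path
    cohort: Path
    out_dir: Path
    weights: Optional[Path] = None
    phenotype: Optional[Path] = None
    gene_panel: Optional[Path] = None
    literature_variants: Optional[Path] = None
    frameshift_genes: list[str] = field(default_factory=list)
    run_gene_tests: bool = True
    run_category_tests: bool = True
    run_variant_tests: bool = True
    n_pcs: Optional[int] = None

    def validate(self) -> None:
        for name in ("vcf", "annotations", "cohort", "weights", "phenotype",
                     "gene_panel", "literature_variants"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict (also written as manifest)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "version": __version__,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (
                ("vcf", config.vcf),
                ("annotations", config.annotations),
                ("cohort", config.cohort),
                ("weights", config.weights),
                ("phenotype", config.phenotype),
                ("gene_panel", config.gene_panel),
                ("literature_variants", config.literature_variants),
            )
            if p is not None
        },
        "toggles": {
            "gene_tests": config.run_gene_tests,
            "category_tests": config.run_category_tests,
            "variant_tests": config.run_variant_tests,
        },
    }

    weight_config = load_weight_config(config.weights)
    pheno_config = PhenotypeConfig.from_file(config.phenotype) if config.phenotype else None

    cohort = read_cohort(config.cohort)
    assign_case_status(cohort, pheno_config)
    manifest["phenotype_summary"] = phenotype_summary(cohort, pheno_config)

    read_report: dict = {}
    records = read_genotypes(config.vcf, cohort.subject_id, report=read_report)
    records = annotate_records(records, read_annotations(config.annotations),
                               weight_config, report=read_report)
    manifest["read_report"] = read_report

    genes = (
        load_gene_panel(config.gene_panel)
        if config.gene_panel
        else sorted({r.gene for r in records})
    )

    gene_results, category_results, variant_results = [], [], []
    for gene in genes:
        gene_records = [r for r in records if r.gene == gene]
        weighted = weight_variants(gene_records, cohort, weight_config)
        if config.run_gene_tests:
            gene_results.append(
                gene_burden_test(weighted, cohort, gene, n_pcs=config.n_pcs)
            )
        if config.run_category_tests:
            category_results.extend(
                category_regression(weighted, cohort, weight_config, gene,
                                    n_pcs=config.n_pcs)
            )

    if config.run_variant_tests:
        if config.literature_variants:
            variant_results.extend(
                literature_variant_tests(
                    load_literature_variants(config.literature_variants), records, cohort
                )
            )
        for gene in config.frameshift_genes:
            variant_results.append(frameshift_aggregate(gene, records, cohort))

    paths = write_results(gene_results, category_results, variant_results, out)
    manifest["outputs"] = {k: str(p) for k, p in paths.items()}
    bonferroni = 0.05 / max(len(genes), 1)
    manifest["bonferroni_threshold"] = {"n_genes": len(genes), "alpha_0.05": bonferroni}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %s", manifest_path)
    return manifest
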