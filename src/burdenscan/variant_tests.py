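"""Category-level and single-variant / pooled carrier tests.

Carrier convention: a subject with dosage >= 1 counts once (het or hom);
missing genotypes count as non-carriers. Contingency tests are Pearson
chi-squared with 1 df and no continuity correction; category tests fall back
to Fisher's exact test when the category has fewer than 50 variant-allele
occurrences.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from burdenscan.burden_assoc import _drop_degenerate_columns, _fit_logit, covariate_matrix, slp_from_p
from burdenscan.model import (
    CategoryResult,
    CohortTable,
    VariantRecord,
    VariantResult,
    WeightConfig,
    WeightedVariant,
)

logger = logging.getLogger(__name__)

FISHER_OCCURRENCE_THRESHOLD = 50
MIN_INDIVIDUAL_CARRIERS = 20


def carrier_chisq(
    case_carriers: int, case_n: int, control_carriers: int, control_n: int
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 carrier table.

    Returns (chi2, p). Zero carriers in both strata gives (0.0, 1.0).
    """
    if case_n <= 0 or control_n <= 0:
        raise ValueError("empty stratum")
    if case_carriers > case_n or control_carriers > control_n:
        raise ValueError("carrier count exceeds stratum size")
    table = np.array(
        [
            [case_carriers, case_n - case_carriers],
            [control_carriers, control_n - control_carriers],
        ],
        dtype=float,
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def _category_counts(
    gene_variants: Sequence[WeightedVariant], config: WeightConfig, n_subjects: int
) -> dict[str, np.ndarray]:
    """Per-subject variant-allele counts for each category present in the config."""
    counts = {cat: np.zeros(n_subjects, dtype=float) for cat in config.categories}
    for wv in gene_variants:
        cat = config.category_of[wv.variant.consequence]
        dosage = np.maximum(wv.variant.genotypes, 0).astype(float)  # missing -> 0
        counts[cat] += dosage
    return counts


def _category_carriers(
    gene_variants: Sequence[WeightedVariant], config: WeightConfig, n_subjects: int
) -> dict[str, np.ndarray]:
    carriers = {cat: np.zeros(n_subjects, dtype=bool) for cat in config.categories}
    for wv in gene_variants:
        cat = config.category_of[wv.variant.consequence]
        carriers[cat] |= wv.variant.genotypes >= 1
    return carriers


def category_regression(
    gene_variants: Sequence[WeightedVariant],
    cohort: CohortTable,
    weight_config: Optional[WeightConfig] = None,
    gene: str = "",
    n_pcs: Optional[int] = None,
) -> list[CategoryResult]:
    """Joint logistic regression of case status on per-category variant counts.

    One model per gene with one count predictor per non-empty category plus sex
    and principal components. Per-category p is the Wald test when the category
    has >= 50 variant-allele occurrences, otherwise Fisher's exact test on the
    carrier 2x2 table. SLP is signed positive when the mean count is higher in
    cases. Empty categories are reported as NA rows.
    """
    config = weight_config or WeightConfig()
    cohort._require_status()
    y = cohort.is_case.astype(float)
    counts = _category_counts(gene_variants, config, cohort.n)
    carriers = _category_carriers(gene_variants, config, cohort.n)
    occurrences = {cat: int(c.sum()) for cat, c in counts.items()}
    active = [cat for cat in config.categories if occurrences[cat] > 0]

    results: list[CategoryResult] = []
    if not active:
        return [
            CategoryResult(gene, cat, None, None, None, None, 0) for cat in config.categories
        ]

    covs = covariate_matrix(cohort, n_pcs)
    X = np.column_stack([np.ones(cohort.n)] + [counts[cat] for cat in active] + [covs])
    X, keep = _drop_degenerate_columns(X)
    # map retained count columns back to their categories
    kept_active = [cat for i, cat in enumerate(active) if keep[1 + i]]
    dropped = set(active) - set(kept_active)
    if dropped:
        logger.warning("gene %s: collinear category column(s) pruned: %s", gene, sorted(dropped))

    params, _, _ = _fit_logit(y, X)
    # observed-information standard errors
    eta = X @ params
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    try:
        cov = np.linalg.inv(X.T @ (X * W[:, None]))
        ses = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        ses = np.full(X.shape[1], np.nan)

    col = {cat: 1 + kept_active.index(cat) for cat in kept_active}
    for cat in config.categories:
        occ = occurrences[cat]
        if occ == 0:
            results.append(CategoryResult(gene, cat, None, None, None, None, 0))
            continue
        mean_cases = counts[cat][cohort.is_case].mean()
        mean_controls = counts[cat][~cohort.is_case].mean()
        higher_in_cases = mean_cases > mean_controls
        beta = se = None
        if cat in col:
            beta = float(params[col[cat]])
            se = float(ses[col[cat]])
        if occ >= FISHER_OCCURRENCE_THRESHOLD and beta is not None and np.isfinite(se) and se > 0:
            p = float(2.0 * stats.norm.sf(abs(beta) / se))
            test = "wald"
        else:
            carr = carriers[cat]
            table = [
                [int(carr[cohort.is_case].sum()), int((~carr[cohort.is_case]).sum())],
                [int(carr[~cohort.is_case].sum()), int((~carr[~cohort.is_case]).sum())],
            ]
            p = float(stats.fisher_exact(table)[1])
            test = "fisher"
        p = min(max(p, np.finfo(float).tiny), 1.0)
        results.append(
            CategoryResult(
                gene=gene,
                category=cat,
                odds_ratio=None if beta is None else float(np.exp(beta)),
                se_log_or=se,
                slp=slp_from_p(p, higher_in_cases),
                test_used=test,
                occurrences=occ,
                p_value=p,
            )
        )
    return results


def _carrier_union(records: Iterable[VariantRecord], n_subjects: int) -> np.ndarray:
    mask = np.zeros(n_subjects, dtype=bool)
    for rec in records:
        mask |= rec.genotypes >= 1
    return mask


def _result_from_mask(
    mask: np.ndarray,
    cohort: CohortTable,
    gene: str,
    transcript: Optional[str],
    aa_change: Optional[str],
    pooled: bool,
) -> VariantResult:
    case_c = int(mask[cohort.is_case].sum())
    ctrl_c = int(mask[~cohort.is_case].sum())
    chi2, p = carrier_chisq(case_c, cohort.n_cases, ctrl_c, cohort.n_controls)
    return VariantResult(
        gene=gene,
        transcript=transcript,
        aa_change=aa_change,
        case_carriers=case_c,
        control_carriers=ctrl_c,
        case_n=cohort.n_cases,
        control_n=cohort.n_controls,
        chi2=chi2,
        p_value=p,
        pooled=pooled,
    )


def literature_variant_tests(
    variant_list: pd.DataFrame,
    records: Sequence[VariantRecord],
    cohort: CohortTable,
    min_carriers: int = MIN_INDIVIDUAL_CARRIERS,
) -> list[VariantResult]:
    """Test listed variants individually when carried by >= ``min_carriers``
    subjects in the full sample, pooling rarer ones per gene.

    List entries are matched against annotated records by (gene, aa_change),
    or by coordinates when chrom/pos/ref/alt columns are present. A listed
    variant absent from the data contributes zero carriers. Pooled counts are
    de-duplicated by subject (a subject carrying two pooled variants counts
    once).
    """
    cohort._require_status()
    by_ga: dict[tuple[str, str], list[VariantRecord]] = {}
    by_key = {rec.key: rec for rec in records}
    for rec in records:
        if rec.gene is not None and rec.aa_change:
            by_ga.setdefault((rec.gene, rec.aa_change), []).append(rec)

    has_coords = all(c in variant_list.columns for c in ("chrom", "pos", "ref", "alt"))
    matched: list[tuple[pd.Series, list[VariantRecord]]] = []
    for _, row in variant_list.iterrows():
        recs: list[VariantRecord] = []
        if has_coords and pd.notna(row.get("chrom")):
            rec = by_key.get(
                (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
            )
            if rec is not None:
                recs = [rec]
        if not recs:
            recs = by_ga.get((row["gene"], row["aa_change"]), [])
        matched.append((row, recs))

    results: list[VariantResult] = []
    pooled_by_gene: dict[str, list[tuple[pd.Series, list[VariantRecord]]]] = {}
    for row, recs in matched:
        mask = _carrier_union(recs, cohort.n)
        if int(mask.sum()) >= min_carriers:
            results.append(
                _result_from_mask(
                    mask, cohort, row["gene"], row.get("transcript"), row["aa_change"], False
                )
            )
        else:
            pooled_by_gene.setdefault(row["gene"], []).append((row, recs))

    for gene, items in pooled_by_gene.items():
        all_recs = [rec for _, recs in items for rec in recs]
        mask = _carrier_union(all_recs, cohort.n)
        transcript = next(
            (r.get("transcript") for r, _ in items if pd.notna(r.get("transcript"))), None
        )
        results.append(
            _result_from_mask(mask, cohort, gene, transcript, None, True)
        )
    return results


def frameshift_aggregate(
    gene: str, records: Sequence[VariantRecord], cohort: CohortTable
) -> VariantResult:
    """Carrier test on the union of all frameshift-variant carriers in a gene."""
    cohort._require_status()
    fs = [r for r in records if r.gene == gene and r.consequence == "frameshift_variant"]
    mask = _carrier_union(fs, cohort.n)
    transcript = next((r.transcript for r in fs if r.transcript), None)
    return _result_from_mask(mask, cohort, gene, transcript, "frameshift_aggregate", True)
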