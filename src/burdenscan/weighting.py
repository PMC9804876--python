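"""Variant weighting: functional weight x MAF weight, plus the rare-variant filter.

A variant qualifies when its minor allele frequency is <= ``maf_cap`` (default
0.01) in cases AND in controls, separately. The MAF weight declines linearly
from ``maf_weight_max`` (default 10) at MAF 0 to ``maf_weight_min`` (default 1)
at the cap; the weighting MAF is taken from the full sample while the
inclusion filter uses the stratum MAFs.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from burdenscan.model import (
    CohortTable,
    VariantRecord,
    WeightConfig,
    WeightedVariant,
)


def assign_functional_weight(consequence: str, config: WeightConfig) -> float:
    """Configured weight for a consequence term; unknown terms are an error."""
    try:
        return config.functional_weight[consequence]
    except KeyError:
        raise ValueError(f"unknown consequence term {consequence!r}") from None


def maf_weight(maf: float, config: Optional[WeightConfig] = None) -> float:
    """Linear MAF weight: ``maf_weight_max`` at 0 down to ``maf_weight_min`` at the cap."""
    config = config or WeightConfig()
    if maf < 0 or maf > config.maf_cap:
        raise ValueError(f"MAF {maf} outside [0, {config.maf_cap}]; filter first")
    span = config.maf_weight_max - config.maf_weight_min
    return config.maf_weight_min + span * (config.maf_cap - maf) / config.maf_cap


def _stratum_maf(dosage: np.ndarray, mask: np.ndarray) -> float:
    d = dosage[mask]
    ok = d >= 0
    n = int(ok.sum())
    if n == 0:
        raise ValueError("stratum has no non-missing genotypes")
    freq = d[ok].sum() / (2.0 * n)
    return min(freq, 1.0 - freq)


def compute_mafs(variant: VariantRecord, cohort: CohortTable) -> tuple[float, float, float]:
    """Minor allele frequency in cases, controls and the full sample.

    Frequency is (sum of dosages) / (2 x non-missing subjects) per stratum,
    folded to the minor allele.
    """
    cohort._require_status()
    is_case = cohort.is_case
    return (
        _stratum_maf(variant.genotypes, is_case),
        _stratum_maf(variant.genotypes, ~is_case),
        _stratum_maf(variant.genotypes, np.ones(cohort.n, dtype=bool)),
    )


def weight_variants(
    records: Iterable[VariantRecord],
    cohort: CohortTable,
    config: Optional[WeightConfig] = None,
    report: Optional[dict] = None,
) -> list[WeightedVariant]:
    """Apply the rare-variant filter and weight each qualifying variant."""
    config = config or WeightConfig()
    kept: list[WeightedVariant] = []
    n_excluded = 0
    for rec in records:
        maf_cases, maf_controls, maf_overall = compute_mafs(rec, cohort)
        if maf_cases > config.maf_cap or maf_controls > config.maf_cap:
            n_excluded += 1
            continue
        kept.append(
            WeightedVariant(
                variant=rec,
                maf_cases=maf_cases,
                maf_controls=maf_controls,
                maf_overall=maf_overall,
                functional_weight=assign_functional_weight(rec.consequence, config),
                maf_weight=maf_weight(min(maf_overall, config.maf_cap), config),
            )
        )
    if report is not None:
        report.update(n_maf_excluded=n_excluded, n_qualifying=len(kept))
    return kept
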