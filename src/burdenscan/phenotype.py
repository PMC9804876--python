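"""Composite case definition and cohort phenotype summaries.

A subject is a case when any of three indicators holds: self-reported
migraine, an ICD-10 code under the configured prefix, or use of a configured
migraine-specific medication. Everyone else is a control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from burdenscan.model import CohortTable

# Placeholder medication code set standing in for a curated migraine-specific
# medication list; swap via PhenotypeConfig / config file in real analyses.
DEFAULT_MEDICATION_CODES: frozenset[str] = frozenset(
    {
        "MIG_SUMATRIPTAN",
        "MIG_RIZATRIPTAN",
        "MIG_ZOLMITRIPTAN",
        "MIG_NARATRIPTAN",
        "MIG_ELETRIPTAN",
        "MIG_ALMOTRIPTAN",
        "MIG_FROVATRIPTAN",
        "MIG_ERGOTAMINE",
        "MIG_PIZOTIFEN",
        "MIG_CLONIDINE_MIGRAINE",
    }
)


@dataclass
class PhenotypeConfig:
    """ICD-10 prefix and medication code set defining the composite phenotype."""

    icd10_prefix: str = "G43"
    medication_codes: frozenset[str] = field(default_factory=lambda: DEFAULT_MEDICATION_CODES)
    use_medication_criterion: bool = True

    def __post_init__(self) -> None:
        self.medication_codes = frozenset(self.medication_codes)
        if self.use_medication_criterion and not self.medication_codes:
            raise ValueError("medication_codes must be non-empty when the criterion is enabled")

    @classmethod
    def from_file(cls, path: str | Path) -> "PhenotypeConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            icd10_prefix=raw.get("icd10_prefix", "G43"),
            medication_codes=frozenset(raw.get("medication_codes", DEFAULT_MEDICATION_CODES)),
            use_medication_criterion=raw.get("use_medication_criterion", True),
        )


def _strip_dots(code: str) -> str:
    return code.replace(".", "")


def icd10_matches(code: str, prefix: str) -> bool:
    """Prefix match after stripping dots: 'G431' and 'G43.1' both match 'G43'."""
    return _strip_dots(code).startswith(_strip_dots(prefix))


def classify_case(
    self_report: bool,
    icd10_codes: list[str],
    medication_codes: list[str],
    config: Optional[PhenotypeConfig] = None,
) -> bool:
    """True iff any of the three phenotype indicators holds for this subject."""
    config = config or PhenotypeConfig()
    if self_report:
        return True
    if any(icd10_matches(c, config.icd10_prefix) for c in icd10_codes):
        return True
    if config.use_medication_criterion and any(
        c in config.medication_codes for c in medication_codes
    ):
        return True
    return False


def indicator_flags(cohort: CohortTable, config: Optional[PhenotypeConfig] = None) -> np.ndarray:
    """Per-subject boolean (n, 3) array: [self_report, icd10, medication]."""
    config = config or PhenotypeConfig()
    flags = np.zeros((cohort.n, 3), dtype=bool)
    flags[:, 0] = cohort.self_report_migraine
    for i in range(cohort.n):
        flags[i, 1] = any(icd10_matches(c, config.icd10_prefix) for c in cohort.icd10_codes[i])
        if config.use_medication_criterion:
            flags[i, 2] = any(c in config.medication_codes for c in cohort.medication_codes[i])
    return flags


def assign_case_status(cohort: CohortTable, config: Optional[PhenotypeConfig] = None) -> CohortTable:
    """Derive ``is_case`` for the whole cohort (in place; returns the cohort)."""
    cohort.is_case = indicator_flags(cohort, config).any(axis=1)
    return cohort


def phenotype_summary(cohort: CohortTable, config: Optional[PhenotypeConfig] = None) -> dict:
    """Cohort-level counts and the 7-way indicator-combination breakdown.

    The breakdown keys are strings like ``"self_report+icd10"``; its cell
    counts partition the cases (they sum to ``n_cases``).
    """
    if cohort.is_case is None:
        assign_case_status(cohort, config)
    flags = indicator_flags(cohort, config)
    is_case = cohort.is_case

    names = ("self_report", "icd10", "medication")
    breakdown: dict[str, int] = {}
    for mask in range(1, 8):
        combo = tuple(bool(mask >> b & 1) for b in range(3))
        label = "+".join(n for n, on in zip(names, combo) if on)
        breakdown[label] = int((flags == np.array(combo)).all(axis=1).sum())

    def pct_female(mask: np.ndarray) -> float:
        return float("nan") if mask.sum() == 0 else 100.0 * cohort.sex[mask].mean()

    summary = {
        "n": cohort.n,
        "n_cases": int(is_case.sum()),
        "n_controls": int((~is_case).sum()),
        "pct_female_cases": pct_female(is_case),
        "pct_female_controls": pct_female(~is_case),
        "breakdown": breakdown,
    }
    if cohort.age is not None:
        for label, mask in (("cases", is_case), ("controls", ~is_case)):
            if mask.sum():
                summary[f"age_mean_{label}"] = float(cohort.age[mask].mean())
                summary[f"age_sd_{label}"] = float(cohort.age[mask].std(ddof=1))
    return summary
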