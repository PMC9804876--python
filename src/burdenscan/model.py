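"""Core data model: variants, cohort, weight configuration and result records."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MISSING = -1  # sentinel for a missing genotype in dosage vectors

# Default consequence -> functional weight table. The two anchors
# (stop_gained=100, missense_variant=5) are fixed; the remaining entries follow
# a severity ordering and are fully overridable via configuration.
DEFAULT_FUNCTIONAL_WEIGHTS: dict[str, float] = {
    "stop_gained": 100.0,
    "frameshift_variant": 100.0,
    "splice_donor_variant": 100.0,
    "splice_acceptor_variant": 100.0,
    "missense_variant": 5.0,
    "inframe_insertion": 5.0,
    "inframe_deletion": 5.0,
    "splice_region_variant": 3.0,
    "synonymous_variant": 1.0,
    "intron_variant": 1.0,
    "5_prime_UTR_variant": 1.0,
    "3_prime_UTR_variant": 1.0,
}

# Default consequence -> broad category map.
DEFAULT_CATEGORIES: dict[str, str] = {
    "stop_gained": "LOF",
    "frameshift_variant": "LOF",
    "splice_donor_variant": "LOF",
    "splice_acceptor_variant": "LOF",
    "missense_variant": "protein_altering",
    "inframe_insertion": "protein_altering",
    "inframe_deletion": "protein_altering",
    "splice_region_variant": "splice_site",
    "synonymous_variant": "synonymous",
    "intron_variant": "intronic",
    "5_prime_UTR_variant": "intronic",
    "3_prime_UTR_variant": "intronic",
}


def normalize_chrom(chrom: str) -> str:
    """Strip any leading 'chr' prefix so GRCh38 naming dialects compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class VariantRecord:
    """One biallelic variant with per-subject minor-allele dosages.

    ``genotypes`` holds ALT-allele dosage per subject in {0, 1, 2} with
    :data:`MISSING` (-1) marking a missing call. Folding to the minor allele
    happens in the weighting module, not here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    gene: Optional[str] = None
    transcript: Optional[str] = None
    consequence: Optional[str] = None
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(str(self.chrom))
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(
                f"variant {self.key}: dosages must be in {{-1,0,1,2}}, "
                f"got {np.unique(self.genotypes[bad])}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    def carriers(self) -> np.ndarray:
        """Boolean mask of subjects with dosage >= 1 (missing counts as non-carrier)."""
        return self.genotypes >= 1


@dataclass
class CohortTable:
    """Per-subject covariates and phenotype-source fields.

    ``sex`` is coded 1 = female, 0 = male for regression. ``is_case`` is
    derived by the phenotype module and is ``None`` until assigned.
    """

    subject_id: np.ndarray
    sex: np.ndarray
    pcs: np.ndarray
    self_report_migraine: np.ndarray
    icd10_codes: list[list[str]]
    medication_codes: list[list[str]]
    is_case: Optional[np.ndarray] = None
    age: Optional[np.ndarray] = None

    N_PCS = 20

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.pcs = np.asarray(self.pcs, dtype=float)
        self.self_report_migraine = np.asarray(self.self_report_migraine, dtype=bool)
        n = len(self.subject_id)
        if len(set(self.subject_id)) != n:
            ids, counts = np.unique(self.subject_id, return_counts=True)
            dupes = ids[counts > 1]
            raise ValueError(f"duplicated subject_id: {', '.join(map(str, dupes))}")
        if self.pcs.shape != (n, self.N_PCS):
            raise ValueError(
                f"pcs must have shape ({n}, {self.N_PCS}), got {self.pcs.shape}"
            )
        for name, arr in (
            ("sex", self.sex),
            ("self_report_migraine", self.self_report_migraine),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != cohort size {n}")
        if len(self.icd10_codes) != n or len(self.medication_codes) != n:
            raise ValueError("code lists must match cohort size")
        if self.is_case is not None:
            self.is_case = np.asarray(self.is_case, dtype=bool)
            if len(self.is_case) != n:
                raise ValueError("is_case length mismatch")

    @property
    def n(self) -> int:
        return len(self.subject_id)

    @property
    def n_cases(self) -> int:
        self._require_status()
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        self._require_status()
        return int((~self.is_case).sum())

    def _require_status(self) -> None:
        if self.is_case is None:
            raise ValueError("case status not assigned; run phenotype classification first")


@dataclass
class WeightConfig:
    """Consequence weights, category map and the MAF-weight parameters."""

    functional_weight: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTIONAL_WEIGHTS)
    )
    category_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    maf_cap: float = 0.01
    maf_weight_max: float = 10.0
    maf_weight_min: float = 1.0

    def __post_init__(self) -> None:
        if self.maf_weight_min > self.maf_weight_max:
            raise ValueError("maf_weight_min must be <= maf_weight_max")
        if self.maf_cap <= 0:
            raise ValueError("maf_cap must be positive")
        for cons, w in self.functional_weight.items():
            if w <= 0:
                raise ValueError(f"functional weight for {cons!r} must be positive")
        missing_cat = set(self.functional_weight) - set(self.category_of)
        if missing_cat:
            raise ValueError(
                f"consequences lacking a category: {', '.join(sorted(missing_cat))}"
            )

    @property
    def categories(self) -> list[str]:
        """Category labels in a stable order."""
        seen: dict[str, None] = {}
        for cons in self.functional_weight:
            seen.setdefault(self.category_of[cons], None)
        return list(seen)


@dataclass
class WeightedVariant:
    """A variant that passed the rare-variant filter, with its weights."""

    variant: VariantRecord
    maf_cases: float
    maf_controls: float
    maf_overall: float
    functional_weight: float
    maf_weight: float

    @property
    def overall_weight(self) -> float:
        return self.functional_weight * self.maf_weight


@dataclass
class GeneResult:
    gene: str
    slp: float
    beta: float
    p_value: float
    n_qualifying_variants: int
    score_mean_cases: float
    score_mean_controls: float
    wald_p: Optional[float] = None
    degenerate: bool = False
    converged: bool = True


@dataclass
class CategoryResult:
    gene: str
    category: str
    odds_ratio: Optional[float]
    se_log_or: Optional[float]
    slp: Optional[float]
    test_used: Optional[str]  # "wald" or "fisher"; None when the category is empty
    occurrences: int
    p_value: Optional[float] = None


@dataclass
class VariantResult:
    gene: str
    transcript: Optional[str]
    aa_change: Optional[str]
    case_carriers: int
    control_carriers: int
    case_n: int
    control_n: int
    chi2: float
    p_value: float
    pooled: bool = False

    @property
    def case_freq(self) -> float:
        return self.case_carriers / self.case_n

    @property
    def control_freq(self) -> float:
        return self.control_carriers / self.control_n


def subject_index(cohort: CohortTable) -> dict[str, int]:
    return {sid: i for i, sid in enumerate(cohort.subject_id)}
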