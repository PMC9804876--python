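import numpy as np
import pytest

from burdenscan.model import CohortTable, VariantRecord
from burdenscan.synth_cohort import GeneSpec, SimConfig, render_fixture, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-gene synthetic cohort shared by read/roundtrip tests."""
    cfg = SimConfig(
        n_subjects=800,
        seed=42,
        genes=[GeneSpec("GENEA", n_variants=12), GeneSpec("GENEB", n_variants=8)],
        missing_rate=0.02,
        burden_beta=0.001,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    records, cohort, annotations, truth = small_sim
    out = tmp_path_factory.mktemp("fixture")
    paths = render_fixture(records, cohort, out, annotations, truth)
    return paths


def make_cohort(n, seed=0, n_cases=None, pcs=None, sex=None):
    """Hand-rolled cohort helper for unit tests (no phenotype plumbing)."""
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = rng.integers(0, 2, n)
    if pcs is None:
        pcs = rng.standard_normal((n, 20))
    is_case = np.zeros(n, dtype=bool)
    if n_cases:
        is_case[rng.choice(n, n_cases, replace=False)] = True
    return CohortTable(
        subject_id=np.array([f"S{i}" for i in range(n)], dtype=object),
        sex=sex,
        pcs=pcs,
        self_report_migraine=is_case.copy(),
        icd10_codes=[[] for _ in range(n)],
        medication_codes=[[] for _ in range(n)],
        is_case=is_case,
    )


def make_variant(genotypes, gene="G1", consequence="missense_variant", pos=100,
                 aa_change=None, transcript="ENST_T1", chrom="1"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alt="G",
        genotypes=np.asarray(genotypes, dtype=np.int8),
        gene=gene, transcript=transcript, consequence=consequence, aa_change=aa_change,
    )
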