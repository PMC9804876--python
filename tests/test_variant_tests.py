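import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from burdenscan.model import WeightConfig
from burdenscan.variant_tests import (
    carrier_chisq,
    category_regression,
    frameshift_aggregate,
    literature_variant_tests,
)
from burdenscan.weighting import weight_variants

from conftest import make_cohort, make_variant


def oracle_chisq(a, na, b, nb):
    """Brute-force Pearson statistic from expected counts."""
    obs = np.array([[a, na - a], [b, nb - b]], dtype=float)
    total = obs.sum()
    exp = np.outer(obs.sum(1), obs.sum(0)) / total
    return float(((obs - exp) ** 2 / exp).sum())


class TestCarrierChisq:
    # the three KCNK18 tables and the ATP1A2 p.(Glu492Lys) table
    @pytest.mark.parametrize(
        "table,chi2_exp,p_exp",
        [
            ((10, 7194, 196, 193433), 0.96, 0.33),
            ((6, 7194, 205, 193433), 0.34, 0.56),
            ((16, 7194, 421, 193433), 0.01, 0.93),
            ((18, 7194, 298, 193433), 4.08, 0.04),
        ],
    )
    def test_published_tables(self, table, chi2_exp, p_exp):
        chi2, p = carrier_chisq(*table)
        assert round(chi2, 2) == chi2_exp
        assert round(p, 2) == p_exp

    def test_no_association_when_proportions_equal(self):
        chi2, p = carrier_chisq(10, 100, 100, 1000)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_carriers_both_strata(self):
        assert carrier_chisq(0, 100, 0, 1000) == (0.0, 1.0)

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError):
            carrier_chisq(0, 0, 5, 100)

    def test_carriers_exceeding_stratum_errors(self):
        with pytest.raises(ValueError):
            carrier_chisq(11, 10, 5, 100)

    @settings(max_examples=200, deadline=None)
    @given(
        na=st.integers(2, 5000), nb=st.integers(2, 5000),
        fa=st.floats(0, 1), fb=st.floats(0, 1),
    )
    def test_matches_brute_force(self, na, nb, fa, fb):
        a, b = int(fa * na), int(fb * nb)
        if (a + b == 0) or (a == na and b == nb):
            return
        chi2, _ = carrier_chisq(a, na, b, nb)
        assert chi2 == pytest.approx(oracle_chisq(a, na, b, nb), abs=1e-10)

    def test_fisher_chisq_asymptotic_agreement(self):
        # smallest expected cell >= 10 -> the two p-values agree within 20%
        for a, na, b, nb in [(30, 1000, 45, 2000), (25, 500, 60, 1500)]:
            exp_min = min(
                (a + b) * na / (na + nb), (a + b) * nb / (na + nb),
                (na - a + nb - b) * na / (na + nb), (na - a + nb - b) * nb / (na + nb),
            )
            assert exp_min >= 10
            _, p_chi = carrier_chisq(a, na, b, nb)
            p_f = stats.fisher_exact([[a, na - a], [b, nb - b]])[1]
            assert abs(p_chi - p_f) / p_f < 0.2


def _category_fixture(n=4000, seed=0, lof_case_boost=0):
    rng = np.random.default_rng(seed)
    cohort = make_cohort(n, seed=seed, n_cases=n // 10)
    variants = []
    for i, cons in enumerate(
        ["stop_gained", "missense_variant", "missense_variant", "synonymous_variant"]
    ):
        dosage = rng.binomial(1, 0.004, n).astype(np.int8)
        if cons == "stop_gained" and lof_case_boost:
            extra = rng.random(n) < lof_case_boost * cohort.is_case
            dosage = np.maximum(dosage, extra.astype(np.int8))
        variants.append(make_variant(dosage, consequence=cons, pos=100 + i))
    return cohort, weight_variants(variants, cohort)


class TestCategoryRegression:
    def test_empty_category_reported_na(self):
        cohort, weighted = _category_fixture()
        results = {r.category: r for r in category_regression(weighted, cohort, n_pcs=3)}
        assert results["intronic"].occurrences == 0
        assert results["intronic"].test_used is None
        assert results["intronic"].slp is None

    def test_fisher_below_50_occurrences(self):
        cohort, weighted = _category_fixture()
        results = {r.category: r for r in category_regression(weighted, cohort, n_pcs=3)}
        for r in results.values():
            if r.test_used is not None:
                assert (r.test_used == "fisher") == (r.occurrences < 50)

    def test_wald_at_or_above_50(self):
        cohort, weighted = _category_fixture(n=30000, seed=2)
        results = {r.category: r for r in category_regression(weighted, cohort, n_pcs=3)}
        pa = results["protein_altering"]
        assert pa.occurrences >= 50 and pa.test_used == "wald"
        assert pa.odds_ratio is not None and pa.se_log_or is not None

    def test_or_and_slp_sign_when_lof_enriched(self):
        cohort, weighted = _category_fixture(n=20000, seed=3, lof_case_boost=0.01)
        results = {r.category: r for r in category_regression(weighted, cohort, n_pcs=3)}
        lof = results["LOF"]
        assert lof.slp is not None and lof.slp > 0
        assert lof.odds_ratio is None or lof.odds_ratio > 1

    def test_lof_effect_detected_across_replicates(self):
        """With only the LOF category affecting liability (OR 3 per count),
        the LOF SLP is positive and the largest in >= 90% of replicates."""
        from burdenscan.synth_cohort import GeneSpec, SimConfig, simulate_cohort

        wins = 0
        n_reps = 40
        for rep in range(n_reps):
            cfg = SimConfig(
                n_subjects=20000,
                seed=1000 + rep,
                genes=[GeneSpec(
                    "G",
                    n_variants=16,
                    consequence_mix={
                        "stop_gained": 0.25, "missense_variant": 0.35,
                        "synonymous_variant": 0.2, "intron_variant": 0.2,
                    },
                    maf_beta_a=1.0, maf_beta_b=6.0,
                )],
                category_betas={"LOF": np.log(3.0)},
                female_case_odds_multiplier=1.0,
            )
            records, cohort, _, _ = simulate_cohort(cfg)
            weighted = weight_variants(records, cohort)
            results = category_regression(weighted, cohort, gene="G")
            slps = {r.category: r.slp for r in results if r.slp is not None}
            if slps.get("LOF", -np.inf) > 0 and slps["LOF"] == max(slps.values()):
                wins += 1
        assert wins / n_reps >= 0.9


class TestLiteratureVariantTests:
    def _setup(self, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        cohort = make_cohort(n, seed=seed, n_cases=n // 10)
        recs = []
        carriers = [60, 10, 5]  # first tested alone, other two pooled
        for i, k in enumerate(carriers):
            dosage = np.zeros(n, dtype=np.int8)
            dosage[rng.choice(n, k, replace=False)] = 1
            recs.append(
                make_variant(dosage, gene="GX", pos=100 + i, aa_change=f"p.(V{i})")
            )
        lst = pd.DataFrame(
            {"gene": ["GX"] * 3, "transcript": ["T"] * 3,
             "aa_change": ["p.(V0)", "p.(V1)", "p.(V2)"]}
        )
        return cohort, recs, lst

    def test_threshold_split(self):
        cohort, recs, lst = self._setup()
        results = literature_variant_tests(lst, recs, cohort, min_carriers=20)
        individual = [r for r in results if not r.pooled]
        pooled = [r for r in results if r.pooled]
        assert len(individual) == 1 and individual[0].aa_change == "p.(V0)"
        assert len(pooled) == 1
        assert individual[0].case_carriers + individual[0].control_carriers == 60
        assert pooled[0].case_carriers + pooled[0].control_carriers <= 15

    def test_pooled_carriers_deduplicated(self):
        cohort = make_cohort(100, n_cases=20)
        d1 = np.zeros(100, dtype=np.int8); d1[0] = 1
        d2 = np.zeros(100, dtype=np.int8); d2[0] = 1; d2[1] = 1
        recs = [make_variant(d1, gene="GX", pos=1, aa_change="p.(A)"),
                make_variant(d2, gene="GX", pos=2, aa_change="p.(B)")]
        lst = pd.DataFrame({"gene": ["GX"] * 2, "aa_change": ["p.(A)", "p.(B)"],
                            "transcript": ["T", "T"]})
        results = literature_variant_tests(lst, recs, cohort, min_carriers=20)
        assert len(results) == 1 and results[0].pooled
        total = results[0].case_carriers + results[0].control_carriers
        assert total == 2  # subject 0 counted once

    def test_listed_variant_absent_counts_zero(self):
        cohort = make_cohort(50, n_cases=10)
        lst = pd.DataFrame({"gene": ["GY"], "aa_change": ["p.(Q1X)"], "transcript": ["T"]})
        results = literature_variant_tests(lst, [], cohort)
        assert len(results) == 1
        assert results[0].case_carriers == 0 and results[0].control_carriers == 0
        assert results[0].p_value == 1.0

    def test_pooled_le_sum_of_per_variant(self):
        cohort, recs, lst = self._setup(seed=9)
        results = literature_variant_tests(lst, recs, cohort, min_carriers=1000)
        pooled_total = results[0].case_carriers + results[0].control_carriers
        per_variant_sum = sum(int((r.genotypes >= 1).sum()) for r in recs)
        assert pooled_total <= per_variant_sum

    def test_coordinate_matching(self):
        cohort = make_cohort(200, n_cases=40)
        d = np.zeros(200, dtype=np.int8); d[:30] = 1
        recs = [make_variant(d, gene="GX", pos=777, aa_change=None)]
        lst = pd.DataFrame({"gene": ["GX"], "aa_change": ["p.(?)"], "transcript": ["T"],
                            "chrom": ["1"], "pos": [777], "ref": ["A"], "alt": ["G"]})
        results = literature_variant_tests(lst, recs, cohort, min_carriers=20)
        assert results[0].case_carriers + results[0].control_carriers == 30


class TestFrameshiftAggregate:
    def test_union_not_sum(self):
        cohort = make_cohort(100, n_cases=20)
        d1 = np.zeros(100, dtype=np.int8); d1[:3] = 1
        d2 = np.zeros(100, dtype=np.int8); d2[2:5] = 1  # overlaps subject 2
        recs = [make_variant(d1, gene="KG", consequence="frameshift_variant", pos=1),
                make_variant(d2, gene="KG", consequence="frameshift_variant", pos=2),
                make_variant(d1, gene="KG", consequence="missense_variant", pos=3)]
        res = frameshift_aggregate("KG", recs, cohort)
        assert res.case_carriers + res.control_carriers == 5  # union of subjects 0..4

    def test_single_frameshift_equals_individual(self):
        cohort = make_cohort(80, n_cases=15)
        d = np.zeros(80, dtype=np.int8); d[:4] = 1
        recs = [make_variant(d, gene="KG", consequence="frameshift_variant", pos=1)]
        agg = frameshift_aggregate("KG", recs, cohort)
        case_c = int(d[cohort.is_case].sum())
        ctrl_c = int(d[~cohort.is_case].sum())
        chi2, p = carrier_chisq(case_c, cohort.n_cases, ctrl_c, cohort.n_controls)
        assert (agg.chi2, agg.p_value) == (pytest.approx(chi2), pytest.approx(p))

    def test_other_genes_ignored(self):
        cohort = make_cohort(50, n_cases=10)
        d = np.zeros(50, dtype=np.int8); d[0] = 1
        recs = [make_variant(d, gene="OTHER", consequence="frameshift_variant", pos=1)]
        res = frameshift_aggregate("KG", recs, cohort)
        assert res.case_carriers + res.control_carriers == 0
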