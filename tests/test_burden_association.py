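"""Stratified CMH association and the exome-wide scan."""

import numpy as np
import pandas as pd
import pytest

from conftest import enumerate_cmh_exact_p, enumerate_fisher_p
from qvburden.burden_association import (
    StratifiedTables,
    bonferroni_threshold,
    build_strata,
    cmh_test,
    exome_wide_scan,
    geneset_burden_test,
)
from qvburden.gene_sets import burden_profile
from qvburden.qv_selection import qualify_variants
from qvburden.stats_core import Table2x2

# per-gene carrier counts in a 25 vs 25 anemia split: (carriers in anemic,
# non-carriers in anemic, carriers in non-anemic, non-carriers in non-anemic)
NOTCH_STRATA = [
    ("LFNG", (10, 15, 5, 20)),
    ("ATXN1", (7, 18, 2, 23)),
    ("DTX3L", (1, 24, 0, 25)),
    ("NCOR2", (12, 13, 7, 18)),
]


class TestStratifiedTables:
    def test_from_printed_counts_preserves_margins(self):
        strata = StratifiedTables.from_counts(NOTCH_STRATA)
        assert len(strata) == 4
        for t in strata.tables:
            assert t.a + t.b == 25 and t.c + t.d == 25

    def test_zero_total_stratum_rejected(self):
        with pytest.raises(ValueError):
            StratifiedTables.from_counts([("empty", (0, 0, 0, 0))])

    def test_uninformative_strata_dropped(self):
        strata = StratifiedTables.from_counts(
            [("good", (3, 7, 1, 9)), ("no-carriers", (0, 10, 0, 10))])
        assert len(strata.informative()) == 1


class TestCMH:
    def test_hand_evaluated_mh_or_on_notch_counts(self):
        # sum(ad/n) = 4 + 3.22 + 0.5 + 4.32; sum(bc/n) = 1.5 + 0.72 + 0 + 1.82
        res = cmh_test(StratifiedTables.from_counts(NOTCH_STRATA))
        assert res.mh_or == pytest.approx(12.04 / 4.04, rel=1e-9)
        assert res.mh_or == pytest.approx(2.98, abs=0.005)
        assert res.ci95[0] < res.mh_or < res.ci95[1]

    def test_single_stratum_reduces_to_tail_doubled_fisher(self, rng):
        from scipy.stats import hypergeom

        for _ in range(50):
            n = int(rng.integers(6, 30))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = int(rng.integers(0, n - a - b + 1))
            d = n - a - b - c
            t = Table2x2(a, b, c, d)
            if t.has_zero_margin():
                continue
            res = cmh_test(StratifiedTables.from_counts([("g", (a, b, c, d))]))
            dist = hypergeom(n, a + b, a + c)
            expected = min(1.0, 2 * min(dist.cdf(a), dist.sf(a - 1)))
            assert res.p_value == pytest.approx(expected, rel=1e-9)
            # and the single-table MH estimate is ad/bc exactly
            if b * c > 0:
                assert res.mh_or == pytest.approx(a * d / (b * c), rel=1e-12)

    def test_identical_unit_strata_are_null(self):
        res = cmh_test(StratifiedTables.from_counts(
            [("g1", (1, 1, 1, 1)), ("g2", (1, 1, 1, 1))]))
        assert res.mh_or == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_brute_force_convolution(self, rng):
        for _ in range(40):
            k = int(rng.integers(1, 4))
            tables = []
            for _ in range(k):
                n = int(rng.integers(4, 11))
                a = int(rng.integers(0, n + 1))
                b = int(rng.integers(0, n - a + 1))
                c = int(rng.integers(0, n - a - b + 1))
                d = n - a - b - c
                if min(a + b, c + d, a + c, b + d) == 0:
                    continue
                tables.append((a, b, c, d))
            if not tables:
                continue
            labelled = [(f"s{i}", t) for i, t in enumerate(tables)]
            res = cmh_test(StratifiedTables.from_counts(labelled))
            assert res.p_value == pytest.approx(
                enumerate_cmh_exact_p(tables), rel=1e-9, abs=1e-12)

    def test_exact_and_asymptotic_agree_for_large_balanced_strata(self):
        strata = StratifiedTables.from_counts(
            [("g1", (30, 70, 18, 82)), ("g2", (25, 75, 14, 86))])
        p_exact = cmh_test(strata, mode="exact").p_value
        p_asym = cmh_test(strata, mode="asymptotic").p_value
        assert p_asym == pytest.approx(p_exact, rel=0.10)

    def test_asymptotic_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        strata = StratifiedTables.from_counts(NOTCH_STRATA)
        res = cmh_test(strata, mode="asymptotic")
        sm = StratifiedTable([np.array([[a, b], [c, d]])
                              for _, (a, b, c, d) in NOTCH_STRATA])
        ref = sm.test_null_odds(correction=True)
        assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_infinite_or_flagged_p_defined(self):
        res = cmh_test(StratifiedTables.from_counts([("g", (4, 6, 0, 10))]))
        assert np.isinf(res.mh_or)
        assert "infinite-or" in res.flags
        assert 0 <= res.p_value <= 1


class TestBuildStrata:
    def test_strata_from_burden_profile(self, small_cohort):
        c = small_cohort
        qv = qualify_variants(c.catalog, c.genotypes)
        prof = burden_profile(qv, c.genotypes, c.catalog, c.collection)
        groups = c.samples["anemia"]
        strata = build_strata(prof, groups, "GO_derived")
        n1 = int((groups == 1).sum())
        n0 = int((groups == 0).sum())
        for t in strata.tables:
            assert t.a + t.b <= n1 and t.c + t.d <= n0
            assert t.a + t.c >= 1  # informative: at least one carrier

    def test_sample_order_invariance(self, small_cohort):
        c = small_cohort
        qv = qualify_variants(c.catalog, c.genotypes)
        prof = burden_profile(qv, c.genotypes, c.catalog, c.collection)
        groups = c.samples["anemia"]
        s1 = build_strata(prof, groups, "GO_derived")
        s2 = build_strata(prof, groups.sample(frac=1.0, random_state=1),
                          "GO_derived")
        assert s1.tables == s2.tables

    def test_non_binary_groups_rejected(self, small_cohort):
        c = small_cohort
        qv = qualify_variants(c.catalog, c.genotypes)
        prof = burden_profile(qv, c.genotypes, c.catalog, c.collection)
        bad = pd.Series(np.arange(len(c.samples)), index=c.samples.index)
        with pytest.raises(ValueError, match="binary"):
            build_strata(prof, bad, "GO_derived")

    def test_variant_stratification(self, small_cohort):
        c = small_cohort
        qv = qualify_variants(c.catalog, c.genotypes)
        prof = burden_profile(qv, c.genotypes, c.catalog, c.collection)
        strata = build_strata(prof, c.samples["anemia"], "GO_derived",
                              stratify_by="variant")
        assert len(strata) >= 1


class TestGenesetBurdenTest:
    def test_duplicate_set_gives_identical_rows(self, small_cohort):
        c = small_cohort
        from qvburden.gene_sets import GeneSetCollection

        genes = list(c.collection["GO_derived"].genes)
        coll = GeneSetCollection.from_dict({"one": genes, "two": genes})
        qv = qualify_variants(c.catalog, c.genotypes)
        out = geneset_burden_test(qv, c.genotypes, c.catalog, coll,
                                  c.samples["anemia"])
        a = out[out["set"] == "one"].iloc[0]
        b = out[out["set"] == "two"].iloc[0]
        for col in ("or", "ci_low", "ci_high", "p", "strata_used"):
            assert (a[col] == b[col]) or (np.isnan(a[col]) and np.isnan(b[col]))

    def test_untestable_set_flagged(self, small_cohort):
        c = small_cohort
        from qvburden.gene_sets import GeneSetCollection

        coll = GeneSetCollection.from_dict({"empty": ["NO_SUCH_GENE"]})
        qv = qualify_variants(c.catalog, c.genotypes)
        out = geneset_burden_test(qv, c.genotypes, c.catalog, coll,
                                  c.samples["anemia"])
        assert not out["testable"].iloc[0]
        assert np.isnan(out["p"].iloc[0])


class TestScan:
    @pytest.mark.parametrize("m,expected", [
        (144249, 3.47e-7),
        (105294, 4.75e-7),
    ])
    def test_bonferroni_thresholds_to_three_significant_figures(self, m, expected):
        thr = bonferroni_threshold(m, alpha=0.05)
        assert float(f"{thr:.2e}") == pytest.approx(expected, rel=1e-9)

    def test_scan_on_cohort(self, small_cohort):
        c = small_cohort
        scan = exome_wide_scan(c.catalog, c.genotypes, c.samples["anemia"])
        assert scan.m_tested + scan.n_skipped == len(c.catalog)
        assert scan.bonferroni == pytest.approx(0.05 / scan.m_tested)
        assert (np.diff(scan.qq_observed) >= 0).all()
        assert scan.lambda_gc > 0
        # per-variant p equals a direct Fisher on the carrier table
        row = scan.table.iloc[0]
        vid = row["variant_id"]
        carrier = c.genotypes.column(vid) >= 1
        grp = c.samples["anemia"].reindex(c.genotypes.sample_ids).to_numpy()
        a = int((carrier & (grp == 1)).sum())
        b = int((~carrier & (grp == 1)).sum())
        cc = int((carrier & (grp == 0)).sum())
        d = int((~carrier & (grp == 0)).sum())
        assert row["p"] == pytest.approx(enumerate_fisher_p(a, b, cc, d), rel=1e-9)

    def test_null_scan_shows_no_inflation(self):
        # permuted labels: the exact-test scan must not inflate; with
        # discrete conditional p-values it deflates (observed <= expected),
        # the same behaviour small-cohort scans show on real exomes
        from qvburden.synthetic_data import SimConfig, simulate_cohort

        cfg = SimConfig(seed=77, n_samples=60, n_background_genes=250,
                        mean_variants_per_gene=10.0, planted_sets=())
        c = simulate_cohort(cfg)
        rng = np.random.default_rng(0)
        labels = pd.Series(rng.permutation([0, 1] * 30),
                           index=c.genotypes.sample_ids)
        scan = exome_wide_scan(c.catalog, c.genotypes, labels)
        assert 0 <= scan.lambda_gc <= 1.1  # 0 when the median p is exactly 1
        assert (scan.qq_observed <= scan.qq_expected + 0.5).all()
        assert (scan.table["p"] > scan.bonferroni).all()
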