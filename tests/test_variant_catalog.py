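"""Catalog ingestion, classification and spectrum summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qvburden.variant_catalog import (
    AFBin,
    AnnotatedVariant,
    CatalogFormatError,
    CatalogIntegrityError,
    GenotypeMatrix,
    ImpactClass,
    VariantCatalog,
    VariantType,
    af_bin,
    classify_impact,
    classify_variant_type,
    cohort_overlap,
    percentage,
    read_variant_table,
    summarize_spectrum,
    write_tsv,
    write_vcf,
)


def make_variant(i, gene="GENE1", consequence="missense_variant", pop_af=0.0005,
                 ref="A", alt="G"):
    return AnnotatedVariant(chrom="1", pos=100 + i, ref=ref, alt=alt, gene=gene,
                            consequence=consequence, pop_af=pop_af)


TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=GENE,Number=A,Type=String,Description="g">
##INFO=<ID=CONSEQ,Number=A,Type=String,Description="c">
##INFO=<ID=POP_AF,Number=A,Type=Float,Description="af">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t.\tPASS\tGENE=BRCA1;CONSEQ=stop_gained;POP_AF=0.0002\tGT\t0/0\t0/1\t1/1
1\t200\t.\tC\tT,G\t.\tPASS\tGENE=TP53,TP53;CONSEQ=missense_variant,synonymous_variant;POP_AF=0.001,0.2\tGT\t0/1\t0/2\t./.
"""


class TestReadVCF:
    @pytest.fixture()
    def toy(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        return read_variant_table(p, format="vcf")

    def test_biallelic_dosages(self, toy):
        catalog, gt = toy
        assert list(gt.column("1:100:A:G")) == [0, 1, 2]

    def test_triallelic_decomposed_per_alt(self, toy):
        catalog, gt = toy
        ids = catalog.variant_ids
        assert "1:200:C:T" in ids and "1:200:C:G" in ids
        assert len(catalog) == 3 and catalog.n_source_records == 2
        assert list(gt.column("1:200:C:T")) == [1, 0, -1]
        assert list(gt.column("1:200:C:G")) == [0, 1, -1]

    def test_missing_annotation_column_is_format_error(self, tmp_path):
        bad = TOY_VCF.replace("GENE=BRCA1;", "")
        p = tmp_path / "bad.vcf"
        p.write_text(bad)
        with pytest.raises(CatalogFormatError, match="GENE"):
            read_variant_table(p, format="vcf")

    def test_duplicate_variant_id_is_integrity_error(self, tmp_path):
        dup = TOY_VCF + "1\t100\t.\tA\tG\t.\tPASS\tGENE=X;CONSEQ=missense_variant\tGT\t0/0\t0/0\t0/0\n"
        p = tmp_path / "dup.vcf"
        p.write_text(dup)
        with pytest.raises(CatalogIntegrityError):
            read_variant_table(p, format="vcf")

    def test_duplicate_resolved_by_severity_when_requested(self, tmp_path):
        dup = TOY_VCF + "1\t100\t.\tA\tG\t.\tPASS\tGENE=BRCA1;CONSEQ=synonymous_variant\tGT\t0/0\t0/0\t0/0\n"
        p = tmp_path / "dup.vcf"
        p.write_text(dup)
        catalog, _ = read_variant_table(p, format="vcf", on_duplicate="most_severe")
        assert catalog.by_id()["1:100:A:G"].impact is ImpactClass.HI


class TestRoundTrip:
    def test_vcf_write_read_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "rt.vcf"
        write_vcf(small_cohort.catalog, small_cohort.genotypes, path)
        cat2, gt2 = read_variant_table(path, format="vcf")
        assert cat2.variant_ids == small_cohort.catalog.variant_ids
        assert np.array_equal(gt2.dosage, small_cohort.genotypes.dosage)
        for a, b in zip(small_cohort.catalog, cat2):
            assert a.gene == b.gene
            assert a.impact is b.impact
            if a.pop_af is None:
                assert b.pop_af is None
            else:
                assert b.pop_af == pytest.approx(a.pop_af, rel=1e-5)

    def test_tsv_write_read_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "rt.tsv"
        write_tsv(small_cohort.catalog, small_cohort.genotypes, path)
        cat2, gt2 = read_variant_table(path, format="tsv")
        assert cat2.variant_ids == small_cohort.catalog.variant_ids
        assert gt2.sample_ids == small_cohort.genotypes.sample_ids
        assert np.array_equal(gt2.dosage, small_cohort.genotypes.dosage)


class TestClassification:
    @pytest.mark.parametrize("term,expected", [
        ("stop_gained", ImpactClass.HI),
        ("stop gained", ImpactClass.HI),
        ("frameshift_variant", ImpactClass.HI),
        ("splice_acceptor_variant", ImpactClass.HI),
        ("splice_donor_variant", ImpactClass.HI),
        ("stop_lost", ImpactClass.HI),
        ("start_lost", ImpactClass.HI),
        ("missense_variant", ImpactClass.MISSENSE),
        ("synonymous_variant", ImpactClass.SYNONYMOUS),
        ("intron_variant", ImpactClass.OTHER),
        ("transcript_ablation", ImpactClass.OTHER),  # severe-looking but unlisted
    ])
    def test_impact_classes(self, term, expected):
        assert classify_impact(term) is expected

    def test_empty_consequence_rejected(self):
        with pytest.raises(ValueError):
            classify_impact("  ")

    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", VariantType.SNV),
        ("A", "ATT", VariantType.INSERTION),
        ("ACG", "A", VariantType.DELETION),
    ])
    def test_variant_types(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) is expected

    def test_mnv_is_other_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_variant_type("AT", "GC") is VariantType.OTHER


class TestAFBin:
    @pytest.mark.parametrize("af,expected", [
        (None, AFBin.NO_AF),
        (float("nan"), AFBin.NO_AF),
        (0.0005, AFBin.RARE),
        (0.001, AFBin.LOW_FREQUENCY),
        (0.0099, AFBin.LOW_FREQUENCY),
        (0.01, AFBin.COMMON),
        (0.05, AFBin.COMMON),
        (1.0, AFBin.COMMON),
    ])
    def test_bin_boundaries(self, af, expected):
        assert af_bin(af) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            af_bin(1.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.one_of(st.none(), st.floats(min_value=0, max_value=1)))
    def test_every_af_maps_to_exactly_one_bin(self, af):
        assert af_bin(af) in set(AFBin)


class TestSpectrum:
    def test_printed_share_arithmetic(self):
        # the percentage convention used for published impact-class shares
        assert percentage(2911, 144249) == 2.02
        assert percentage(52637, 144249) == 36.49
        assert percentage(3328, 105294) == 3.16
        assert percentage(41560, 105294) == 39.47

    def test_planted_composition(self):
        variants = ([make_variant(i, consequence="stop_gained") for i in range(10)]
                    + [make_variant(100 + i) for i in range(40)]
                    + [make_variant(200 + i, consequence="synonymous_variant")
                       for i in range(50)])
        summary = summarize_spectrum(VariantCatalog(variants))
        assert summary.class_percent["HI"] == 10.00
        assert summary.class_percent["MISSENSE"] == 40.00
        assert summary.class_percent["SYNONYMOUS"] == 50.00

    def test_empty_catalog_flagged(self):
        summary = summarize_spectrum(VariantCatalog([]))
        assert summary.n_unique_variants == 0
        assert all(v == 0 for v in summary.class_counts.values())
        assert "empty-catalog" in summary.flags

    def test_class_and_bin_counts_conserve_total(self, small_cohort):
        summary = summarize_spectrum(small_cohort.catalog, small_cohort.genotypes)
        total = summary.n_unique_variants
        assert sum(summary.class_counts.values()) == total
        assert sum(summary.af_bin_counts.values()) == total

    def test_singletons_invariant_under_sample_reorder(self, small_cohort):
        gt = small_cohort.genotypes
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(gt.sample_ids))
        s1 = summarize_spectrum(small_cohort.catalog, gt)
        s2 = summarize_spectrum(small_cohort.catalog, gt.reorder_samples(perm))
        assert s1.n_singletons == s2.n_singletons
        assert s1.singleton_af_bin_counts == s2.singleton_af_bin_counts


class TestOverlap:
    def test_identical_catalogs(self):
        cat = [make_variant(i) for i in range(5)]
        res = cohort_overlap(cat, cat)
        assert res == {"a_only": 0, "shared": 5, "b_only": 0}

    def test_disjoint_catalogs(self):
        a = [make_variant(i) for i in range(5)]
        b = [make_variant(100 + i) for i in range(4)]
        assert cohort_overlap(a, b)["shared"] == 0

    def test_planted_shared_keys(self):
        shared = [make_variant(i) for i in range(15)]
        a = shared + [make_variant(100 + i) for i in range(7)]
        b = shared + [make_variant(200 + i) for i in range(9)]
        res = cohort_overlap(a, b, key="variant_id")
        assert res == {"a_only": 7, "shared": 15, "b_only": 9}

    def test_gene_level_overlap(self):
        a = [make_variant(i, gene=f"G{i % 3}") for i in range(6)]
        b = [make_variant(100 + i, gene=f"G{i % 2}") for i in range(4)]
        res = cohort_overlap(a, b, key="gene")
        assert res == {"a_only": 1, "shared": 2, "b_only": 0}


class TestGenotypeMatrix:
    def test_allele_counts_exclude_missing(self):
        gm = GenotypeMatrix(["s1", "s2", "s3"], ["v1"],
                            np.array([[2], [-1], [1]], dtype=np.int8))
        assert gm.alt_allele_counts()[0] == 3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(["s1"], ["v1", "v2"], np.zeros((1, 1), dtype=np.int8))

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(["s1"], ["v1"], np.array([[3]], dtype=np.int8))
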