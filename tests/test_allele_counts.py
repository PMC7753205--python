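"""SNP filtering, in-silico mixing and gene aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regdiv._stats import binom_test_balanced
from regdiv.allele_counts import (
    aggregate_to_genes,
    build_insilico_mix,
    filter_biased_snps,
    filter_variants,
    read_ase_table,
)


def snp_frame(rows):
    """rows: (contig, position, p1, p2)"""
    return pd.DataFrame(
        [
            (c, p, f"{c}_{p}", "A", "G", a, b)
            for c, p, a, b in rows
        ],
        columns=[
            "contig", "position", "variant_id", "ref_allele", "alt_allele",
            "p1_count", "p2_count",
        ],
    )


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="g">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tparent1\tparent2
"""


class TestFilterVariants:
    @pytest.mark.parametrize(
        "record,kept",
        [
            # bi-allelic SNP, parents homozygous-different, thresholds passed
            ("chr1\t100\t.\tA\tG\t99\tPASS\t.\tGT:GQ:DP\t0/0:30:12\t1/1:28:9", True),
            # GQ exactly at the threshold: strict inequality rejects
            ("chr1\t101\t.\tA\tG\t99\tPASS\t.\tGT:GQ:DP\t0/0:20:12\t1/1:28:9", False),
            # DP exactly 5 rejected
            ("chr1\t102\t.\tA\tG\t99\tPASS\t.\tGT:GQ:DP\t0/0:30:5\t1/1:28:9", False),
            # tri-allelic
            ("chr1\t103\t.\tA\tG,T\t99\tPASS\t.\tGT:GQ:DP\t0/0:30:12\t1/1:28:9", False),
            # heterozygous parent
            ("chr1\t104\t.\tA\tG\t99\tPASS\t.\tGT:GQ:DP\t0/1:30:12\t1/1:28:9", False),
            # parents identical genotype
            ("chr1\t105\t.\tA\tG\t99\tPASS\t.\tGT:GQ:DP\t1/1:30:12\t1/1:28:9", False),
            # indel
            ("chr1\t106\t.\tAT\tA\t99\tPASS\t.\tGT:GQ:DP\t0/0:30:12\t1/1:28:9", False),
            # missing GQ must not crash, just reject
            ("chr1\t107\t.\tA\tG\t99\tPASS\t.\tGT:DP\t0/0:12\t1/1:9", False),
        ],
    )
    def test_filter_rules(self, tmp_path, record, kept):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(VCF_HEADER + record + "\n")
        got = filter_variants(str(vcf))
        assert (len(got) == 1) is kept

    def test_bundle_vcf_fully_retained(self, bundle, small_dataset):
        got = filter_variants(bundle["vcf"])
        n_unique = small_dataset.snp_counts[["contig", "position"]].drop_duplicates()
        assert len(got) == len(n_unique)


class TestBiasFilter:
    @pytest.mark.parametrize(
        "p1,p2,pval,kept",
        [
            (12, 8, 0.5034, True),
            (30, 10, 0.0022, False),
            (10, 10, 1.0, True),
        ],
    )
    def test_known_pvalues(self, p1, p2, pval, kept):
        out = filter_biased_snps(snp_frame([("chr1", 1, p1, p2)]))
        assert out["p_bias"].iloc[0] == pytest.approx(pval, rel=1e-2)
        assert bool(out["retained"].iloc[0]) is kept

    def test_zero_depth_snp_removed(self):
        out = filter_biased_snps(snp_frame([("chr1", 1, 0, 0)]))
        assert not out["retained"].iloc[0]

    def test_matches_scipy_binomtest(self):
        """The vectorized balanced test equals scipy's exact two-sided test."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 80))
            k = int(rng.integers(0, n + 1))
            assert binom_test_balanced(k, n) == pytest.approx(
                stats.binomtest(k, n, 0.5).pvalue, abs=1e-12
            )


class TestInsilicoMix:
    def test_equal_libraries_elementwise_sum(self):
        a = snp_frame([("chr1", 1, 10, 0), ("chr1", 2, 5, 0)])
        b = snp_frame([("chr1", 1, 0, 8), ("chr1", 2, 0, 7)])
        mix = build_insilico_mix(a, b)
        assert mix["p1_count"].tolist() == [10, 5]
        assert mix["p2_count"].tolist() == [8, 7]

    def test_scale_mode_halves_larger_library(self):
        a = snp_frame([("chr1", 1, 10, 0), ("chr1", 2, 1999990, 0)])  # lib 2,000,000
        b = snp_frame([("chr1", 1, 0, 10), ("chr1", 2, 0, 999990)])  # lib 1,000,000
        mix = build_insilico_mix(a, b, mode="scale")
        assert mix.loc[mix["position"] == 1, "p1_count"].iloc[0] == 5

    def test_subsample_mode_deterministic_and_exact(self):
        a = snp_frame([("chr1", i, 50, 0) for i in range(1, 21)])  # lib 1000
        b = snp_frame([("chr1", i, 0, 25) for i in range(1, 21)])  # lib 500
        m1 = build_insilico_mix(a, b, mode="subsample", seed=11)
        m2 = build_insilico_mix(a, b, mode="subsample", seed=11)
        pd.testing.assert_frame_equal(m1, m2)
        # down-sampled parent contributes exactly the smaller library size
        assert (m1["p1_count"].sum() + m1["p2_count"].sum()) == 1000

    def test_zero_library_rejected(self):
        a = snp_frame([("chr1", 1, 0, 0)])
        b = snp_frame([("chr1", 1, 0, 10)])
        with pytest.raises(ValueError, match="library"):
            build_insilico_mix(a, b)


def gene_models(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestAggregate:
    def test_summation_example(self):
        f1 = snp_frame([("chr1", 10, 10, 5), ("chr1", 20, 12, 6), ("chr1", 30, 8, 4)])
        mix = snp_frame([("chr1", 10, 7, 7), ("chr1", 20, 7, 7), ("chr1", 30, 7, 7)])
        gm = gene_models([("gA", "chr1", 1, 100)])
        prof = aggregate_to_genes(f1, mix, gm, expr_bounds=None)
        assert prof.loc[0, ["f1_p1", "f1_p2"]].tolist() == [30, 15]
        assert prof.loc[0, "n_snps"] == 3

    def test_single_snp_gene_excluded(self):
        f1 = snp_frame([("chr1", 10, 30, 30)])
        mix = snp_frame([("chr1", 10, 30, 30)])
        gm = gene_models([("gA", "chr1", 1, 100)])
        assert len(aggregate_to_genes(f1, mix, gm, expr_bounds=None)) == 0

    @pytest.mark.parametrize("counts,kept", [(2, False), (30, True), (600, False)])
    def test_expression_filter_bounds(self, counts, kept):
        # per-sample gene total = 4 * counts; mean over the two samples likewise
        f1 = snp_frame([("chr1", 10, counts, counts), ("chr1", 20, counts, counts)])
        mix = snp_frame([("chr1", 10, counts, counts), ("chr1", 20, counts, counts)])
        gm = gene_models([("gA", "chr1", 1, 100)])
        prof = aggregate_to_genes(f1, mix, gm, expr_bounds=(10, 1000))
        assert (len(prof) == 1) is kept

    def test_retained_keys_restrict_snps(self):
        f1 = snp_frame([("chr1", 10, 9, 9), ("chr1", 20, 9, 9), ("chr1", 30, 9, 9)])
        mix = f1.copy()
        gm = gene_models([("gA", "chr1", 1, 100)])
        keys = pd.DataFrame({"contig": ["chr1", "chr1"], "position": [10, 20]})
        prof = aggregate_to_genes(f1, mix, gm, expr_bounds=None, retained_keys=keys)
        assert prof.loc[0, "n_snps"] == 2
        assert prof.loc[0, "f1_p1"] == 18

    def test_overlapping_genes_counted_in_both(self):
        f1 = snp_frame([("chr1", 50, 5, 5), ("chr1", 60, 5, 5)])
        mix = f1.copy()
        gm = gene_models([("gA", "chr1", 1, 100), ("gB", "chr1", 40, 140)])
        prof = aggregate_to_genes(f1, mix, gm, expr_bounds=None)
        assert set(prof["gene_id"]) == {"gA", "gB"}
        assert (prof["f1_p1"] == 10).all()

    def test_aggregation_conserves_reads(self, small_dataset, bundle):
        f1 = read_ase_table(bundle["f1"])
        mix = read_ase_table(bundle["mix_rna"])
        gm = small_dataset.gene_models.rename(columns={"chrom": "chrom"})
        prof = aggregate_to_genes(f1, mix, gm, min_snps=1, expr_bounds=None)
        assert prof["f1_p1"].sum() + prof["f1_p2"].sum() == (
            f1["p1_count"].sum() + f1["p2_count"].sum()
        )

    def test_parent_label_swap_transposes_profiles(self, small_dataset, bundle):
        f1 = read_ase_table(bundle["f1"])
        mix = read_ase_table(bundle["mix_rna"])
        gm = small_dataset.gene_models
        swapped_f1 = f1.rename(columns={"p1_count": "p2_count", "p2_count": "p1_count"})
        swapped_mix = mix.rename(columns={"p1_count": "p2_count", "p2_count": "p1_count"})
        a = aggregate_to_genes(f1, mix, gm, expr_bounds=None)
        b = aggregate_to_genes(swapped_f1, swapped_mix, gm, expr_bounds=None)
        assert (a["n_snps"].values == b["n_snps"].values).all()
        assert (a["f1_p1"].values == b["f1_p2"].values).all()
        assert (a["mix_p1"].values == b["mix_p2"].values).all()
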