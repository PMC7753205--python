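"""Read per-SNP allele counts, apply SNP/gene filters, aggregate to genes.

The counting dialect is that of GATK ASEReadCounter: one row per SNP with
``refCount``/``altCount`` columns.  Throughout the package the reference
allele is parent 1 and the alternate allele is parent 2 (reads are assigned
to a parent by genotype, with parent 1 homozygous reference).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from regdiv._stats import binom_test_balanced

logger = logging.getLogger(__name__)

SAMPLES = ("F1", "MIX_RNA", "MIX_DNA")

_ASE_COLUMNS = {
    "contig": "contig",
    "position": "position",
    "variantID": "variant_id",
    "refAllele": "ref_allele",
    "altAllele": "alt_allele",
    "refCount": "p1_count",
    "altCount": "p2_count",
}


def read_ase_table(path: str) -> pd.DataFrame:
    """Read an ASEReadCounter-dialect TSV; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ASE_COLUMNS if c not in df.columns and c != "variantID"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    keep = [c for c in _ASE_COLUMNS if c in df.columns]
    out = df[keep].rename(columns=_ASE_COLUMNS)
    if "variant_id" not in out.columns:
        out["variant_id"] = out["contig"].astype(str) + "_" + out["position"].astype(str)
    if (out["p1_count"] < 0).any() or (out["p2_count"] < 0).any():
        raise ValueError(f"{path}: negative allele counts")
    order = ["contig", "position", "variant_id", "ref_allele", "alt_allele", "p1_count", "p2_count"]
    return out[order].reset_index(drop=True)


def write_ase_table(df: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "position": df["position"],
            "variantID": df["variant_id"],
            "refAllele": df["ref_allele"],
            "altAllele": df["alt_allele"],
            "refCount": df["p1_count"],
            "altCount": df["p2_count"],
            "totalCount": df["p1_count"] + df["p2_count"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def filter_variants(vcf_path: str, min_gq: float = 20, min_dp: float = 5) -> pd.DataFrame:
    """Retain bi-allelic SNPs, homozygous-different between the two parents,
    with GQ > ``min_gq`` and DP > ``min_dp`` (strict) in both parents.

    Records with missing GQ/DP are rejected with a logged reason, not a
    crash.  Returns a frame of (contig, position, ref_allele, alt_allele).
    """
    rows = []
    rejected: dict[str, int] = {}

    def reject(reason: str) -> None:
        rejected[reason] = rejected.get(reason, 0) + 1

    with pysam.VariantFile(vcf_path) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 2:
            raise ValueError(f"{vcf_path}: expected 2 parental samples, found {len(sample_names)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                reject("not bi-allelic")
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                reject("not a SNP")
                continue
            gts = []
            ok = True
            for name in sample_names:
                call = rec.samples[name]
                gt = call.get("GT")
                gq = call.get("GQ")
                dp = call.get("DP")
                if gt is None or None in gt:
                    reject("missing genotype")
                    ok = False
                    break
                if gq is None or dp is None:
                    reject("missing GQ/DP")
                    ok = False
                    break
                if not (gq > min_gq and dp > min_dp):
                    reject("low GQ/DP")
                    ok = False
                    break
                if len(set(gt)) != 1:
                    reject("heterozygous parent")
                    ok = False
                    break
                gts.append(gt[0])
            if not ok:
                continue
            if gts[0] == gts[1]:
                reject("parents identical")
                continue
            rows.append((rec.contig, rec.pos, rec.ref, rec.alts[0]))
    if rejected:
        detail = ", ".join(f"{k}: {v}" for k, v in sorted(rejected.items()))
        logger.info("filter_variants rejected %d records (%s)", sum(rejected.values()), detail)
    return pd.DataFrame(rows, columns=["contig", "position", "ref_allele", "alt_allele"])


def filter_biased_snps(dna_counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag SNPs with parental-DNA allele counts inconsistent with 1:1.

    A SNP is removed iff the two-sided exact binomial p-value of its mixed
    DNA counts against 0.5 is below ``alpha`` (raw p-values, no FDR).  SNPs
    with zero total depth are untestable and removed.  Returns the input
    with added ``p_bias`` and boolean ``retained`` columns.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = dna_counts.copy()
    k = out["p1_count"].to_numpy(dtype=np.int64)
    n = k + out["p2_count"].to_numpy(dtype=np.int64)
    p = binom_test_balanced(k, np.maximum(n, 1))
    p = np.where(n > 0, p, np.nan)
    out["p_bias"] = p
    out["retained"] = (n > 0) & ~(p < alpha)
    n_zero = int((n == 0).sum())
    if n_zero:
        logger.info("filter_biased_snps: %d SNPs with zero DNA depth removed", n_zero)
    logger.info(
        "filter_biased_snps: removed %d / %d SNPs at alpha=%g",
        int((~out["retained"]).sum()),
        len(out),
        alpha,
    )
    return out


def build_insilico_mix(
    parent1_counts: pd.DataFrame,
    parent2_counts: pd.DataFrame,
    mode: str = "scale",
    seed: int | None = None,
) -> pd.DataFrame:
    """Combine two parental RNA count tables into a mid-parent mixture.

    Both parents contribute equal effective library size.  In ``scale`` mode
    the larger library's counts are multiplied by (smaller / larger) and
    rounded half-to-even; in ``subsample`` mode the larger library is
    down-sampled without replacement (multivariate hypergeometric) to the
    smaller library size using ``seed``.  The mixture count per SNP per
    allele is the sum of the two adjusted parental counts.
    """
    if mode not in ("scale", "subsample"):
        raise ValueError(f"unknown mode {mode!r}")
    lib1 = int(parent1_counts["p1_count"].sum() + parent1_counts["p2_count"].sum())
    lib2 = int(parent2_counts["p1_count"].sum() + parent2_counts["p2_count"].sum())
    if lib1 == 0 or lib2 == 0:
        raise ValueError("zero library size in a parental sample")

    key = ["contig", "position", "variant_id", "ref_allele", "alt_allele"]
    merged = parent1_counts.merge(
        parent2_counts, on=key, how="outer", suffixes=("_a", "_b")
    ).fillna(0)
    merged = merged.sort_values(["contig", "position"], kind="mergesort").reset_index(drop=True)
    mat = merged[["p1_count_a", "p2_count_a", "p1_count_b", "p2_count_b"]].to_numpy(np.int64)

    target = min(lib1, lib2)
    cols = slice(0, 2) if lib1 > lib2 else slice(2, 4)
    if lib1 != lib2:
        if mode == "scale":
            factor = target / max(lib1, lib2)
            mat = mat.astype(float)
            mat[:, cols] = np.rint(mat[:, cols] * factor)
            mat = mat.astype(np.int64)
        else:
            rng = np.random.default_rng(seed)
            flat = mat[:, cols].ravel()
            sampled = rng.multivariate_hypergeometric(flat, target)
            mat[:, cols] = sampled.reshape(-1, 2)

    out = merged[key].copy()
    out["p1_count"] = mat[:, 0] + mat[:, 2]
    out["p2_count"] = mat[:, 1] + mat[:, 3]
    return out


def aggregate_to_genes(
    f1_counts: pd.DataFrame,
    mix_counts: pd.DataFrame,
    gene_models: pd.DataFrame,
    min_snps: int = 2,
    expr_bounds: tuple[float, float] | None = (10.0, 1000.0),
    retained_keys: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sum per-SNP counts over each gene body and apply the gene filters.

    A SNP belongs to a gene when its position falls inside the gene's full
    genomic extent (either strand); a SNP inside overlapping genes counts
    toward each and is logged.  Genes with fewer than ``min_snps`` retained
    SNPs are dropped, as are genes whose mean total count over the F1 and
    mixture samples is <= ``expr_bounds[0]`` or >= ``expr_bounds[1]``.
    ``retained_keys`` (contig, position) restricts to SNPs that passed the
    upstream filters.
    """
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")

    def keyed(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out["snp_key"] = list(zip(out["contig"].astype(str), out["position"].astype(int)))
        return out

    f1 = keyed(f1_counts)
    mix = keyed(mix_counts)
    if retained_keys is not None:
        keys = set(zip(retained_keys["contig"].astype(str), retained_keys["position"].astype(int)))
        f1 = f1[f1["snp_key"].isin(keys)]
        mix = mix[mix["snp_key"].isin(keys)]

    trees: dict[str, IntervalTree] = {}
    for row in gene_models.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end) + 1, row.gene_id
        )

    all_keys = sorted(set(f1["snp_key"]).union(mix["snp_key"]))
    snp_genes: dict[tuple, list] = {}
    n_multi = 0
    for contig, pos in all_keys:
        tree = trees.get(contig)
        if tree is None:
            continue
        genes = sorted(iv.data for iv in tree[pos])
        if len(genes) > 1:
            n_multi += 1
        if genes:
            snp_genes[(contig, pos)] = genes
    if n_multi:
        logger.info(
            "aggregate_to_genes: %d SNPs fall in overlapping genes and count toward each",
            n_multi,
        )

    def gene_sums(df: pd.DataFrame) -> dict:
        sums: dict[str, list] = {}
        for row in df.itertuples(index=False):
            for g in snp_genes.get(row.snp_key, ()):
                acc = sums.setdefault(g, [0, 0])
                acc[0] += int(row.p1_count)
                acc[1] += int(row.p2_count)
        return sums

    f1_sums = gene_sums(f1)
    mix_sums = gene_sums(mix)
    snps_per_gene: dict[str, int] = {}
    for key, genes in snp_genes.items():
        for g in genes:
            snps_per_gene[g] = snps_per_gene.get(g, 0) + 1

    rows = []
    for g in gene_models["gene_id"]:
        n = snps_per_gene.get(g, 0)
        if n == 0:
            continue
        fp1, fp2 = f1_sums.get(g, (0, 0))
        mp1, mp2 = mix_sums.get(g, (0, 0))
        rows.append((g, n, fp1, fp2, mp1, mp2))
    profiles = pd.DataFrame(
        rows, columns=["gene_id", "n_snps", "f1_p1", "f1_p2", "mix_p1", "mix_p2"]
    )

    before = len(profiles)
    profiles = profiles[profiles["n_snps"] >= min_snps]
    logger.info(
        "aggregate_to_genes: %d genes dropped by the min-SNP filter (< %d SNPs)",
        before - len(profiles),
        min_snps,
    )
    if expr_bounds is not None:
        low, high = expr_bounds
        mean_total = (
            profiles["f1_p1"] + profiles["f1_p2"] + profiles["mix_p1"] + profiles["mix_p2"]
        ) / 2.0
        keep = (mean_total > low) & (mean_total < high)
        logger.info(
            "aggregate_to_genes: %d genes dropped by the expression filter (mean total "
            "outside (%g, %g))",
            int((~keep).sum()),
            low,
            high,
        )
        profiles = profiles[keep]
    return profiles.reset_index(drop=True)


def write_profiles(profiles: pd.DataFrame, path: str) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profiles(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
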