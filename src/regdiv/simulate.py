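"""Synthetic allele-count datasets and genome layouts with known ground truth.

Two generators live here.  ``simulate_dataset`` emits per-SNP bi-parental
allele counts for an F1 hybrid, an in-silico (mid-parent) hybrid and a mixed
parental DNA control, for genes whose cis (c) and trans (t) regulatory
effects are drawn from a configurable mixture of architectures.  The F1
parent-1 allele fraction is 2^c / (1 + 2^c); the mid-parent mix fraction is
2^(c+t) / (1 + 2^(c+t)), i.e. the trans effect is the extra log2 parental
ratio beyond what the cis effect alone explains.  ``simulate_genome_layout``
plants gene orders, homology hits, collinear blocks and Ks values such that
the duplication-mode assigner can recover the planted modes exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ARCHITECTURES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
    "conserved",
)

#: duplication modes, in assignment-priority order (highest first is wgd)
LAYOUT_MODES = ("wgd", "tandem", "proximal", "dispersed", "singleton")

_BASES = np.array(list("ACGT"))


def _default_category_mix() -> dict:
    # roughly the category frequencies seen in interspecific hybrid studies:
    # conserved dominates, trans-only outnumbers cis-only ~2:1
    return {
        "conserved": 0.55,
        "cis_only": 0.09,
        "trans_only": 0.21,
        "cis_plus_trans": 0.06,
        "cis_x_trans": 0.04,
        "compensatory": 0.05,
    }


@dataclass
class SimConfig:
    """Parameters of the allele-count generator.

    Effect-size specs (``cis_effect_log2``, ``trans_effect_log2``) give the
    magnitude of the effect in log2 units: a single float for a fixed
    magnitude or a ``(low, high)`` pair for a uniform draw; the sign is
    random.  ``snps_per_gene`` is an int or an inclusive ``(low, high)``
    integer range (minimum 1).
    """

    n_genes: int = 1000
    category_mix: dict = field(default_factory=_default_category_mix)
    cis_effect_log2: object = (0.5, 2.0)
    trans_effect_log2: object = (0.5, 2.0)
    mean_depth_f1: float = 300.0
    mean_depth_mix: float = 300.0
    nb_dispersion: float = 0.1
    snps_per_gene: object = (2, 5)
    dna_depth_per_snp: int = 30
    biased_snp_fraction: float = 0.05
    biased_snp_allele_prob: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        extra = set(self.category_mix) - set(ARCHITECTURES)
        if extra:
            raise ValueError(f"unknown categories in category_mix: {sorted(extra)}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix proportions sum to {total}, not 1")
        if any(v < 0 for v in self.category_mix.values()):
            raise ValueError("category_mix proportions must be non-negative")
        if self.mean_depth_f1 <= 0 or self.mean_depth_mix <= 0:
            raise ValueError("mean depths must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.dna_depth_per_snp <= 0:
            raise ValueError("dna_depth_per_snp must be positive")
        if not 0.0 <= self.biased_snp_fraction <= 1.0:
            raise ValueError("biased_snp_fraction must lie in [0, 1]")
        if not 0.0 < self.biased_snp_allele_prob < 1.0 or self.biased_snp_allele_prob == 0.5:
            raise ValueError("biased_snp_allele_prob must lie in (0, 1) and differ from 0.5")
        lo = _int_spec_min(self.snps_per_gene)
        if lo < 1:
            raise ValueError("snps_per_gene spec must not admit values below 1")


@dataclass
class SimDataset:
    """A simulated dataset: tidy SNP counts, per-gene truth, gene models."""

    snp_counts: pd.DataFrame
    truth: pd.DataFrame
    gene_models: pd.DataFrame
    config: SimConfig


def allele_fractions(c: float, t: float) -> tuple[float, float]:
    """Expected parent-1 allele fractions (F1, mid-parent mix) for effects c, t."""
    p_f1 = 2.0**c / (1.0 + 2.0**c)
    p_mix = 2.0 ** (c + t) / (1.0 + 2.0 ** (c + t))
    return p_f1, p_mix


def _int_spec_min(spec) -> int:
    if isinstance(spec, dict):
        if spec.get("kind") == "fixed":
            return int(spec["value"])
        return int(spec["low"])
    if isinstance(spec, (tuple, list)):
        return int(spec[0])
    return int(spec)


def _draw_magnitudes(spec, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, dict):
        if spec.get("kind") == "fixed":
            return np.full(size, float(spec["value"]))
        return rng.uniform(float(spec["low"]), float(spec["high"]), size)
    if isinstance(spec, (tuple, list)):
        return rng.uniform(float(spec[0]), float(spec[1]), size)
    return np.full(size, float(spec))


def _draw_snp_numbers(spec, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, dict):
        if spec.get("kind") == "fixed":
            return np.full(size, int(spec["value"]), dtype=int)
        return rng.integers(int(spec["low"]), int(spec["high"]) + 1, size)
    if isinstance(spec, (tuple, list)):
        return rng.integers(int(spec[0]), int(spec[1]) + 1, size)
    return np.full(size, int(spec), dtype=int)


def _allocate_counts(n: int, mix: dict) -> dict:
    """Largest-remainder allocation of n genes to categories."""
    cats = [c for c in ARCHITECTURES if mix.get(c, 0.0) > 0]
    raw = {c: n * mix[c] for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    short = n - sum(counts.values())
    for c in sorted(cats, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _effects_for_category(cat, n, cis_spec, trans_spec, rng):
    c = np.zeros(n)
    t = np.zeros(n)
    if cat == "conserved":
        return c, t
    sign_c = rng.choice([-1.0, 1.0], n)
    if cat == "cis_only":
        c = sign_c * _draw_magnitudes(cis_spec, n, rng)
    elif cat == "trans_only":
        t = rng.choice([-1.0, 1.0], n) * _draw_magnitudes(trans_spec, n, rng)
    elif cat == "cis_plus_trans":
        c = sign_c * _draw_magnitudes(cis_spec, n, rng)
        t = sign_c * _draw_magnitudes(trans_spec, n, rng)
    elif cat == "cis_x_trans":
        # the architecture is observable as opposite F1/parental ratio signs
        # only when the trans change overshoots the cis change (|t| > |c|);
        # |t| = |c| would be compensatory and |t| < |c| presents as cis+trans
        c = sign_c * _draw_magnitudes(cis_spec, n, rng)
        t = -sign_c * (np.abs(c) + _draw_magnitudes(trans_spec, n, rng))
    elif cat == "compensatory":
        c = sign_c * _draw_magnitudes(cis_spec, n, rng)
        t = -c
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(cat)
    return c, t


def _nb_total(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # NB parameterized by mean mu and dispersion phi: var = mu + phi * mu^2
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return int(rng.negative_binomial(shape, p))


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Draw a full synthetic dataset under ``config``.

    Per gene: total F1 depth is negative-binomial, parent-1 reads binomial
    with the architecture's expected fraction, and both allele totals are
    split over the gene's SNPs with equal multinomial weights.  The mixed
    parental DNA control draws binomial(dna_depth, 0.5) per SNP except for a
    configurable fraction of mapping-biased SNPs.  Each sample type has its
    own RNG stream spawned from the master seed, and within a stream genes
    are drawn sequentially, so extending a dataset does not perturb the
    counts of earlier genes.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_f1, rng_mix, rng_dna = (np.random.default_rng(s) for s in ss.spawn(4))

    counts = _allocate_counts(config.n_genes, config.category_mix)
    categories: list[str] = []
    for cat in ARCHITECTURES:
        categories.extend([cat] * counts.get(cat, 0))

    n = len(categories)
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    c_all = np.zeros(n)
    t_all = np.zeros(n)
    idx = 0
    for cat in ARCHITECTURES:
        m = counts.get(cat, 0)
        if m == 0:
            continue
        c_all[idx : idx + m], t_all[idx : idx + m] = _effects_for_category(
            cat, m, config.cis_effect_log2, config.trans_effect_log2, rng_truth
        )
        idx += m

    n_snps = _draw_snp_numbers(config.snps_per_gene, n, rng_truth)

    gene_len = 1500
    spacing = 2000
    genes_per_chrom = 100
    chroms = [f"chr{i // genes_per_chrom + 1}" for i in range(n)]
    starts = [(i % genes_per_chrom) * spacing + 1 for i in range(n)]

    snp_pos: list[np.ndarray] = []
    snp_ref: list[np.ndarray] = []
    snp_alt: list[np.ndarray] = []
    for i in range(n):
        offs = np.sort(rng_truth.choice(gene_len, size=n_snps[i], replace=False))
        snp_pos.append(starts[i] + offs)
        ref = _BASES[rng_truth.integers(0, 4, n_snps[i])]
        shift = rng_truth.integers(1, 4, n_snps[i])
        alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
        snp_ref.append(ref)
        snp_alt.append(alt)

    p_f1 = 2.0**c_all / (1.0 + 2.0**c_all)
    p_mix = 2.0 ** (c_all + t_all) / (1.0 + 2.0 ** (c_all + t_all))

    def rna_sample(rng, means, probs):
        per_gene = []
        totals = []
        for i in range(n):
            total = _nb_total(rng, means, config.nb_dispersion)
            k1 = int(rng.binomial(total, probs[i]))
            w = np.full(n_snps[i], 1.0 / n_snps[i])
            p1 = rng.multinomial(k1, w)
            p2 = rng.multinomial(total - k1, w)
            per_gene.append((p1, p2))
            totals.append(total)
        return per_gene, totals

    f1_counts, f1_totals = rna_sample(rng_f1, config.mean_depth_f1, p_f1)
    mix_counts, mix_totals = rna_sample(rng_mix, config.mean_depth_mix, p_mix)

    dna_counts = []
    for i in range(n):
        biased = rng_dna.random(n_snps[i]) < config.biased_snp_fraction
        probs = np.where(biased, config.biased_snp_allele_prob, 0.5)
        p1 = rng_dna.binomial(config.dna_depth_per_snp, probs)
        dna_counts.append((p1, config.dna_depth_per_snp - p1))

    rows = []
    for i in range(n):
        for j in range(n_snps[i]):
            key = (
                chroms[i],
                int(snp_pos[i][j]),
                f"{chroms[i]}_{snp_pos[i][j]}",
                snp_ref[i][j],
                snp_alt[i][j],
            )
            rows.append(key + (int(f1_counts[i][0][j]), int(f1_counts[i][1][j]), "F1"))
            rows.append(key + (int(mix_counts[i][0][j]), int(mix_counts[i][1][j]), "MIX_RNA"))
            rows.append(key + (int(dna_counts[i][0][j]), int(dna_counts[i][1][j]), "MIX_DNA"))

    snp_df = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "position",
            "variant_id",
            "ref_allele",
            "alt_allele",
            "p1_count",
            "p2_count",
            "sample",
        ],
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "c": c_all,
            "t": t_all,
            "true_category": categories,
            "f1_depth": f1_totals,
            "mix_depth": mix_totals,
        }
    )
    gene_models = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": starts,
            "end": [s + gene_len - 1 for s in starts],
        }
    )
    return SimDataset(snp_counts=snp_df, truth=truth, gene_models=gene_models, config=config)


# ---------------------------------------------------------------------------
# fixture-bundle writer
# ---------------------------------------------------------------------------

_ASE_HEADER = [
    "contig",
    "position",
    "variantID",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
]


def _sample_frame(snp_counts: pd.DataFrame, sample: str) -> pd.DataFrame:
    sub = snp_counts[snp_counts["sample"] == sample]
    out = pd.DataFrame(
        {
            "contig": sub["contig"],
            "position": sub["position"],
            "variantID": sub["variant_id"],
            "refAllele": sub["ref_allele"],
            "altAllele": sub["alt_allele"],
            "refCount": sub["p1_count"],
            "altCount": sub["p2_count"],
            "totalCount": sub["p1_count"] + sub["p2_count"],
        }
    )
    return out.sort_values(["contig", "position"], kind="mergesort").reset_index(drop=True)


def write_fixture_bundle(dataset: SimDataset, out_dir: str) -> dict:
    """Write a complete input bundle and return the mapping of file paths.

    Emits one ASEReadCounter-dialect TSV per sample, a VCFv4.2 of the SNPs
    with per-parent GT/GQ/DP, a GFF3 of the gene models, the truth table and
    the generating config as YAML.  Files round-trip through the readers in
    :mod:`regdiv.allele_counts`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "f1": os.path.join(out_dir, "f1.tsv"),
        "mix_rna": os.path.join(out_dir, "mix_rna.tsv"),
        "mix_dna": os.path.join(out_dir, "mix_dna.tsv"),
        "vcf": os.path.join(out_dir, "snps.vcf"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "config": os.path.join(out_dir, "sim_config.yaml"),
    }
    for sample, key in (("F1", "f1"), ("MIX_RNA", "mix_rna"), ("MIX_DNA", "mix_dna")):
        _sample_frame(dataset.snp_counts, sample).to_csv(paths[key], sep="\t", index=False)

    snps = (
        dataset.snp_counts[["contig", "position", "variant_id", "ref_allele", "alt_allele"]]
        .drop_duplicates()
        .sort_values(["contig", "position"], kind="mergesort")
    )
    contigs = sorted(dataset.gene_models["chrom"].unique()) if len(dataset.gene_models) else []
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=regdiv-simulate\n")
        for ctg in contigs:
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tparent1\tparent2\n")
        for row in snps.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.position}\t{row.variant_id}\t{row.ref_allele}\t"
                f"{row.alt_allele}\t100\tPASS\t.\tGT:GQ:DP\t0/0:60:30\t1/1:60:30\n"
            )

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in dataset.gene_models.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tregdiv_sim\tgene\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )

    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        cfg = dataclasses.asdict(dataset.config)
        cfg["category_mix"] = dict(cfg["category_mix"])
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# genome layout with planted duplication modes
# ---------------------------------------------------------------------------


def _default_mode_mix() -> dict:
    # paleopolyploid-like genome: most duplicates retained in collinear blocks
    return {
        "wgd": 0.60,
        "dispersed": 0.15,
        "singleton": 0.10,
        "tandem": 0.10,
        "proximal": 0.05,
    }


@dataclass
class GenomeLayout:
    """Planted gene order, homology and Ks fixtures with mode/age truth."""

    positions: pd.DataFrame  # gene_id, chrom, rank, start, end
    hits: pd.DataFrame  # 12-column blast tabular
    ks: pd.DataFrame  # gene1, gene2, ks
    blocks: pd.DataFrame  # block_id, gene1, gene2, ks, tier
    truth_modes: pd.DataFrame  # gene_id, mode
    truth_ages: pd.DataFrame  # gene_id, age (wgd genes only)


_KS_TIERS = ((0.08, 0.15), (0.50, 0.70), (1.20, 1.60))


def simulate_genome_layout(
    n_genes: int,
    mode_mix: dict | None = None,
    seed: int = 0,
    proximal_intervening: int = 3,
    block_size: int = 6,
    min_anchors: int = 5,
    gene_ids: list[str] | None = None,
) -> GenomeLayout:
    """Plant a genome layout whose duplication modes are known exactly.

    Each collinear block gets its own chromosome pair so planted blocks are
    detected as-is; odd-numbered blocks are antiparallel.  Tandem pairs are
    adjacent on the main chromosome; proximal pairs are separated by
    ``proximal_intervening`` hit-less genes; dispersed pairs span the main
    chromosome and a partner chromosome.  Ks values for anchor pairs are
    drawn from three well-separated tiers cycling over blocks; genes in
    tier-0 (lowest-Ks) blocks are the planted "young" WGD duplicates.
    """
    mix = dict(mode_mix) if mode_mix is not None else _default_mode_mix()
    extra = set(mix) - set(LAYOUT_MODES)
    if extra:
        raise ValueError(f"unknown modes: {sorted(extra)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mode proportions sum to {total}, not 1")
    requested = [m for m in LAYOUT_MODES if mix.get(m, 0.0) > 0]
    if n_genes < len(requested):
        raise ValueError("n_genes smaller than the number of modes requested")

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # largest-remainder allocation, then parity fixes (pair modes need even counts)
    raw = {m: n_genes * mix.get(m, 0.0) for m in LAYOUT_MODES}
    counts = {m: int(np.floor(raw[m])) for m in LAYOUT_MODES}
    short = n_genes - sum(counts.values())
    for m in sorted(LAYOUT_MODES, key=lambda m: raw[m] - counts[m], reverse=True)[:short]:
        counts[m] += 1
    for m in ("wgd", "tandem", "proximal", "dispersed"):
        if counts[m] % 2:
            counts[m] -= 1
            counts["singleton"] += 1
    if counts["wgd"] and counts["wgd"] // 2 < min_anchors:
        raise ValueError(
            f"wgd allocation of {counts['wgd']} genes cannot form a block of "
            f">= {min_anchors} anchor pairs"
        )

    n_prox_pairs = counts["proximal"] // 2
    fillers_needed = n_prox_pairs * proximal_intervening
    fillers_avail = counts["singleton"] + counts["dispersed"] // 2
    if fillers_needed > fillers_avail:
        raise ValueError(
            "not enough singleton/dispersed genes to separate proximal pairs: "
            f"need {fillers_needed}, have {fillers_avail}"
        )

    if gene_ids is not None:
        if len(gene_ids) < n_genes:
            raise ValueError("gene_ids shorter than n_genes")
        # decouple mode from whatever order the caller's ids carry
        gene_ids = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    next_id = [0]

    def new_gene() -> str:
        i = next_id[0]
        next_id[0] += 1
        return gene_ids[i] if gene_ids is not None else f"g_{i:05d}"

    truth: dict[str, str] = {}
    ages: dict[str, str] = {}
    pair_hits: list[tuple[str, str]] = []
    ks_rows: list[tuple[str, str, float]] = []
    block_rows: list[tuple[str, str, str, float, int]] = []
    chrom_orders: dict[str, list[str]] = {}

    # --- WGD blocks, one chromosome pair per block -------------------------
    wgd_pairs = counts["wgd"] // 2
    if wgd_pairs:
        n_blocks = max(1, wgd_pairs // block_size)
        while n_blocks > 1 and wgd_pairs // n_blocks < min_anchors:
            n_blocks -= 1
        sizes = [wgd_pairs // n_blocks] * n_blocks
        for i in range(wgd_pairs - sum(sizes)):
            sizes[i] += 1
        for b, size in enumerate(sizes):
            tier = b % len(_KS_TIERS)
            lo, hi = _KS_TIERS[tier]
            side_a = [new_gene() for _ in range(size)]
            side_b = [new_gene() for _ in range(size)]
            chrom_a, chrom_b = f"chrA{b:02d}", f"chrB{b:02d}"
            chrom_orders[chrom_a] = list(side_a)
            chrom_orders[chrom_b] = list(side_b) if b % 2 == 0 else list(reversed(side_b))
            for a, bb in zip(side_a, side_b):
                pair_hits.append((a, bb))
                ks = float(rng.uniform(lo, hi))
                ks_rows.append((a, bb, ks))
                block_rows.append((f"planted_{b:03d}", a, bb, ks, tier))
                truth[a] = truth[bb] = "wgd"
                age = "young" if tier == 0 else "old"
                ages[a] = ages[bb] = age

    # --- small-scale modes on the main chromosome pair ---------------------
    main: list[str] = []

    singles = [new_gene() for _ in range(counts["singleton"])]
    for g in singles:
        truth[g] = "singleton"
    disp_main, disp_part = [], []
    for _ in range(counts["dispersed"] // 2):
        a, bb = new_gene(), new_gene()
        truth[a] = truth[bb] = "dispersed"
        pair_hits.append((a, bb))
        disp_main.append(a)
        disp_part.append(bb)

    filler_pool = singles + disp_main
    used_fillers = 0

    for _ in range(counts["tandem"] // 2):
        a, bb = new_gene(), new_gene()
        truth[a] = truth[bb] = "tandem"
        pair_hits.append((a, bb))
        main.extend([a, bb])

    for _ in range(n_prox_pairs):
        a, bb = new_gene(), new_gene()
        truth[a] = truth[bb] = "proximal"
        pair_hits.append((a, bb))
        between = filler_pool[used_fillers : used_fillers + proximal_intervening]
        used_fillers += proximal_intervening
        main.extend([a, *between, bb])

    main.extend(filler_pool[used_fillers:])
    if main:
        chrom_orders["chrM"] = main
    # scatter dispersed partners over chromosomes that each hold fewer than
    # min_anchors genes, so dispersed pairs can never chain into a block
    per_chrom = max(1, min_anchors - 1)
    for i in range(0, len(disp_part), per_chrom):
        chrom_orders[f"chrP{i // per_chrom:02d}"] = disp_part[i : i + per_chrom]

    # --- assemble tables ----------------------------------------------------
    pos_rows = []
    for chrom, order in sorted(chrom_orders.items()):
        for rank, g in enumerate(order):
            start = rank * 3000 + 1
            pos_rows.append((g, chrom, rank, start, start + 1999))
    positions = pd.DataFrame(pos_rows, columns=["gene_id", "chrom", "rank", "start", "end"])
    positions = positions.sort_values(["chrom", "rank"], kind="mergesort").reset_index(drop=True)

    hit_rows = []

    def blast_row(q, s):
        return (q, s, 92.5, 310, 20, 2, 1, 310, 1, 310, 1e-80, 410.0)

    for g in positions["gene_id"]:
        hit_rows.append(blast_row(g, g))  # self-hit, as all-vs-all blastp reports
    for a, bb in pair_hits:
        hit_rows.append(blast_row(a, bb))
        hit_rows.append(blast_row(bb, a))
    hits = pd.DataFrame(
        hit_rows,
        columns=[
            "qseqid",
            "sseqid",
            "pident",
            "length",
            "mismatch",
            "gapopen",
            "qstart",
            "qend",
            "sstart",
            "send",
            "evalue",
            "bitscore",
        ],
    )

    ks = pd.DataFrame(ks_rows, columns=["gene1", "gene2", "ks"])
    blocks = pd.DataFrame(block_rows, columns=["block_id", "gene1", "gene2", "ks", "tier"])
    truth_modes = pd.DataFrame(
        sorted(truth.items()), columns=["gene_id", "mode"]
    )
    truth_ages = pd.DataFrame(sorted(ages.items()), columns=["gene_id", "age"])
    return GenomeLayout(
        positions=positions,
        hits=hits,
        ks=ks,
        blocks=blocks,
        truth_modes=truth_modes,
        truth_ages=truth_ages,
    )


def simulate_annotations(
    gene_ids,
    n_terms: int = 50,
    term_size: tuple[int, int] = (5, 30),
    seed: int = 0,
    enriched_term: str | None = None,
    enriched_genes=None,
    enriched_fraction: float = 0.8,
) -> pd.DataFrame:
    """Random gene-to-term annotations, optionally with one planted-enriched term.

    Each of ``n_terms`` terms annotates a uniform random subset of genes of
    size drawn from ``term_size``.  When ``enriched_term`` is given, that
    term draws ``enriched_fraction`` of its genes from ``enriched_genes``
    (the planted signal) and the rest at random.
    """
    gene_ids = list(gene_ids)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        size = min(size, len(gene_ids))
        for g in rng.choice(gene_ids, size=size, replace=False):
            rows.append((g, f"TERM:{i:04d}"))
    if enriched_term is not None:
        pool = list(enriched_genes)
        n_in = max(1, int(round(enriched_fraction * len(pool))))
        chosen = list(rng.choice(pool, size=min(n_in, len(pool)), replace=False))
        others = [g for g in gene_ids if g not in set(chosen)]
        n_out = max(0, int(round(len(chosen) * (1 - enriched_fraction) / enriched_fraction)))
        chosen += list(rng.choice(others, size=min(n_out, len(others)), replace=False))
        rows.extend((g, enriched_term) for g in chosen)
    df = pd.DataFrame(rows, columns=["gene_id", "term"]).drop_duplicates()
    return df.sort_values(["term", "gene_id"], kind="mergesort").reset_index(drop=True)


def write_layout_files(layout: GenomeLayout, out_dir: str) -> dict:
    """Write GFF3 / blast tabular / .collinearity / Ks files for a layout."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "gff": os.path.join(out_dir, "layout_genes.gff3"),
        "hits": os.path.join(out_dir, "blast.tsv"),
        "collinearity": os.path.join(out_dir, "blocks.collinearity"),
        "ks": os.path.join(out_dir, "ks.tsv"),
        "modes_truth": os.path.join(out_dir, "modes_truth.tsv"),
    }
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in layout.positions.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tregdiv_sim\tgene\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )
    layout.hits.to_csv(paths["hits"], sep="\t", index=False, header=False)
    with open(paths["collinearity"], "w") as fh:
        fh.write("############### regdiv synthetic collinearity ###############\n")
        for i, (block_id, grp) in enumerate(layout.blocks.groupby("block_id", sort=True)):
            fh.write(
                f"## Alignment {i}: score=1000.0 e_value=0 N={len(grp)} "
                f"{block_id} plus\n"
            )
            for j, row in enumerate(grp.itertuples(index=False)):
                fh.write(f"{i:3d}-{j:3d}:\t{row.gene1}\t{row.gene2}\t0\n")
    layout.ks.to_csv(paths["ks"], sep="\t", index=False)
    layout.truth_modes.to_csv(paths["modes_truth"], sep="\t", index=False)
    return paths
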