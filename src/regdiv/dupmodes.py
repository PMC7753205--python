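"""Gene duplication-mode assignment and Ks-based WGD age classification.

Modes follow the MCScanX convention: *singleton* genes have no non-self
homology hit; *tandem* duplicates are consecutive paralogs on a chromosome;
*proximal* duplicates are same-chromosome paralogs separated by fewer than
``proximal_max_gap`` genes; *WGD* duplicates are anchor genes of collinear
blocks; everything else with a hit is *dispersed*.  Assignment priority is
wgd > tandem > proximal > dispersed.  WGD genes are further split into
young/old duplicates by clustering collinear-block mean Ks values into
three groups and calling young the genes found only in the lowest-Ks
cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("singleton", "dispersed", "proximal", "tandem", "wgd")

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class CollinearBlock:
    """A chain of anchor pairs collinear in both genomes' rank space."""

    block_id: str
    anchor_pairs: list = field(default_factory=list)
    mean_ks: float | None = None

    def genes(self) -> set:
        out = set()
        for a, b in self.anchor_pairs:
            out.add(a)
            out.add(b)
        return out


def read_gff_genes(path: str, featuretype: str = "gene") -> pd.DataFrame:
    """Read gene features from a GFF3 and rank them by start per chromosome."""
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = [
        (f.id, f.seqid, f.start, f.end)
        for f in db.features_of_type(featuretype, order_by=("seqid", "start"))
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("chrom").cumcount()
    return df[["gene_id", "chrom", "rank", "start", "end"]]


def read_blast_hits(
    path: str, max_evalue: float = 1e-10, top_n: int | None = 5
) -> pd.DataFrame:
    """Read 12-column blast tabular output into symmetric non-self gene pairs.

    Hits are filtered to e-value <= ``max_evalue`` and, per query, the
    ``top_n`` best non-self hits by bitscore (MCScanX-style defaults).
    Returns unique unordered pairs (gene1 < gene2).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#")
    df = df[df["qseqid"] != df["sseqid"]]
    df = df[df["evalue"] <= max_evalue]
    if top_n is not None:
        df = (
            df.sort_values(["qseqid", "bitscore"], ascending=[True, False], kind="mergesort")
            .groupby("qseqid", sort=False)
            .head(top_n)
        )
    pairs = {tuple(sorted((q, s))) for q, s in zip(df["qseqid"], df["sseqid"])}
    return pd.DataFrame(sorted(pairs), columns=["gene1", "gene2"])


def detect_collinearity(
    positions: pd.DataFrame,
    hits: pd.DataFrame,
    min_anchors: int = 5,
    max_gap: int = 25,
    min_self_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain homology anchors into collinear blocks.

    Blocks are maximal chains of anchor pairs monotonically ordered in both
    genomes' rank space (parallel or antiparallel), with a per-step rank gap
    of at most ``max_gap`` on both sides, and at least ``min_anchors``
    pairs.  Same-chromosome pairs closer than ``min_self_gap`` ranks are
    local (tandem/proximal-type) duplicates and are excluded from chaining,
    mirroring how MCScanX collapses tandem arrays before block detection.
    A simplified greedy chaining, not the full MCScanX dynamic program.
    """
    loc = {r.gene_id: (r.chrom, int(r.rank)) for r in positions.itertuples(index=False)}
    unknown = [
        g for g in pd.concat([hits["gene1"], hits["gene2"]]).unique() if g not in loc
    ]
    if unknown:
        raise ValueError(f"hits reference genes without positions: {sorted(unknown)[:5]}")

    by_chrompair: dict[tuple, list] = {}
    for g1, g2 in zip(hits["gene1"], hits["gene2"]):
        c1, r1 = loc[g1]
        c2, r2 = loc[g2]
        if (c1, g1) > (c2, g2):
            g1, g2, c1, r1, c2, r2 = g2, g1, c2, r2, c1, r1
        if c1 == c2 and r1 > r2:
            r1, r2 = r2, r1
            g1, g2 = g2, g1
        if c1 == c2 and abs(r2 - r1) <= min_self_gap:
            continue  # local duplicate, not a synteny anchor
        by_chrompair.setdefault((c1, c2), []).append((r1, r2, g1, g2))

    blocks: list[CollinearBlock] = []
    n = 0
    for (c1, c2), anchors in sorted(by_chrompair.items()):
        anchors.sort()
        for orient in (1, -1):
            chains: list[list] = []
            for r1, r2, g1, g2 in anchors:
                best = None
                for chain in chains:
                    lr1, lr2 = chain[-1][0], chain[-1][1]
                    d1 = r1 - lr1
                    d2 = orient * (r2 - lr2)
                    if 1 <= d1 <= max_gap and 1 <= d2 <= max_gap:
                        if best is None or chain[-1][0] > best[-1][0]:
                            best = chain
                if best is not None:
                    best.append((r1, r2, g1, g2))
                else:
                    chains.append([(r1, r2, g1, g2)])
            for chain in chains:
                if len(chain) >= min_anchors:
                    blocks.append(
                        CollinearBlock(
                            block_id=f"block_{n:04d}",
                            anchor_pairs=[(g1, g2) for _, _, g1, g2 in chain],
                        )
                    )
                    n += 1
    return blocks


def read_collinearity_file(path: str) -> list[CollinearBlock]:
    """Read blocks from an MCScanX-style .collinearity file."""
    blocks: list[CollinearBlock] = []
    current: CollinearBlock | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## Alignment"):
                ident = line.split(":", 1)[0].replace("## Alignment", "").strip()
                current = CollinearBlock(block_id=f"block_{ident}")
                blocks.append(current)
            elif line.startswith("#") or not line.strip():
                continue
            elif current is not None:
                fields = line.replace(":", " ").split()
                genes = [f for f in fields[1:] if not _is_number(f)]
                if len(genes) >= 2:
                    current.anchor_pairs.append((genes[0], genes[1]))
    return [b for b in blocks if b.anchor_pairs]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def attach_ks(blocks: list[CollinearBlock], ks_table: pd.DataFrame) -> list[CollinearBlock]:
    """Set each block's mean Ks from per-pair Ks values (gene1, gene2, ks)."""
    ks_map = {
        frozenset((r.gene1, r.gene2)): float(r.ks) for r in ks_table.itertuples(index=False)
    }
    missing = 0
    for block in blocks:
        vals = [ks_map[frozenset(p)] for p in block.anchor_pairs if frozenset(p) in ks_map]
        if vals:
            block.mean_ks = float(np.mean(vals))
        else:
            block.mean_ks = None
            missing += 1
    if missing:
        logger.info("attach_ks: %d blocks have no Ks values", missing)
    return blocks


def assign_modes(
    positions: pd.DataFrame,
    hits: pd.DataFrame,
    blocks: list[CollinearBlock] | None = None,
    proximal_max_gap: int = 20,
) -> pd.DataFrame:
    """Assign one duplication mode per positioned gene.

    ``hits`` must be symmetric unique non-self pairs (as produced by
    :func:`read_blast_hits`).  Rank distance 1 on a chromosome is tandem;
    rank distance in [2, proximal_max_gap] is proximal ("interrupted by
    fewer than ``proximal_max_gap`` genes").  Genes appearing in a block's
    anchor pairs are wgd regardless of other relations.
    """
    loc = {r.gene_id: (r.chrom, int(r.rank)) for r in positions.itertuples(index=False)}
    for col in ("gene1", "gene2"):
        unknown = [g for g in hits[col].unique() if g not in loc]
        if unknown:
            raise ValueError(f"hit references unknown gene ids: {sorted(unknown)[:5]}")

    partners: dict[str, set] = {g: set() for g in loc}
    for g1, g2 in zip(hits["gene1"], hits["gene2"]):
        if g1 == g2:
            continue
        partners[g1].add(g2)
        partners[g2].add(g1)

    wgd_genes: set = set()
    for block in blocks or []:
        gs = block.genes()
        missing = [g for g in gs if g not in loc]
        if missing:
            raise ValueError(f"block {block.block_id} references unknown genes: {missing[:5]}")
        wgd_genes.update(gs)

    rows = []
    for g, (chrom, rank) in loc.items():
        if g in wgd_genes:
            mode = "wgd"
        elif not partners[g]:
            mode = "singleton"
        else:
            dists = [
                abs(rank - loc[p][1]) for p in partners[g] if loc[p][0] == chrom
            ]
            if any(d == 1 for d in dists):
                mode = "tandem"
            elif any(2 <= d <= proximal_max_gap for d in dists):
                mode = "proximal"
            else:
                mode = "dispersed"
        rows.append((g, mode))
    df = pd.DataFrame(rows, columns=["gene_id", "mode"])
    df["age"] = "not_applicable"
    return df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Ks age clustering
# ---------------------------------------------------------------------------


def _kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 1-D k-means via dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the exact
    solution is a contiguous-partition DP (O(n^2 k)); this removes any
    dependence on initialization or random restarts.  Returns (labels,
    centers) with clusters ordered by center.
    """
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:  # segment [i, j)
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / (j - i)

    inf = float("inf")
    cost = np.full((k + 1, n + 1), inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            for i in range(g - 1, j):
                c = cost[g - 1, i] + sse(i, j)
                if c < cost[g, j] - 1e-12:
                    cost[g, j] = c
                    split[g, j] = i
    bounds = [n]
    j = n
    for g in range(k, 0, -1):
        j = split[g, j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for g in range(k):
        lo, hi = bounds[g], bounds[g + 1]
        labels_sorted[lo:hi] = g
        centers[g] = x[lo:hi].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centers


def classify_wgd_age(
    blocks: list[CollinearBlock], k: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Split WGD genes into young/old by clustering block mean Ks (k groups).

    A gene is *young* iff every block containing it falls in the cluster
    with the smallest mean Ks; genes found in at least one older cluster
    are *old*.  With fewer than ``k`` distinct Ks values the clustering
    degenerates to grouping by distinct value (logged).  The 1-D k-means is
    solved exactly, so ``seed`` does not influence the result; it is kept
    for interface stability.
    """
    del seed  # exact 1-D solver is deterministic
    usable = [b for b in blocks if b.mean_ks is not None]
    skipped = len(blocks) - len(usable)
    if skipped:
        logger.info("classify_wgd_age: %d blocks without Ks excluded", skipped)
    if not usable:
        return pd.DataFrame(columns=["gene_id", "age"])
    values = np.array([b.mean_ks for b in usable], dtype=float)
    distinct = np.unique(values)
    if len(distinct) < k:
        logger.info(
            "classify_wgd_age: only %d distinct Ks values; grouping by value",
            len(distinct),
        )
        labels = np.searchsorted(distinct, values)
        centers = distinct
    else:
        labels, centers = _kmeans_1d(values, k)
    young_cluster = int(np.argmin(centers))

    gene_clusters: dict[str, set] = {}
    for block, lab in zip(usable, labels):
        for g in block.genes():
            gene_clusters.setdefault(g, set()).add(int(lab))
    rows = [
        (g, "young" if clusters == {young_cluster} else "old")
        for g, clusters in sorted(gene_clusters.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "age"])


def assign_modes_with_age(
    positions: pd.DataFrame,
    hits: pd.DataFrame,
    blocks: list[CollinearBlock] | None = None,
    ks_table: pd.DataFrame | None = None,
    proximal_max_gap: int = 20,
    kmeans_k: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: modes plus young/old ages when Ks is available."""
    assignments = assign_modes(positions, hits, blocks, proximal_max_gap)
    if blocks and ks_table is not None and len(ks_table):
        attach_ks(blocks, ks_table)
        ages = classify_wgd_age(blocks, k=kmeans_k, seed=seed)
        age_map = dict(zip(ages["gene_id"], ages["age"]))
        is_wgd = assignments["mode"] == "wgd"
        assignments.loc[is_wgd, "age"] = [
            age_map.get(g, "not_applicable") for g in assignments.loc[is_wgd, "gene_id"]
        ]
    return assignments


def write_assignments(assignments: pd.DataFrame, path: str) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
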