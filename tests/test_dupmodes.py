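"""Duplication-mode assignment, collinearity chaining and Ks age clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regdiv.dupmodes import (
    CollinearBlock,
    _kmeans_1d,
    assign_modes,
    assign_modes_with_age,
    attach_ks,
    classify_wgd_age,
    detect_collinearity,
    read_blast_hits,
    read_collinearity_file,
    read_gff_genes,
)


def positions_frame(rows):
    """rows: (gene_id, chrom, rank)"""
    return pd.DataFrame(
        [(g, c, r, r * 1000 + 1, r * 1000 + 500) for g, c, r in rows],
        columns=["gene_id", "chrom", "rank", "start", "end"],
    )


def hits_frame(pairs):
    return pd.DataFrame(sorted({tuple(sorted(p)) for p in pairs}), columns=["gene1", "gene2"])


class TestAssignModes:
    def test_mode_rules(self):
        pos = positions_frame(
            [("a", "c1", 0), ("b", "c1", 1), ("c", "c1", 7), ("d", "c1", 8),
             ("e", "c1", 3), ("f", "c1", 14), ("g", "c2", 0), ("h", "c2", 5),
             ("lone", "c2", 9)]
        )
        hits = hits_frame([("c", "d"), ("e", "f"), ("g", "a")])
        got = assign_modes(pos, hits).set_index("gene_id")["mode"]
        assert got["lone"] == "singleton"  # no non-self hit
        assert got["c"] == "tandem" and got["d"] == "tandem"  # consecutive ranks
        assert got["e"] == "proximal" and got["f"] == "proximal"  # 10 intervening
        assert got["g"] == "dispersed" and got["a"] == "dispersed"  # cross-chrom

    @pytest.mark.parametrize("rank2,mode", [(1, "tandem"), (11, "proximal"),
                                            (20, "proximal"), (21, "dispersed")])
    def test_rank_distance_boundaries(self, rank2, mode):
        pos = positions_frame(
            [("a", "c1", 0), ("b", "c1", rank2)]
            + [(f"f{i}", "c1", i) for i in range(1, rank2)]
        )
        got = assign_modes(pos, hits_frame([("a", "b")])).set_index("gene_id")["mode"]
        assert got["a"] == mode and got["b"] == mode

    def test_block_membership_overrides_local_modes(self):
        pos = positions_frame([("a", "c1", 0), ("b", "c1", 1)])
        block = CollinearBlock("blk", [("a", "b")])
        got = assign_modes(pos, hits_frame([("a", "b")]), [block])
        assert set(got["mode"]) == {"wgd"}

    def test_unknown_hit_gene_rejected(self):
        pos = positions_frame([("a", "c1", 0)])
        with pytest.raises(ValueError, match="unknown"):
            assign_modes(pos, hits_frame([("a", "ghost")]))

    def test_every_gene_gets_exactly_one_mode(self, layout):
        got = assign_modes(layout.positions, hits_frame(
            list(zip(layout.ks["gene1"], layout.ks["gene2"]))
        ))
        assert len(got) == len(layout.positions)
        assert got["gene_id"].is_unique


def chain_oracle(anchors, min_anchors, max_gap):
    """Enumerate all maximal valid chains by depth-first search.

    anchors: list of (rankA, rankB, gene1, gene2).  A chain step must move
    forward by 1..max_gap in rank A and by 1..max_gap in rank B (parallel)
    or backward (antiparallel).  Returns frozensets of anchor indices.
    """
    n = len(anchors)
    results = set()
    for orient in (1, -1):
        succ = {
            i: [
                j
                for j in range(n)
                if 1 <= anchors[j][0] - anchors[i][0] <= max_gap
                and 1 <= orient * (anchors[j][1] - anchors[i][1]) <= max_gap
            ]
            for i in range(n)
        }
        has_pred = {j for js in succ.values() for j in js}

        def extend(chain):
            tails = succ[chain[-1]]
            if not tails:
                if len(chain) >= min_anchors:
                    results.add(frozenset(chain))
                return
            for j in tails:
                extend(chain + [j])

        for i in range(n):
            if i not in has_pred:
                extend([i])
    # keep only inclusion-maximal chains (a chain that skips an anchor of a
    # longer valid chain is a subset of it, not a distinct block)
    return {
        s for s in results if not any(s < other for other in results)
    }


class TestDetectCollinearity:
    def test_planted_block_of_six(self):
        pos = positions_frame(
            [(f"a{i}", "c1", i * 2) for i in range(6)]
            + [(f"b{i}", "c2", i * 3) for i in range(6)]
        )
        hits = hits_frame([(f"a{i}", f"b{i}") for i in range(6)])
        blocks = detect_collinearity(pos, hits, min_anchors=5, max_gap=3)
        assert len(blocks) == 1
        assert len(blocks[0].anchor_pairs) == 6

    def test_below_min_anchors_no_block(self):
        pos = positions_frame(
            [(f"a{i}", "c1", i) for i in range(4)] + [(f"b{i}", "c2", i) for i in range(4)]
        )
        hits = hits_frame([(f"a{i}", f"b{i}") for i in range(4)])
        assert detect_collinearity(pos, hits, min_anchors=5) == []

    def test_antiparallel_block_detected(self):
        pos = positions_frame(
            [(f"a{i}", "c1", i) for i in range(6)]
            + [(f"b{i}", "c2", 5 - i) for i in range(6)]
        )
        hits = hits_frame([(f"a{i}", f"b{i}") for i in range(6)])
        blocks = detect_collinearity(pos, hits, min_anchors=5)
        assert len(blocks) == 1 and len(blocks[0].anchor_pairs) == 6

    def test_local_same_chromosome_pairs_excluded(self):
        # consecutive tandem pairs must not chain into a fake block
        pos = positions_frame([(f"t{i}", "c1", i) for i in range(12)])
        hits = hits_frame([(f"t{2 * i}", f"t{2 * i + 1}") for i in range(6)])
        assert detect_collinearity(pos, hits, min_anchors=5) == []

    def test_matches_exhaustive_oracle_on_planted_sets(self):
        """Greedy chaining agrees with DFS enumeration of maximal chains on
        small anchor sets (two interleaved blocks, gaps, one stray anchor)."""
        cases = [
            # one clean block
            [(i, i, f"a{i}", f"b{i}") for i in range(7)],
            # two blocks far apart in rank B
            [(i, i, f"a{i}", f"b{i}") for i in range(5)]
            + [(i + 40, i + 100, f"c{i}", f"d{i}") for i in range(5)],
            # block with internal gaps of 2-3 plus a stray anchor
            [(0, 0, "a0", "b0"), (2, 3, "a1", "b1"), (5, 5, "a2", "b2"),
             (7, 8, "a3", "b3"), (9, 9, "a4", "b4"), (60, 2, "s", "t")],
        ]
        for anchors in cases:
            pos_rows = [(g1, "cA", r1) for r1, _, g1, _ in anchors] + [
                (g2, "cB", r2) for _, r2, _, g2 in anchors
            ]
            pos = positions_frame(pos_rows)
            hits = hits_frame([(g1, g2) for _, _, g1, g2 in anchors])
            got = {
                frozenset(b.anchor_pairs)
                for b in detect_collinearity(pos, hits, min_anchors=5, max_gap=3)
            }
            want = {
                frozenset((anchors[i][2], anchors[i][3]) for i in idxs)
                for idxs in chain_oracle(anchors, min_anchors=5, max_gap=3)
            }
            assert got == want


class TestCollinearityFile:
    def test_round_trip_with_layout_writer(self, layout, layout_files):
        blocks = read_collinearity_file(layout_files["collinearity"])
        got_pairs = {frozenset(p) for b in blocks for p in b.anchor_pairs}
        want_pairs = {
            frozenset((g1, g2)) for g1, g2 in zip(layout.blocks["gene1"], layout.blocks["gene2"])
        }
        assert got_pairs == want_pairs


class TestBlastReader:
    def test_self_hits_and_evalue_filter(self, tmp_path):
        rows = [
            "g1\tg1\t100\t300\t0\t0\t1\t300\t1\t300\t0.0\t600",  # self
            "g1\tg2\t90\t300\t10\t0\t1\t300\t1\t300\t1e-50\t400",
            "g2\tg1\t90\t300\t10\t0\t1\t300\t1\t300\t1e-50\t400",
            "g1\tg3\t40\t100\t50\t5\t1\t100\t1\t100\t1e-3\t50",  # weak
        ]
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(rows) + "\n")
        got = read_blast_hits(str(path))
        assert got.values.tolist() == [["g1", "g2"]]


class TestKsAge:
    def make_blocks(self, means):
        return [
            CollinearBlock(f"b{i}", [(f"x{i}", f"y{i}")], mean_ks=m)
            for i, m in enumerate(means)
        ]

    def test_well_separated_groups(self):
        means = [0.10, 0.12, 0.11, 0.60, 0.62, 1.5, 1.4]
        ages = classify_wgd_age(self.make_blocks(means)).set_index("gene_id")["age"]
        for i, m in enumerate(means):
            want = "young" if m < 0.2 else "old"
            assert ages[f"x{i}"] == want

    def test_gene_in_young_and_old_block_is_old(self):
        blocks = self.make_blocks([0.11, 0.12, 0.13, 1.4, 1.5, 0.6])
        blocks[3].anchor_pairs.append(("x0", "z9"))  # x0 also in a 1.4 block
        ages = classify_wgd_age(blocks).set_index("gene_id")["age"]
        assert ages["x0"] == "old"
        assert ages["y0"] == "young"

    def test_identical_ks_degenerates_to_one_cluster(self):
        ages = classify_wgd_age(self.make_blocks([0.5] * 6))
        assert set(ages["age"]) == {"young"}

    def test_attach_ks_averages_pairs(self):
        block = CollinearBlock("b", [("a", "b"), ("c", "d")])
        ks = pd.DataFrame({"gene1": ["a", "d"], "gene2": ["b", "c"], "ks": [0.2, 0.4]})
        attach_ks([block], ks)
        assert block.mean_ks == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_kmeans_matches_exhaustive_partition_search(self, seed):
        """The 1-D 3-means solution equals the best contiguous 3-partition
        found by brute force over all boundary pairs (optimal 1-D clusters
        are contiguous in sorted order)."""
        rng = np.random.default_rng(seed)
        values = np.sort(rng.uniform(0, 2, size=int(rng.integers(6, 30))))

        def sse(seg):
            return ((seg - seg.mean()) ** 2).sum() if len(seg) else 0.0

        best = min(
            (
                sse(values[:i]) + sse(values[i:j]) + sse(values[j:])
                for i, j in itertools.combinations(range(1, len(values)), 2)
            )
        )
        labels, centers = _kmeans_1d(values, 3)
        got = sum(
            sse(values[labels == g]) for g in range(3)
        )
        assert got == pytest.approx(best, abs=1e-9)


class TestPlantedLayoutClosedLoop:
    def test_modes_and_ages_recovered_exactly(self, layout, layout_files):
        positions = read_gff_genes(layout_files["gff"])
        hits = read_blast_hits(layout_files["hits"])
        blocks = detect_collinearity(positions, hits)
        ks = pd.read_csv(layout_files["ks"], sep="\t")
        got = assign_modes_with_age(positions, hits, blocks, ks)
        modes = got.merge(layout.truth_modes, on="gene_id", suffixes=("_got", "_true"))
        assert (modes["mode_got"] == modes["mode_true"]).all()
        ages = got.merge(layout.truth_ages, on="gene_id", suffixes=("_got", "_true"))
        assert (ages["age_got"] == ages["age_true"]).all()

    def test_adding_blocks_only_moves_genes_into_wgd(self, layout):
        hits = hits_frame(list(zip(layout.ks["gene1"], layout.ks["gene2"])))
        without = assign_modes(layout.positions, hits, blocks=None)
        blocks = [
            CollinearBlock(bid, list(zip(grp["gene1"], grp["gene2"])))
            for bid, grp in layout.blocks.groupby("block_id")
        ]
        with_blocks = assign_modes(layout.positions, hits, blocks=blocks)
        merged = without.merge(with_blocks, on="gene_id", suffixes=("_a", "_b"))
        changed = merged[merged["mode_a"] != merged["mode_b"]]
        assert (changed["mode_b"] == "wgd").all()
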