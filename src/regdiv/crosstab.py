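"""Cross-tabulation of regulatory categories by duplication mode.

Produces the mode x category count table with row-normalized percentages,
plus the two chi-squared constructions used to compare cis-only and
trans-only prevalence: a 1-df goodness-of-fit of (cis, trans) counts
against 1:1 within a mode, and a 2x2 test of a mode's cis-only rate against
the rest of the genome.  A differential-expression summary tabulator
reports DEG counts and percentages per pairwise comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from regdiv._stats import round_half_up
from regdiv.classify import CATEGORIES
from regdiv.dupmodes import MODES

logger = logging.getLogger(__name__)


@dataclass
class CrossTable:
    """Counts and row percentages of genes per (duplication mode, category)."""

    counts: pd.DataFrame
    proportions: pd.DataFrame


def crosstab(calls: pd.DataFrame, assignments: pd.DataFrame) -> CrossTable:
    """Count classified genes per mode and category, with a Total row.

    Every gene in ``calls`` must have a duplication assignment; proportions
    are row-normalized percentages rounded half-up to 2 decimals.
    """
    mode_map = dict(zip(assignments["gene_id"], assignments["mode"]))
    missing = [g for g in calls["gene_id"] if g not in mode_map]
    if missing:
        raise ValueError(
            f"{len(missing)} classified genes lack a duplication assignment, "
            f"e.g. {sorted(missing)[:5]}"
        )
    df = pd.DataFrame(
        {
            "mode": [mode_map[g] for g in calls["gene_id"]],
            "category": calls["category"],
        }
    )
    counts = (
        pd.crosstab(df["mode"], df["category"])
        .reindex(index=list(MODES), columns=list(CATEGORIES), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    counts.loc["Total"] = counts.sum(axis=0)
    counts.index.name = "mode"
    counts.columns.name = "category"
    proportions = proportions_from_counts(counts)
    return CrossTable(counts=counts, proportions=proportions)


def proportions_from_counts(counts: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Row-normalized percentages of a count table, rounded half-up."""
    rowsums = counts.sum(axis=1)
    pct = counts.div(rowsums.replace(0, np.nan), axis=0) * 100.0
    return pct.map(lambda v: np.nan if pd.isna(v) else round_half_up(v, ndigits))


def cis_vs_trans_test(counts_cis: int, counts_trans: int):
    """1-df goodness-of-fit chi-squared of (cis, trans) counts against 1:1.

    No continuity correction.  Returns (statistic, p-value); both NaN when
    the two counts are zero (logged).
    """
    if counts_cis < 0 or counts_trans < 0:
        raise ValueError("counts must be non-negative")
    if counts_cis + counts_trans == 0:
        logger.info("cis_vs_trans_test: both counts zero, test undefined")
        return float("nan"), float("nan")
    stat, p = stats.chisquare([counts_cis, counts_trans])
    return float(stat), float(p)


def mode_vs_genome_test(mode_cis: int, mode_total: int, genome_cis: int, genome_total: int):
    """2x2 chi-squared of a mode's cis-only rate vs the rest of the genome.

    The comparison group is the genome minus the mode's genes; no
    continuity correction.  Degenerate margins return NaN (logged).
    """
    if not (0 <= mode_cis <= mode_total and 0 <= genome_cis <= genome_total):
        raise ValueError("require 0 <= cis <= total for mode and genome")
    if mode_total > genome_total or mode_cis > genome_cis:
        raise ValueError("mode counts cannot exceed genome counts")
    rest_cis = genome_cis - mode_cis
    rest_total = genome_total - mode_total
    table = np.array(
        [
            [mode_cis, mode_total - mode_cis],
            [rest_cis, rest_total - rest_cis],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.info("mode_vs_genome_test: degenerate margin, test undefined")
        return float("nan"), float("nan")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def mode_tests(table: CrossTable) -> pd.DataFrame:
    """Run both chi-squared constructions for every duplication mode."""
    counts = table.counts
    genome_cis = int(counts.loc["Total", "cis_only"])
    genome_total = int(counts.loc["Total"].sum())
    rows = []
    for mode in MODES:
        if mode not in counts.index:
            continue
        cis = int(counts.loc[mode, "cis_only"])
        trans = int(counts.loc[mode, "trans_only"])
        mode_total = int(counts.loc[mode].sum())
        stat1, p1 = cis_vs_trans_test(cis, trans)
        rows.append((mode, "cis_vs_trans_1to1", stat1, p1))
        stat2, p2 = mode_vs_genome_test(cis, mode_total, genome_cis, genome_total)
        rows.append((mode, "cis_rate_vs_genome", stat2, p2))
    return pd.DataFrame(rows, columns=["mode", "test", "statistic", "p_value"])


def deg_summary(deg_sets: dict, n_expressed: int) -> pd.DataFrame:
    """Tabulate DEG counts per comparison with percentages of expressed genes.

    ``deg_sets`` maps a comparison label to ``{"up": int|set, "down":
    int|set}`` (an optional ``"total"`` is checked against up + down).
    Percentages are reported to 1 decimal, half-up.
    """
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    rows = []
    for name, entry in deg_sets.items():
        up = entry["up"] if isinstance(entry["up"], int) else len(entry["up"])
        down = entry["down"] if isinstance(entry["down"], int) else len(entry["down"])
        total = entry.get("total", up + down)
        if up + down != total:
            raise ValueError(f"{name}: up ({up}) + down ({down}) != total ({total})")
        rows.append(
            (
                name,
                total,
                round_half_up(100.0 * total / n_expressed, 1),
                up,
                round_half_up(100.0 * up / n_expressed, 1),
                down,
                round_half_up(100.0 * down / n_expressed, 1),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["comparison", "degs", "degs_pct", "up", "up_pct", "down", "down_pct"],
    )


def write_crosstab(table: CrossTable, counts_path: str, pct_path: str) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.proportions.to_csv(pct_path, sep="\t")
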