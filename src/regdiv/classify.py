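"""Seven-way cis/trans regulatory-divergence classification.

Three exact tests are run per gene: the allelic ratio in the in-silico
(mid-parent) hybrid against 1:1 (the P comparison, evidence of parental
divergence), the allelic ratio in the F1 hybrid against 1:1 (the H
comparison, evidence of cis divergence), and the F1 vs mid-parent 2x2 table
by Fisher's exact test (the T comparison, evidence of trans divergence).
Significance is assessed on Benjamini-Hochberg adjusted p-values, applied
separately within each comparison across all tested genes, and the
significance pattern plus the agreement of the two log2 allelic-ratio signs
determines the category:

==========  =====  =====  =====  ===================
category    sig P  sig H  sig T  log2-ratio signs
==========  =====  =====  =====  ===================
cis_only      *      *           --
trans_only    *             *    --
cis+trans     *      *      *    same
cis*trans     *      *      *    opposite
compensat.           *      *    --
conserved                        --
ambiguous   (every other pattern)
==========  =====  =====  =====  ===================
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from regdiv._stats import bh_adjust, binom_test_balanced

logger = logging.getLogger(__name__)

CATEGORIES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)

PSEUDOCOUNT = 0.5


def test_comparisons(profiles: pd.DataFrame) -> pd.DataFrame:
    """Compute raw P/H/T p-values and log2 allelic ratios per gene.

    p_P and p_H are two-sided exact binomial tests (minimum-likelihood
    rule) of the mixture and F1 allele counts against 0.5; p_T is the
    two-sided Fisher exact test on [[f1_p1, f1_p2], [mix_p1, mix_p2]].
    A gene with a zero row total in either sample gets the affected
    p-values set to 1 and is flagged ``forced_ambiguous``.
    """
    out = profiles.copy().reset_index(drop=True)
    f1_tot = (out["f1_p1"] + out["f1_p2"]).to_numpy(np.int64)
    mix_tot = (out["mix_p1"] + out["mix_p2"]).to_numpy(np.int64)

    p_h = binom_test_balanced(out["f1_p1"].to_numpy(np.int64), np.maximum(f1_tot, 1))
    p_p = binom_test_balanced(out["mix_p1"].to_numpy(np.int64), np.maximum(mix_tot, 1))
    p_h = np.where(f1_tot > 0, p_h, 1.0)
    p_p = np.where(mix_tot > 0, p_p, 1.0)

    p_t = np.ones(len(out))
    testable = (f1_tot > 0) & (mix_tot > 0)
    for i in np.flatnonzero(testable):
        table = [
            [int(out.at[i, "f1_p1"]), int(out.at[i, "f1_p2"])],
            [int(out.at[i, "mix_p1"]), int(out.at[i, "mix_p2"])],
        ]
        p_t[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    forced = ~testable
    if forced.any():
        logger.info(
            "test_comparisons: %d genes with a zero sample total routed to ambiguous",
            int(forced.sum()),
        )

    out["p_P"] = p_p
    out["p_H"] = p_h
    out["p_T"] = p_t
    out["log2_ratio_f1"] = np.log2(
        (out["f1_p1"] + PSEUDOCOUNT) / (out["f1_p2"] + PSEUDOCOUNT)
    )
    out["log2_ratio_mix"] = np.log2(
        (out["mix_p1"] + PSEUDOCOUNT) / (out["mix_p2"] + PSEUDOCOUNT)
    )
    out["forced_ambiguous"] = forced
    return out


def adjust_fdr(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; empty input yields empty output."""
    if method != "fdr_bh":
        raise ValueError("only Benjamini-Hochberg ('fdr_bh') adjustment is supported")
    return bh_adjust(pvalues)


def classify_gene(sig_p: bool, sig_h: bool, sig_t: bool, same_sign: bool) -> str:
    """Map one significance pattern (and sign agreement) to a category.

    Total function over all 8 significance patterns x 2 sign states; the
    sign only matters when all three comparisons are significant.
    """
    if sig_p and sig_h and not sig_t:
        return "cis_only"
    if sig_p and not sig_h and sig_t:
        return "trans_only"
    if sig_p and sig_h and sig_t:
        return "cis_plus_trans" if same_sign else "cis_x_trans"
    if not sig_p and sig_h and sig_t:
        return "compensatory"
    if not sig_p and not sig_h and not sig_t:
        return "conserved"
    return "ambiguous"


def classify_all(profiles: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Test, adjust and classify every gene; returns the calls table.

    BH adjustment is applied separately within each of the P, H and T
    comparisons across all tested genes.  Raises on duplicate gene ids.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if profiles["gene_id"].duplicated().any():
        dups = profiles.loc[profiles["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if len(profiles) == 0:
        cols = list(profiles.columns) + [
            "p_P", "p_H", "p_T", "q_P", "q_H", "q_T",
            "log2_ratio_f1", "log2_ratio_mix", "forced_ambiguous", "category",
        ]
        return pd.DataFrame(columns=cols)

    res = test_comparisons(profiles)
    res["q_P"] = adjust_fdr(res["p_P"])
    res["q_H"] = adjust_fdr(res["p_H"])
    res["q_T"] = adjust_fdr(res["p_T"])

    sig_p = res["q_P"] < alpha
    sig_h = res["q_H"] < alpha
    sig_t = res["q_T"] < alpha
    prod = res["log2_ratio_f1"] * res["log2_ratio_mix"]
    same_sign = prod >= 0  # an exactly-zero ratio counts as agreement
    n_zero = int(((prod == 0) & sig_p & sig_h & sig_t).sum())
    if n_zero:
        logger.info(
            "classify_all: %d fully significant genes with a zero log2 ratio "
            "treated as sign agreement",
            n_zero,
        )

    cats = [
        classify_gene(bool(p), bool(h), bool(t), bool(s))
        for p, h, t, s in zip(sig_p, sig_h, sig_t, same_sign)
    ]
    res["category"] = cats
    res.loc[res["forced_ambiguous"], "category"] = "ambiguous"
    return res


def category_counts(calls: pd.DataFrame) -> pd.Series:
    """Summary counts per category, in canonical order."""
    return calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)


def write_calls(calls: pd.DataFrame, path: str) -> None:
    cols = [
        "gene_id", "f1_p1", "f1_p2", "mix_p1", "mix_p2",
        "p_P", "p_H", "p_T", "q_P", "q_H", "q_T",
        "log2_ratio_f1", "log2_ratio_mix", "category",
    ]
    calls[cols].to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
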