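"""Shared test utilities (not fixtures)."""

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

# the seven-way rule table written out exhaustively, independent of the
# implementation: (sig_P, sig_H, sig_T, same_sign) -> category
RULE_TABLE = {
    (True, True, False, True): "cis_only",
    (True, True, False, False): "cis_only",
    (True, False, True, True): "trans_only",
    (True, False, True, False): "trans_only",
    (True, True, True, True): "cis_plus_trans",
    (True, True, True, False): "cis_x_trans",
    (False, True, True, True): "compensatory",
    (False, True, True, False): "compensatory",
    (False, False, False, True): "conserved",
    (False, False, False, False): "conserved",
    (False, False, True, True): "ambiguous",
    (False, False, True, False): "ambiguous",
    (False, True, False, True): "ambiguous",
    (False, True, False, False): "ambiguous",
    (True, False, False, True): "ambiguous",
    (True, False, False, False): "ambiguous",
}


def bh_manual(p):
    """Textbook Benjamini-Hochberg step-up, independent of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bruteforce_categories(rows, alpha=0.05):
    """Reclassify count tables from scratch with scipy tests, manual BH and
    the enumerated rule table; rows: (gene_id, f1_p1, f1_p2, mix_p1, mix_p2).
    Returns {gene_id: category}.
    """
    raw = []
    for g, f1a, f1b, mxa, mxb in rows:
        p_h = stats.binomtest(f1a, f1a + f1b, 0.5).pvalue if f1a + f1b else 1.0
        p_p = stats.binomtest(mxa, mxa + mxb, 0.5).pvalue if mxa + mxb else 1.0
        p_t = (
            stats.fisher_exact([[f1a, f1b], [mxa, mxb]])[1]
            if (f1a + f1b) and (mxa + mxb)
            else 1.0
        )
        raw.append((g, f1a, f1b, mxa, mxb, p_p, p_h, p_t))
    q_p = bh_manual([r[5] for r in raw])
    q_h = bh_manual([r[6] for r in raw])
    q_t = bh_manual([r[7] for r in raw])
    out = {}
    for (g, f1a, f1b, mxa, mxb, *_), qp, qh, qt in zip(raw, q_p, q_h, q_t):
        if (f1a + f1b) == 0 or (mxa + mxb) == 0:
            out[g] = "ambiguous"
            continue
        l2f = np.log2((f1a + 0.5) / (f1b + 0.5))
        l2m = np.log2((mxa + 0.5) / (mxb + 0.5))
        out[g] = RULE_TABLE[(qp < alpha, qh < alpha, qt < alpha, l2f * l2m >= 0)]
    return out


def profiles_from_dataset(dataset) -> pd.DataFrame:
    """Gene-level profiles summed directly from the tidy SNP counts.

    Bypasses the file round trip and the expression filters; used when a
    test needs every simulated gene classified.
    """
    snp = dataset.snp_counts.copy()
    trees = {}
    for r in dataset.gene_models.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r.gene_id)
    snp["gene_id"] = [
        next(iter(trees[c][p])).data for c, p in zip(snp["contig"], snp["position"])
    ]
    f1 = snp[snp["sample"] == "F1"].groupby("gene_id")[["p1_count", "p2_count"]].sum()
    mx = snp[snp["sample"] == "MIX_RNA"].groupby("gene_id")[["p1_count", "p2_count"]].sum()
    nsnp = snp[snp["sample"] == "F1"].groupby("gene_id").size().reindex(f1.index)
    return pd.DataFrame(
        {
            "gene_id": f1.index,
            "n_snps": nsnp.values,
            "f1_p1": f1["p1_count"].values,
            "f1_p2": f1["p2_count"].values,
            "mix_p1": mx["p1_count"].reindex(f1.index).values,
            "mix_p2": mx["p2_count"].reindex(f1.index).values,
        }
    ).reset_index(drop=True)
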