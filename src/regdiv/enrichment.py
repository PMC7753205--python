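"""One-tailed hypergeometric over-representation of GO/Pfam-style terms.

The universe is the set of expressed genes; terms annotating fewer than
``min_term_size`` universe genes are dropped before testing; the upper-tail
hypergeometric p-value P(X >= k) is adjusted by Benjamini-Hochberg across
the retained terms of one annotation source.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from regdiv._stats import bh_adjust

logger = logging.getLogger(__name__)


def _as_annotation_frame(annotations) -> pd.DataFrame:
    if isinstance(annotations, pd.DataFrame):
        df = annotations.iloc[:, :2].copy()
        df.columns = ["gene_id", "term"]
        return df
    rows = [(g, t) for g, terms in annotations.items() for t in terms]
    return pd.DataFrame(rows, columns=["gene_id", "term"])


def enrich(
    query_set,
    annotations,
    universe,
    min_term_size: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each term for over-representation in ``query_set``.

    ``annotations`` is a two-column frame (gene_id, term) or a mapping
    gene -> iterable of terms; annotations of genes outside the universe
    are ignored (logged).  Returns one row per retained term with k
    (query-term overlap), K (term size in the universe), n (query size), N
    (universe size), the raw upper-tail p and BH-adjusted q, sorted by q.
    """
    universe = set(universe)
    query = set(query_set)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    outside = query - universe
    if outside:
        raise ValueError(
            f"{len(outside)} query genes absent from the universe, "
            f"e.g. {sorted(outside)[:5]}"
        )

    ann = _as_annotation_frame(annotations).drop_duplicates()
    in_universe = ann["gene_id"].isin(universe)
    n_dropped = int((~in_universe).sum())
    if n_dropped:
        logger.info("enrich: %d annotations of genes outside the universe ignored", n_dropped)
    ann = ann[in_universe]

    term_genes = ann.groupby("term")["gene_id"].agg(set)
    sizes = term_genes.map(len)
    small = sizes < min_term_size
    if small.any():
        logger.info(
            "enrich: %d terms with fewer than %d universe genes removed",
            int(small.sum()),
            min_term_size,
        )
    term_genes = term_genes[~small]
    if term_genes.empty:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q", "significant"])

    big_n = len(universe)
    n = len(query)
    terms = list(term_genes.index)
    big_k = np.array([len(term_genes[t]) for t in terms])
    k = np.array([len(term_genes[t] & query) for t in terms])
    p = stats.hypergeom.sf(k - 1, big_n, big_k, n)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "term": terms,
            "k": k,
            "K": big_k,
            "n": n,
            "N": big_n,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )
    return out.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)


def compare_term_overlap(rows_a: pd.DataFrame, rows_b: pd.DataFrame) -> pd.DataFrame:
    """Intersect the significant terms of two enrichment results.

    Both results must come from the same universe (checked via N).  Returns
    the shared significant terms with both q-values.
    """
    if len(rows_a) and len(rows_b):
        if int(rows_a["N"].iloc[0]) != int(rows_b["N"].iloc[0]):
            raise ValueError("enrichment results come from different universes")
    sig_a = rows_a[rows_a["significant"]].set_index("term")["q"]
    sig_b = rows_b[rows_b["significant"]].set_index("term")["q"]
    shared = sorted(set(sig_a.index) & set(sig_b.index))
    return pd.DataFrame(
        {
            "term": shared,
            "q_a": [sig_a[t] for t in shared],
            "q_b": [sig_b[t] for t in shared],
        }
    )


def read_annotations(path: str) -> pd.DataFrame:
    """Read a 2-column gene-to-term TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"], comment="#")
    if df["gene_id"].iloc[0:1].isin(["gene_id", "gene"]).any():
        df = df.iloc[1:].reset_index(drop=True)
    return df


def read_gene_set(path: str) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
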