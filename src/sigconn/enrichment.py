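"""Gene-set over-representation analysis.

One-sided (upper-tail) hypergeometric test per gene set against an
explicit background universe, with the conservative EASE variant (overlap
count decremented by one before the tail sum) and optional
Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .differential import DEGSet
from .errors import ParameterError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, N: int, s: int, q: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, s, q).

    N = universe size, s = set size, q = query size, k = overlap.
    """
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, s, q))


def ora(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    ease: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Over-representation of each gene set in the query.

    Query genes outside the universe are dropped (logged); each set is
    intersected with the universe before testing. EASE mode replaces the
    overlap k with max(k-1, 0) before the upper-tail sum. Rows come back
    sorted by ascending p-value (ties by set id).

    Returns a DataFrame with columns set_id, description, overlap_count,
    query_size, set_size, universe_size, p_value, adjusted_p,
    overlap_genes.
    """
    uni = set(universe)
    if not uni:
        raise ParameterError("universe must be non-empty")
    q_genes = [g for g in dict.fromkeys(query) if g in uni]
    n_dropped = len(set(query)) - len(q_genes)
    if n_dropped:
        logger.info("ora: %d query genes outside the universe dropped", n_dropped)
    if not q_genes:
        raise ParameterError("query is empty after intersecting with the universe")
    N = len(uni)
    qn = len(q_genes)
    qset = set(q_genes)

    rows = []
    for set_id, members in sets.sets.items():
        in_uni = [g for g in members if g in uni]
        overlap = sorted(qset.intersection(in_uni))
        k, s = len(overlap), len(in_uni)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_tail(k_eff, N, s, qn)
        rows.append(
            {
                "set_id": set_id,
                "description": sets.descriptions.get(set_id, ""),
                "overlap_count": k,
                "query_size": qn,
                "set_size": s,
                "universe_size": N,
                "p_value": p,
                "adjusted_p": float("nan"),
                "overlap_genes": ",".join(overlap),
            }
        )
    frame = pd.DataFrame(rows)
    if bh and len(frame):
        frame["adjusted_p"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    return frame.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)


def merge_gene_sets(degsets: list[DEGSet], direction: str) -> list[str]:
    """Deduplicated union of one direction's DEGs across cell lines.

    Order: first appearance across the input sets.
    """
    if not degsets:
        raise ParameterError("need >= 1 DEG set to merge")
    merged: dict[str, None] = {}
    for s in degsets:
        for g in s.genes(direction):
            merged[g] = None
    return list(merged)
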