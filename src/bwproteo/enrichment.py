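"""Over-representation analysis (ORA) of a protein hit list.

Each gene set is tested by the upper tail of the hypergeometric
distribution: with N background proteins, K of them in the set, and n
hits, the p-value is P(X >= k) for the observed overlap k. p-values are
adjusted by Benjamini–Hochberg across all tested sets; retained terms need
at least ``min_overlap`` overlapping proteins and q below ``q_cut``
(defaults 3 and 0.2). Redundant terms are reduced by a greedy Jaccard
filter and organised by average-linkage hierarchical clustering on
1 − Jaccard distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diff import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "hypergeometric_p",
    "run_ora",
    "simplify_terms",
    "cluster_terms",
    "jaccard",
    "linkage_to_newick",
]


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    k overlap, K set size in background, n hit-list size, N background size.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def run_ora(
    hits,
    background,
    collection: GeneSetCollection,
    min_overlap: int = 3,
    q_cut: float = 0.2,
) -> pd.DataFrame:
    """Test every gene set with >= 1 background member against the hit list.

    Returns the retained rows (overlap >= min_overlap and q < q_cut),
    sorted by (q, p, set id). The full multiplicity correction runs across
    all tested sets before filtering.
    """
    hits = set(hits)
    background = set(background)
    if not hits:
        warnings.warn("empty hit list; returning empty enrichment table")
        return _empty_table()
    outside = hits - background
    if outside:
        raise ValueError(f"hits outside background: {sorted(outside)[:5]}")
    N = len(background)
    n = len(hits)
    rows = []
    for set_id in collection.ids():
        members = collection[set_id] & background
        if not members:
            continue
        overlap = members & hits
        k, K = len(overlap), len(members)
        rows.append(
            {
                "set_id": set_id,
                "description": collection.descriptions.get(set_id, ""),
                "overlap": k,
                "set_size": K,
                "n_hits": n,
                "n_background": N,
                "p": hypergeometric_p(k, K, n, N),
                "genes": ",".join(sorted(overlap)),
            }
        )
    if not rows:
        return _empty_table()
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table[(table["overlap"] >= min_overlap) & (table["q"] < q_cut)]
    return table.sort_values(["q", "p", "set_id"], kind="stable").reset_index(drop=True)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "set_id", "description", "overlap", "set_size", "n_hits",
            "n_background", "p", "genes", "q",
        ]
    )


def _member_sets(table: pd.DataFrame) -> list[set[str]]:
    return [set(g.split(",")) if g else set() for g in table["genes"]]


def simplify_terms(table: pd.DataFrame, jaccard_cutoff: float = 0.7) -> pd.DataFrame:
    """Greedy redundancy filter: scan rows by ascending p (set id breaks
    ties); keep a row iff its overlap-gene Jaccard similarity with every
    already-kept row is below the cutoff.

    A set-similarity analogue of ontology "simplify" steps; it never drops
    the global minimum-p row.
    """
    if len(table) == 0:
        return table.copy()
    ordered = table.sort_values(["p", "set_id"], kind="stable")
    members = dict(zip(ordered["set_id"], _member_sets(ordered)))
    kept: list[str] = []
    for set_id in ordered["set_id"]:
        if all(jaccard(members[set_id], members[other]) < jaccard_cutoff for other in kept):
            kept.append(set_id)
    out = ordered[ordered["set_id"].isin(kept)]
    return out.reset_index(drop=True)


def cluster_terms(table: pd.DataFrame, cut_height: float = 0.8):
    """Average-linkage clustering of retained terms on 1 − Jaccard distance.

    Returns (labels, linkage matrix); single-row tables get the trivial
    single cluster and an empty tree.
    """
    if len(table) == 0:
        raise ValueError("cannot cluster an empty enrichment table")
    ids = list(table["set_id"])
    if len(ids) == 1:
        return pd.Series([1], index=ids, name="cluster"), np.empty((0, 4))
    members = _member_sets(table)
    m = len(ids)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = 1.0 - jaccard(members[i], members[j])
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    return pd.Series(labels, index=ids, name="cluster"), link


def linkage_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    if len(link) == 0:
        if len(leaf_names) == 1:
            return f"{leaf_names[0]};"
        return ";"
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
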