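"""Hypergeometric over-representation analysis and the shared-term gene
network.

Given a gene list, a GMT collection, and a background universe, each term
is scored by the upper-tail hypergeometric probability of the observed
overlap, BH-adjusted across terms, significant at FDR < 0.05.  The network
view connects genes that co-occur in at least one enriched term, with edge
weight equal to the number of shared enriched terms.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .io_formats import GeneSetCollection, ValidationError

__all__ = ["hypergeom_upper", "overrepresentation", "shared_term_network"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent arguments K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValidationError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def overrepresentation(
    genes: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term-by-term enrichment of ``genes`` against ``collection``.

    Genes outside the universe are dropped with a warning; terms with no
    member in the universe are omitted.  Rows are sorted by p ascending.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not genes:
        raise ValidationError("empty gene list")
    uni = set(universe)
    outside = [g for g in genes if g not in uni]
    if outside:
        warnings.warn(f"dropping {len(outside)} gene(s) outside the universe")
    query = set(genes) & uni
    if not query:
        raise ValidationError("no query gene lies in the universe")
    N, n = len(uni), len(query)
    rows = []
    for term, members in collection.sets.items():
        in_uni = set(members) & uni
        if not in_uni:
            continue
        K = len(in_uni)
        overlap = sorted(in_uni & query)
        k = len(overlap)
        p = hypergeom_upper(k, K, n, N)
        rows.append((term, k, K, n, N, p, ",".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["term", "overlap", "set_size", "list_size", "universe_size", "p", "genes"]
    )
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["fdr"] < alpha
        table = table.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        table["fdr"] = []
        table["significant"] = []
    return table


def shared_term_network(
    genes: list[str],
    enriched: pd.DataFrame,
    collection: GeneSetCollection,
) -> nx.Graph:
    """Undirected gene graph; edges join genes sharing ≥1 enriched term.

    ``enriched`` is an :func:`overrepresentation` table; only rows flagged
    significant contribute terms.  Nodes are query genes annotated to at
    least one such term; edge weight counts the shared enriched terms.
    """
    if enriched.empty:
        raise ValidationError("enriched term table is empty")
    terms = list(enriched.loc[enriched.get("significant", False), "term"])
    graph = nx.Graph()
    gene_set = set(genes)
    membership: dict[str, set[str]] = {}
    for term in terms:
        members = set(collection.sets.get(term, ())) & gene_set
        for g in members:
            membership.setdefault(g, set()).add(term)
    graph.add_nodes_from(membership)
    nodes = sorted(membership)
    for i, g1 in enumerate(nodes):
        for g2 in nodes[i + 1 :]:
            shared = len(membership[g1] & membership[g2])
            if shared:
                graph.add_edge(g1, g2, weight=shared)
    return graph
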