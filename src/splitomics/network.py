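"""Signed directed interactome analysis.

Connectivity enrichment asks, per candidate gene, whether its distinct
interaction partners are over-represented in a query list (e.g. the DEG
set) relative to a background universe — the interactome analogue of
gene-set enrichment.  Subnetwork induction, hub ranking and the
downstream/upstream (d/u) bipartite annotation support the network view
of the dichotomised response.

Networks are :class:`networkx.DiGraph` objects whose edges carry a
``sign`` attribute in {activation, inhibition, unspecified}.  Partner
sets for enrichment ignore direction and sign; direction matters only
for the d/u annotation.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

from .stats import adjust_pvalues, hypergeometric_tail

__all__ = [
    "SIGNS",
    "build_network",
    "connectivity_enrichment",
    "induced_subnetwork",
    "hub_ranking",
    "bipartite_annotation",
]

SIGNS = ("activation", "inhibition", "unspecified")


def build_network(edges: Iterable[tuple[str, str, str]]) -> nx.DiGraph:
    """Build a signed digraph from (source, sign, target) triples.

    Self-loops are rejected; duplicate ordered pairs are collapsed
    keeping the first sign (the collapse count is stored on the graph as
    ``graph["n_collapsed"]``).
    """
    g = nx.DiGraph()
    collapsed = 0
    for source, sign, target in edges:
        if sign not in SIGNS:
            raise ValueError(f"unknown edge sign {sign!r}; expected one of {SIGNS}")
        if source == target:
            raise ValueError(f"self-loop on {source!r} not allowed")
        if g.has_edge(source, target):
            collapsed += 1
            continue
        g.add_edge(source, target, sign=sign)
    g.graph["n_collapsed"] = collapsed
    return g


def _partners(net: nx.DiGraph, gene: str) -> set[str]:
    return (set(net.successors(gene)) | set(net.predecessors(gene))) - {gene}


def connectivity_enrichment(
    net: nx.DiGraph,
    query: set[str],
    background: set[str],
    adjust_method: str = "benjamini_hochberg",
    query_label: str = "all_deg",
) -> pd.DataFrame:
    """Per-gene hypergeometric over-connectivity to ``query``.

    For every gene g in the background with at least one interaction
    partner inside the background, tests whether partners(g) overlap the
    query more than chance: k = |partners ∩ query|, draws n =
    |partners|, successes K = |query \\ {g}|, population N =
    |background \\ {g}|.  g is excluded from its own partner set and
    from the population so it cannot count itself.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        stray = sorted(query - background)[:5]
        raise ValueError(f"query genes outside background, e.g. {stray}")
    rows = []
    for gene in sorted(background):
        if gene not in net:
            continue
        partners = _partners(net, gene) & background
        n = len(partners)
        if n == 0:
            continue
        k = len(partners & query)
        K = len(query - {gene})
        N = len(background) - 1
        rows.append(
            {
                "gene": gene,
                "degree": n,
                "overlap": k,
                "p": hypergeometric_tail(k, K, n, N),
                "query_label": query_label,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "degree", "overlap", "p", "query_label"])
    if len(out):
        out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), adjust_method).adjusted
        out = out.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out


def induced_subnetwork(
    net: nx.DiGraph, genes: Iterable[str]
) -> tuple[nx.DiGraph, list[set[str]]]:
    """Subgraph on ``genes`` plus its weakly connected components.

    Gene ids absent from the network are dropped; their count is stored
    as ``graph["n_dropped"]``.  Components are sorted largest first.
    """
    genes = set(genes)
    present = genes & set(net.nodes)
    sub = net.subgraph(present).copy()
    sub.graph["n_dropped"] = len(genes - present)
    components = sorted(nx.weakly_connected_components(sub), key=len, reverse=True)
    return sub, components


def hub_ranking(net: nx.DiGraph) -> list[tuple[str, int]]:
    """Nodes by total degree (in + out) descending; ties lexicographic."""
    return sorted(net.degree(), key=lambda item: (-item[1], item[0]))


def bipartite_annotation(
    net: nx.DiGraph, deg_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-node downstream-target (d) and upstream-regulator (u) counts.

    d is the out-degree and u the in-degree within ``net``; when a DEG
    table is supplied its ``log2fc`` and ``direction`` columns are
    joined in so hubs can be cross-referenced with fold changes.
    """
    rows = [
        {"node": node, "d": net.out_degree(node), "u": net.in_degree(node)}
        for node in sorted(net.nodes)
    ]
    out = pd.DataFrame(rows, columns=["node", "d", "u"])
    if deg_table is not None:
        out = out.join(deg_table[["log2fc", "direction"]], on="node")
    return out
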