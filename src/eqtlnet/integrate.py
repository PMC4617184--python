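"""Integration of eQTLs, co-expression modules and protein interactions.

Module-eQTL overlap uses the upper-tail hypergeometric test; a selected
module's co-expression edges are merged with a PPI edge list (proteins
mapping to module genes fuse into one node); the merged graph is analysed
with shortest-path betweenness centrality and greedy modularity community
clustering.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "module_eqtl_overlap",
    "count_module_eqtls",
    "module_edge_list",
    "merge_coexpression_ppi",
    "betweenness_centrality",
    "community_clusters",
    "hypergeometric_gene_set_test",
]

log = logging.getLogger(__name__)


def module_eqtl_overlap(
    module_genes: set, eqtl_genes: set, universe: set
) -> tuple[int, float, float]:
    """Upper-tail hypergeometric overlap test.

    Returns (overlap count, overlap / module size, P(X >= overlap)) with
    population = |universe|, successes = |eqtl genes|, draws = |module|.
    """
    if not universe:
        raise ValueError("empty gene universe")
    module_genes = set(module_genes)
    eqtl_genes = set(eqtl_genes)
    if not module_genes <= universe or not eqtl_genes <= universe:
        raise ValueError("module and eQTL genes must be subsets of the universe")
    k = len(module_genes & eqtl_genes)
    M, K, n = len(universe), len(eqtl_genes), len(module_genes)
    p = float(hypergeom.sf(k - 1, M, K, n))
    frac = k / n if n else 0.0
    return k, frac, min(p, 1.0)


hypergeometric_gene_set_test = module_eqtl_overlap  # generic gene-set plumbing


def count_module_eqtls(
    labels: pd.Series, cis_eqtl_genes: set, universe: set | None = None
) -> pd.DataFrame:
    """Per-module cis-eQTL gene counts, percentages of module size, and
    hypergeometric overlap p-values; sorted by p then module id."""
    if universe is None:
        universe = set(labels.index)
    cis_in_universe = set(cis_eqtl_genes) & universe
    rows = []
    for mod in sorted(set(labels) - {0}):
        genes = set(labels.index[labels == mod])
        k, frac, p = module_eqtl_overlap(genes, cis_in_universe, universe)
        rows.append(
            {
                "module": mod,
                "n_genes": len(genes),
                "n_eqtl_genes": k,
                "percent": 100.0 * frac,
                "p_hypergeom": p,
            }
        )
    return (
        pd.DataFrame(rows, columns=["module", "n_genes", "n_eqtl_genes", "percent", "p_hypergeom"])
        .sort_values(["p_hypergeom", "module"], kind="mergesort")
        .reset_index(drop=True)
    )


def module_edge_list(
    tom: pd.DataFrame, module_genes: list[str], threshold: float = 0.1
) -> pd.DataFrame:
    """Within-module co-expression edges with TOM weight >= threshold."""
    sub = tom.loc[module_genes, module_genes].to_numpy(dtype=float)
    iu = np.triu_indices(len(module_genes), k=1)
    keep = sub[iu] >= threshold
    return pd.DataFrame(
        {
            "gene_a": np.array(module_genes, dtype=object)[iu[0][keep]],
            "gene_b": np.array(module_genes, dtype=object)[iu[1][keep]],
            "weight": sub[iu][keep],
        }
    )


def merge_coexpression_ppi(
    module_edges: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    id_map: pd.DataFrame | None = None,
    weight_threshold: float = 0.0,
) -> nx.Graph:
    """Merge a module co-expression network with a PPI edge list.

    ``module_edges`` has columns gene_a/gene_b/weight; ``ppi_edges`` has
    two columns of protein (or gene) ids; ``id_map`` (columns protein_id,
    gene_id) fuses proteins onto module genes — an unmapped protein stays
    a protein node.  Node attribute ``kind`` in {gene, protein}; edge
    attribute ``kind`` in {coexpression, ppi}.  Many-to-many mappings use
    the first entry; duplicate edges of the same kind collapse.
    """
    G = nx.Graph()
    for _, row in module_edges.iterrows():
        if row.get("weight", 1.0) < weight_threshold:
            continue
        a, b = str(row.iloc[0]), str(row.iloc[1])
        if a == b:
            continue
        G.add_node(a, kind="gene")
        G.add_node(b, kind="gene")
        G.add_edge(a, b, kind="coexpression", weight=float(row.get("weight", 1.0)))

    mapping: dict[str, str] = {}
    if id_map is not None:
        for _, row in id_map.iterrows():
            prot, gene = str(row.iloc[0]), str(row.iloc[1])
            if prot in mapping and mapping[prot] != gene:
                log.warning("conflicting mapping for %s: keeping %s", prot, mapping[prot])
                continue
            mapping[prot] = gene

    for _, row in ppi_edges.iterrows():
        a, b = str(row.iloc[0]), str(row.iloc[1])
        a = mapping.get(a, a)
        b = mapping.get(b, b)
        if a == b:
            continue
        for node in (a, b):
            if node not in G:
                G.add_node(node, kind="protein")
        if G.has_edge(a, b):
            G.edges[a, b]["kind"] = (
                G.edges[a, b]["kind"]
                if G.edges[a, b]["kind"] == "ppi"
                else G.edges[a, b]["kind"] + "+ppi"
            )
        else:
            G.add_edge(a, b, kind="ppi")
    return G


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Unweighted shortest-path betweenness, normalized by (n-1)(n-2)/2."""
    return nx.betweenness_centrality(graph, normalized=True, weight=None)


def community_clusters(graph: nx.Graph) -> tuple[dict[str, int], float]:
    """Greedy modularity maximization communities on the unweighted graph
    (a deterministic stand-in for GUI community-clustering tools).

    Returns (node -> cluster id, modularity).  An edgeless graph yields
    one singleton cluster per node and modularity 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    if graph.number_of_edges() == 0:
        return {n: i + 1 for i, n in enumerate(sorted(graph.nodes))}, 0.0
    comms = nx.algorithms.community.greedy_modularity_communities(graph, weight=None)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    assign = {}
    for cid, members in enumerate(comms, start=1):
        for node in members:
            assign[node] = cid
    q = nx.algorithms.community.modularity(
        graph, [set(c) for c in comms], weight=None
    )
    return assign, float(q)
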