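"""Significant gene-metabolite bipartite graph per condition.

Nodes are the measured genes and metabolites of the connected pairs;
an edge joins a pair whose Spearman correlation survives FDR control.
Degree analysis and hub-gene pathway enrichment follow.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from ._stats import bh_fdr, hypergeom_upper
from .network import MetabolicNetwork


def build_graph(
    association_table: pd.DataFrame,
    pairs,
    alpha: float = 0.05,
    stratum: str = "all",
) -> nx.Graph:
    """Bipartite graph with one edge per FDR-significant measured pair;
    isolated measured nodes are retained with degree 0."""
    g = nx.Graph(stratum=stratum, alpha=alpha)
    measured = {(r.gene_id, r.metabolite_id)
                for r in association_table.itertuples()}
    for pair in pairs:
        if (pair.gene_id, pair.metabolite_id) not in measured:
            continue
        g.add_node(pair.gene_id, kind="gene", bipartite=0)
        g.add_node(pair.metabolite_id, kind="metabolite", bipartite=1)
    for row in association_table.itertuples():
        if row.q < alpha and not row.flagged:
            g.add_edge(row.gene_id, row.metabolite_id)
    return g


def degree_table(graph: nx.Graph, min_degree: int = 4) -> pd.DataFrame:
    """Degree per node with a ``hub`` flag for degree > min_degree."""
    rows = [{"node": n, "kind": graph.nodes[n].get("kind", "?"),
             "degree": d, "hub": d > min_degree}
            for n, d in graph.degree()]
    return pd.DataFrame(rows, columns=["node", "kind", "degree", "hub"]) \
        .sort_values(["kind", "node"], ignore_index=True)


def hub_pathway_enrichment(
    graph: nx.Graph,
    network: MetabolicNetwork,
    degree_threshold: int = 4,
) -> pd.DataFrame:
    """Per-pathway hypergeometric enrichment of hub genes.

    Population: gene nodes of the graph.  Successes: genes with degree
    above the threshold.  Draws per pathway: population genes belonging
    to it (a gene belongs to every pathway of every reaction it
    catalyzes, and counts once per pathway).  Upper-tail p, BH across
    pathways; with no hubs every p is 1.
    """
    genes = [n for n, d in graph.nodes(data=True) if d.get("kind") == "gene"]
    hubs = {n for n in genes if graph.degree(n) > degree_threshold}
    membership = {g: network.gene_pathways(g) for g in genes}
    pathways = sorted({pw for pws in membership.values() for pw in pws})
    rows = []
    for pw in pathways:
        in_pw = [g for g in genes if pw in membership[g]]
        k = len([g for g in in_pw if g in hubs])
        p = hypergeom_upper(k, len(genes), len(hubs), len(in_pw)) \
            if in_pw else 1.0
        rows.append({"pathway_id": pw,
                     "pathway": network.pathway_names.get(pw, str(pw)),
                     "n_genes": len(in_pw), "n_hub": k, "p": p})
    table = pd.DataFrame(rows, columns=["pathway_id", "pathway",
                                        "n_genes", "n_hub", "p"])
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table
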