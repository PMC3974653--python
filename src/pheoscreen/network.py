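"""Drug-target network construction and eccentricity-based hub analysis.

The network is an undirected, unweighted graph with two node kinds: drugs
and their target genes.  Base edges come from the drug->target map; an
optional "connected node network" mode additionally links every target gene
to every drug, which is the construction behind the maximally connected
view of the screen's drug-target map.  Node importance is scored by
eccentricity centrality: the reciprocal of a node's longest shortest-path
distance within its connected component, so a higher score means a more
central node.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .meta import DrugTargetMap

__all__ = [
    "build_drug_target_network",
    "eccentricity_scores",
    "top_hubs",
    "extract_geneset_subnetwork",
    "read_gmt",
    "write_sif",
    "write_node_attributes",
]


def build_drug_target_network(
    dtmap: DrugTargetMap,
    connect_targets_to_all_drugs: bool = False,
) -> nx.Graph:
    """Build the drug-target graph from a drug->target-gene map.

    Node attribute ``kind`` is "drug" or "gene"; edge attribute
    ``relation`` is "targets" for a drug's own target edges and
    "connected" for the extra gene-to-other-drug edges added when
    ``connect_targets_to_all_drugs`` is set.  No self-loops, no duplicate
    edges, and every gene node has at least one incident edge by
    construction.
    """
    if len(dtmap) == 0:
        raise ValueError("empty drug-target map")
    g = nx.Graph()
    for drug in dtmap.drugs:
        g.add_node(drug, kind="drug")
        for gene in sorted(dtmap[drug]):
            g.add_node(gene, kind="gene")
            g.add_edge(drug, gene, relation="targets")
    if connect_targets_to_all_drugs:
        genes = [n for n, k in g.nodes(data="kind") if k == "gene"]
        for gene in genes:
            for drug in dtmap.drugs:
                if not g.has_edge(drug, gene):
                    g.add_edge(drug, gene, relation="connected")
    return g


def eccentricity_scores(net: nx.Graph) -> pd.DataFrame:
    """Eccentricity centrality per node.

    For node v, ecc(v) is the longest shortest-path distance from v to any
    node of its connected component (unweighted); score(v) = 1/ecc(v).
    Nodes in singleton components have no defined score (NaN, ``defined``
    False).  Disconnected graphs are scored per component.
    """
    rows = []
    for comp_id, comp in enumerate(nx.connected_components(net)):
        sub = net.subgraph(comp)
        if len(comp) == 1:
            (node,) = comp
            rows.append((node, net.nodes[node].get("kind", ""), 0,
                         np.nan, np.nan, False, comp_id))
            continue
        ecc = nx.eccentricity(sub)
        for node, e in ecc.items():
            rows.append((node, net.nodes[node].get("kind", ""),
                         net.degree(node), e, 1.0 / e, True, comp_id))
    df = pd.DataFrame(
        rows, columns=["node", "kind", "degree", "eccentricity", "score",
                       "defined", "component"])
    return df.sort_values("node", kind="mergesort").reset_index(drop=True)


def top_hubs(scores: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Top-n nodes by eccentricity score.

    Descending score, ties broken by higher degree then lexical node id;
    undefined-score nodes rank last.  Returns exactly min(n, #nodes) rows.
    """
    df = scores.copy()
    df["_score"] = df["score"].fillna(-np.inf)
    df = df.sort_values(["_score", "degree", "node"],
                        ascending=[False, False, True], kind="mergesort")
    return df.drop(columns="_score").head(n).reset_index(drop=True)


def extract_geneset_subnetwork(
    net: nx.Graph, gene_sets: dict[str, list[str]]
) -> nx.Graph:
    """Induced subgraph on the union of the gene sets plus incident drugs.

    Retained nodes: genes present in the union of the named sets, plus
    every drug with at least one *target* edge ("targets" relation) to a
    retained gene.  All edges among retained nodes are kept, so extraction
    is idempotent.  Graph attributes record node/edge counts and the drugs
    retained.
    """
    wanted = {str(g).upper() for genes in gene_sets.values() for g in genes}
    gene_nodes = {n for n, k in net.nodes(data="kind") if k == "gene"}
    matched = {n for n in gene_nodes if str(n).upper() in wanted}
    if not matched:
        raise ValueError(
            f"no genes matched: {len(wanted)} set genes vs "
            f"{len(gene_nodes)} network genes")
    drugs = set()
    for gene in matched:
        for nbr in net.neighbors(gene):
            if (net.nodes[nbr].get("kind") == "drug"
                    and net.edges[gene, nbr].get("relation", "targets") == "targets"):
                drugs.add(nbr)
    sub = net.subgraph(matched | drugs).copy()
    sub.graph["n_nodes"] = sub.number_of_nodes()
    sub.graph["n_edges"] = sub.number_of_edges()
    sub.graph["drugs_retained"] = sorted(drugs)
    sub.graph["genes_retained"] = sorted(matched)
    return sub


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read named gene sets from a GMT file (set, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_sif(net: nx.Graph, path) -> None:
    """Write the graph as SIF lines: node1 <relation> node2."""
    with open(path, "w") as fh:
        for u, v, rel in sorted(net.edges(data="relation", default="targets")):
            fh.write(f"{u}\t{rel}\t{v}\n")


def write_node_attributes(scores: pd.DataFrame, path) -> None:
    """Write the node-attribute table (id, kind, degree, score...) as TSV."""
    scores.to_csv(path, sep="\t", index=False)
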