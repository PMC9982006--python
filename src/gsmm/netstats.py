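"""Tripartite network representation and topology statistics.

The model graph is undirected and simple, with one node per metabolite,
reaction and gene: a (metabolite, reaction) edge for every nonzero
stoichiometric coefficient and a (gene, reaction) edge for every distinct
GPR leaf. Gene nodes are included because the node count is then exactly
n_metabolites + n_reactions + n_genes, the identity used to pin the graph
convention. Path-length statistics (diameter, radius, characteristic path
length) are computed on the largest connected component so they stay
finite on disconnected graphs, matching common network-analyzer behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from gsmm.core import MetabolicModel


@dataclass
class NetworkStatsReport:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: int
    radius: int
    characteristic_path_length: float
    density: float
    heterogeneity: float
    centralization: float
    n_connected_components: int


def build_model_graph(model: MetabolicModel) -> nx.Graph:
    """Metabolite-reaction-gene graph; no duplicate edges, no self-loops."""
    g = nx.Graph()
    for mid in model.metabolites:
        g.add_node(mid, kind="metabolite")
    for rid in model.reactions:
        g.add_node(rid, kind="reaction")
    for gene in sorted(model.genes):
        g.add_node(gene, kind="gene")
    for rid, rxn in model.reactions.items():
        for mid, coef in rxn.stoichiometry.items():
            if coef != 0.0:
                g.add_edge(mid, rid)
        for gene in rxn.gpr.genes():
            g.add_edge(gene, rid)
    return g


def graph_statistics(graph: nx.Graph) -> NetworkStatsReport:
    """Degree, distance and centralization statistics of a simple graph.

    density = 2E / (N(N-1)); heterogeneity is the coefficient of variation
    of the degree distribution; centralization is Freeman's degree
    centralization N/(N-2) * (max_degree/(N-1) - density). A single-node
    graph reports diameter 0 and density 0.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("graph is empty")
    e = graph.number_of_edges()
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    avg_neighbors = float(degrees.mean())
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    if n > 2:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    else:
        centralization = 0.0

    components = list(nx.connected_components(graph))
    largest = graph.subgraph(max(components, key=len))
    if largest.number_of_nodes() == 1:
        diameter = radius = 0
        cpl = 0.0
    else:
        ecc = nx.eccentricity(largest)
        diameter = max(ecc.values())
        radius = min(ecc.values())
        cpl = nx.average_shortest_path_length(largest)

    return NetworkStatsReport(
        n_nodes=n,
        n_edges=e,
        avg_neighbors=avg_neighbors,
        diameter=int(diameter),
        radius=int(radius),
        characteristic_path_length=float(cpl),
        density=float(density),
        heterogeneity=heterogeneity,
        centralization=float(centralization),
        n_connected_components=len(components),
    )


def network_report(model: MetabolicModel) -> NetworkStatsReport:
    """Build the model graph and compute its statistics in one call."""
    return graph_statistics(build_model_graph(model))
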