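"""Co-occurrence network construction and topology.

A network is built from a SparCC correlation estimate by keeping only robust
(|r| strictly above a threshold, 0.65 by default) and significant (pseudo-P
strictly below α = 0.05) pairs as signed, weighted edges. Isolated taxa are
dropped: node counts follow the co-occurrence convention of counting only
connected OTUs. Topology metrics follow the standard definitions — density
2L/(n(n−1)), average connectivity avgK = 2L/n, mean local clustering (zero
for degree < 2), Freeman degree centralization, diameter and average path
length on the largest connected component, and modularity / community count
from greedy modularity maximisation. Weighted quantities use |r| as the edge
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .sparcc import CorrelationEstimate

DEFAULT_R_MIN = 0.65
DEFAULT_ALPHA = 0.05

TOPOLOGY_FIELDS = [
    "n_nodes",
    "n_links",
    "avgK",
    "avg_weighted_degree",
    "diameter",
    "avg_path_length",
    "density",
    "modularity",
    "n_communities",
    "clustering_coefficient",
    "mean_eigenvector_centrality",
    "centralization_of_degree",
]


@dataclass
class TopologySummary:
    """All topology metrics for one co-occurrence network.

    Metrics that are undefined for the network at hand (e.g. degree
    centralization with fewer than 3 nodes, path lengths of an empty graph)
    are NaN.
    """

    n_nodes: int = 0
    n_links: int = 0
    avgK: float = float("nan")
    avg_weighted_degree: float = float("nan")
    diameter: float = float("nan")
    avg_path_length: float = float("nan")
    density: float = float("nan")
    modularity: float = float("nan")
    n_communities: int = 0
    clustering_coefficient: float = float("nan")
    mean_eigenvector_centrality: float = float("nan")
    centralization_of_degree: float = float("nan")

    def to_series(self) -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in TOPOLOGY_FIELDS})


def build_network(
    estimate: CorrelationEstimate,
    r_min: float = DEFAULT_R_MIN,
    alpha: float = DEFAULT_ALPHA,
    domains: dict[str, str] | None = None,
) -> nx.Graph:
    """Filtered co-occurrence graph from a correlation estimate.

    An edge (i, j) exists iff |r_ij| > r_min strictly AND p_ij < alpha
    strictly; its ``r`` attribute keeps the sign and ``weight`` is |r|.
    Isolated nodes are dropped. ``domains`` optionally maps taxon id →
    'bacteria'/'fungi' for node labelling.
    """
    if estimate.pseudo_p_matrix is None:
        raise ValueError("estimate has no pseudo_p_matrix; run bootstrap_pseudo_p first")
    r = estimate.r_matrix
    p = estimate.pseudo_p_matrix
    taxa = estimate.taxon_ids
    g = nx.Graph(r_min=r_min, alpha=alpha)
    d = len(taxa)
    for i in range(d):
        for j in range(i + 1, d):
            if abs(r[i, j]) > r_min and p[i, j] < alpha:
                g.add_edge(taxa[i], taxa[j], r=float(r[i, j]), weight=float(abs(r[i, j])))
    if domains:
        nx.set_node_attributes(g, {n: domains.get(n, "unknown") for n in g}, "domain")
    return g


def detect_communities(network: nx.Graph) -> list[set]:
    """Greedy modularity-maximising communities (deterministic), largest first."""
    if network.number_of_edges() == 0:
        return []
    comms = nx.community.greedy_modularity_communities(network, weight="weight")
    return sorted((set(c) for c in comms), key=lambda c: (-len(c), sorted(c)))


def topology(network: nx.Graph, seed: int | None = None) -> TopologySummary:
    """Compute the full topology summary of a (possibly disconnected) network.

    Diameter, average path length and mean eigenvector centrality are
    computed on the largest connected component; this choice is recorded here
    rather than silently failing on disconnected graphs. ``seed`` is accepted
    for interface stability; the configured community detector is
    deterministic.
    """
    n = network.number_of_nodes()
    L = network.number_of_edges()
    summary = TopologySummary(n_nodes=n, n_links=L)
    if n == 0:
        return summary

    degrees = np.array([d for _, d in network.degree()], dtype=float)
    summary.avgK = 2.0 * L / n
    summary.avg_weighted_degree = float(
        np.mean([d for _, d in network.degree(weight="weight")])
    )
    summary.density = 2.0 * L / (n * (n - 1)) if n > 1 else float("nan")
    summary.clustering_coefficient = float(nx.average_clustering(network))
    if n >= 3:
        k_max = degrees.max()
        summary.centralization_of_degree = float(
            (k_max - degrees).sum() / ((n - 1) * (n - 2))
        )

    components = sorted(nx.connected_components(network), key=len, reverse=True)
    giant = network.subgraph(components[0])
    if giant.number_of_nodes() > 1:
        summary.diameter = float(nx.diameter(giant))
        summary.avg_path_length = float(nx.average_shortest_path_length(giant))
        # leading eigenvector of the (dense, symmetric) adjacency matrix,
        # L2-normalised; robust down to 2-node components
        adj = nx.to_numpy_array(giant, weight=None)
        _, vecs = np.linalg.eigh(adj)
        lead = np.abs(vecs[:, -1])
        summary.mean_eigenvector_centrality = float(np.mean(lead / np.linalg.norm(lead)))

    comms = detect_communities(network)
    summary.n_communities = len(comms)
    if comms:
        summary.modularity = float(
            nx.community.modularity(network, comms, weight=None)
        )
    return summary


def module_composition(network: nx.Graph, top_k: int = 3) -> pd.DataFrame:
    """Taxon membership of the largest ``top_k`` modules.

    Modules are ranked by node count (ties broken by member ids); per-module
    bacterial/fungal proportions are reported when nodes carry a ``domain``
    attribute. Returns all modules when fewer than ``top_k`` exist.
    """
    comms = detect_communities(network)[:top_k]
    rows = []
    for rank, members in enumerate(comms, start=1):
        domains = [network.nodes[m].get("domain", "unknown") for m in members]
        n = len(members)
        rows.append(
            {
                "module_rank": rank,
                "n_nodes": n,
                "taxa": ",".join(sorted(str(m) for m in members)),
                "frac_bacteria": domains.count("bacteria") / n,
                "frac_fungi": domains.count("fungi") / n,
            }
        )
    return pd.DataFrame(
        rows, columns=["module_rank", "n_nodes", "taxa", "frac_bacteria", "frac_fungi"]
    )


def degree_distribution_ks(network_a: nx.Graph, network_b: nx.Graph):
    """Two-sample Kolmogorov–Smirnov test between node-degree distributions."""
    if network_a.number_of_nodes() == 0 or network_b.number_of_nodes() == 0:
        raise ValueError("KS comparison requires two non-empty networks")
    deg_a = [d for _, d in network_a.degree()]
    deg_b = [d for _, d in network_b.degree()]
    res = stats.ks_2samp(deg_a, deg_b)
    return float(res.statistic), float(res.pvalue)


def network_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Edge list (source, target, r, p-weight) for CSV export."""
    rows = [
        {"source": u, "target": v, "r": d.get("r", np.nan), "weight": d.get("weight", np.nan)}
        for u, v, d in network.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "weight"])
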