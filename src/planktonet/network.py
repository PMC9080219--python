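"""Core-network construction and graph-level analysis.

The core network keeps only the strongest associations (|LS| > 0.7,
Spearman |rho| > 0.7, Bonferroni-adjusted p < 0.001 by default); the OTUs
incident to the surviving edges are the *core* OTUs.  The module provides
the descriptive statistics used to characterize such networks (density,
diameter, average degree, path length, clustering, maximal cliques,
edge-betweenness modularity), per-node centralities, random-graph
baselines (Erdos-Renyi, Watts-Strogatz, Barabasi-Albert), seasonal
subnetworks, MCODE-style module detection, and the hub/connector
classification of central OTUs.

Centralities are computed and normalized within each connected component
(the convention of the interactive network tools this mirrors): the
center of a 3-node path component has betweenness 1 and closeness 1
regardless of the rest of the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


def filter_core(
    associations: pd.DataFrame,
    ls_min: float = 0.7,
    rho_min: float = 0.7,
    q_max: float = 0.001,
) -> nx.Graph:
    """Build the core network from a scored association table.

    Keeps edges with |LS| > ls_min AND |rho| > rho_min AND q < q_max; a
    node survives only if incident to a surviving edge.  Node attribute
    ``kind`` distinguishes OTU from environmental nodes.
    """
    g = nx.Graph()
    if associations.empty:
        return g
    keep = (
        (associations["ls"].abs() > ls_min)
        & (associations["spearman"].abs() > rho_min)
        & (associations["q"] < q_max)
    )
    for _, row in associations[keep].iterrows():
        g.add_node(row["node_a"], kind=row["kind_a"])
        g.add_node(row["node_b"], kind=row["kind_b"])
        g.add_edge(
            row["node_a"],
            row["node_b"],
            ls=float(row["ls"]),
            sign=int(row["sign"]),
            spearman=float(row["spearman"]),
            q=float(row["q"]),
            p=float(row["p"]),
        )
    return g


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    diameter: int
    density: float
    average_degree: float
    average_path_length: float
    average_clustering: float
    largest_clique_size: int
    largest_clique_count: int
    modularity: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def network_stats(net: nx.Graph, compute_modularity: bool = True) -> NetworkStats:
    """Whole-graph statistics; path metrics use the largest connected
    component, clustering is the mean local coefficient with degree<2
    nodes contributing 0."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("network statistics need at least 2 nodes")
    m = net.number_of_edges()
    components = list(nx.connected_components(net))
    giant = net.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        diameter = nx.diameter(giant)
        apl = nx.average_shortest_path_length(giant)
    else:
        diameter, apl = 0, float("nan")
    cliques = list(nx.find_cliques(net)) if m else []
    if cliques:
        cmax = max(len(c) for c in cliques)
        ccount = sum(1 for c in cliques if len(c) == cmax)
    else:
        cmax, ccount = 1, n
    if compute_modularity and m:
        _, q_mod = girvan_newman_modularity(net)
    else:
        q_mod = float("nan")
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        diameter=diameter,
        density=nx.density(net),
        average_degree=2.0 * m / n,
        average_path_length=apl,
        average_clustering=nx.average_clustering(net) if n else float("nan"),
        largest_clique_size=cmax,
        largest_clique_count=ccount,
        modularity=q_mod,
    )


def node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness (normalized within each connected
    component) and local clustering per node."""
    rows = {}
    clustering = nx.clustering(net)
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        bc = nx.betweenness_centrality(sub, normalized=True)
        cc = nx.closeness_centrality(sub, wf_improved=False)
        for node in comp:
            rows[node] = {
                "degree": net.degree(node),
                "betweenness": bc[node],
                "closeness": cc[node],
                "clustering": clustering[node],
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.sort_index()


def random_baseline(
    n_nodes: int,
    n_edges: int,
    model: str = "er",
    params: dict | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Random graph with matched size: Erdos-Renyi G(n, m), Watts-Strogatz
    (ring lattice + rewiring, edge count matched by random addition or
    removal), or Barabasi-Albert (edge count matched as closely as the
    attachment parameter allows)."""
    params = params or {}
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("more edges requested than a simple graph allows")
    rng = np.random.default_rng(seed)
    if model == "er":
        return nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
    if model == "ws":
        k = max(2, int(2 * n_edges / n_nodes) // 2 * 2)
        p_rewire = params.get("p", 0.05)
        g = nx.watts_strogatz_graph(n_nodes, k, p_rewire, seed=int(rng.integers(2**31)))
        _match_edge_count(g, n_edges, rng)
        return g
    if model == "ba":
        # attachment parameter m yields m*(n-m) edges; pick the closest
        m_attach = params.get(
            "m",
            min(
                range(1, n_nodes),
                key=lambda m: abs(m * (n_nodes - m) - n_edges),
            ),
        )
        return nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31)))
    raise ValueError(f"unknown model {model!r}")


def _match_edge_count(g: nx.Graph, target: int, rng: np.random.Generator) -> None:
    nodes = list(g.nodes)
    while g.number_of_edges() > target:
        edges = sorted(g.edges)
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
    while g.number_of_edges() < target:
        u, v = rng.choice(len(nodes), size=2, replace=False)
        u, v = nodes[u], nodes[v]
        if not g.has_edge(u, v):
            g.add_edge(u, v)


def seasonal_subnetwork(
    net: nx.Graph, annotations: dict[str, str], season: str
) -> nx.Graph:
    """Induced subgraph on OTU nodes whose preferred season matches;
    environmental nodes are always excluded."""
    valid = {"winter", "spring", "summer", "autumn", "none"}
    if season not in valid:
        raise ValueError(f"unknown season {season!r}")
    keep = [
        node
        for node, data in net.nodes(data=True)
        if data.get("kind", "otu") == "otu" and annotations.get(node, "none") == season
    ]
    return net.subgraph(keep).copy()


@dataclass
class Module:
    nodes: list[str]
    score: float  # subgraph density x node count
    seed_node: str
    season_majority: str | None = None


def _mcode_weights(g: nx.Graph) -> dict:
    """MCODE vertex weight: highest k-core of the closed neighbourhood,
    weight = k x density of that core."""
    weights = {}
    for v in g.nodes:
        neigh = set(g.neighbors(v)) | {v}
        sub = g.subgraph(neigh)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_num = nx.core_number(sub)
        k = max(core_num.values())
        core_nodes = [u for u, c in core_num.items() if c >= k]
        core_sub = sub.subgraph(core_nodes)
        weights[v] = k * nx.density(core_sub)
    return weights


def mcode_modules(
    net: nx.Graph, vwp: float = 0.2, score_min: float | None = None, haircut: bool = True
) -> list[Module]:
    """MCODE-style module detection.

    Stages: (1) vertex weighting by core-clustering of the closed
    neighbourhood; (2) greedy complex growth from the highest-weight
    unseen seed, admitting neighbours with weight >= (1 - vwp) x seed
    weight; (3) haircut = iterative removal of degree-1 members (the
    2-core of the complex).  Modules are scored density x size and
    returned sorted by score (descending); with ``score_min`` set, only
    modules above the threshold are returned.
    """
    weights = _mcode_weights(net)
    seen: set = set()
    modules: list[Module] = []
    order = sorted(net.nodes, key=lambda v: (-weights[v], str(v)))
    for seed in order:
        if seed in seen or weights[seed] <= 0:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        complex_nodes = {seed}
        queue = [seed]
        while queue:
            u = queue.pop(0)
            for w in net.neighbors(u):
                if w in seen or w in complex_nodes:
                    continue
                if weights[w] >= threshold:
                    complex_nodes.add(w)
                    queue.append(w)
        seen |= complex_nodes
        sub = net.subgraph(complex_nodes).copy()
        if haircut:
            sub = nx.k_core(sub, 2) if sub.number_of_edges() else sub
        if sub.number_of_nodes() < 2 or sub.number_of_edges() == 0:
            continue
        score = nx.density(sub) * sub.number_of_nodes()
        modules.append(
            Module(nodes=sorted(map(str, sub.nodes)), score=float(score), seed_node=str(seed))
        )
    modules.sort(key=lambda m: (-m.score, m.nodes))
    if score_min is not None:
        modules = [m for m in modules if m.score > score_min]
    return modules


def girvan_newman_modularity(net: nx.Graph) -> tuple[list[set], float]:
    """Edge-betweenness (Girvan-Newman) community detection.

    Repeatedly removes the edge with the highest betweenness, recording
    the component partition whenever it changes, and returns the
    partition with maximal Newman-Girvan modularity Q (the trivial
    connected-component partition is a candidate, so Q >= 0 never forces
    a split of a complete graph)."""
    if net.number_of_edges() == 0:
        raise ValueError("modularity needs at least one edge")
    work = net.copy()
    partitions = [list(nx.connected_components(work))]
    n_comp = len(partitions[0])
    while work.number_of_edges():
        ebc = nx.edge_betweenness_centrality(work)
        best_edge = max(sorted(ebc), key=lambda e: ebc[e])
        work.remove_edge(*best_edge)
        comps = list(nx.connected_components(work))
        if len(comps) > n_comp:
            n_comp = len(comps)
            partitions.append(comps)
    best_q = -np.inf
    best_partition = partitions[0]
    for part in partitions:
        q = nx.community.modularity(net, part)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = part
    return best_partition, float(best_q)


@dataclass
class CentralityThresholds:
    degree: float
    betweenness: float
    closeness: float


DEFAULT_HUB = CentralityThresholds(degree=24, betweenness=0.03, closeness=0.3)
DEFAULT_CONNECTOR = CentralityThresholds(degree=5, betweenness=0.03, closeness=0.2)


def classify_central(
    metrics: pd.DataFrame,
    hub: CentralityThresholds = DEFAULT_HUB,
    connector: CentralityThresholds = DEFAULT_CONNECTOR,
) -> pd.Series:
    """Hub/connector classification of core OTUs.

    Hub: degree >= 24, betweenness >= 0.03, closeness >= 0.3.  Connector
    (mutually exclusive with hub): degree <= 5, betweenness >= 0.03,
    closeness >= 0.2.  All bounds are closed so that values printed at
    2-decimal precision on the threshold satisfy their rule.
    """
    is_hub = (
        (metrics["degree"] >= hub.degree)
        & (metrics["betweenness"] >= hub.betweenness)
        & (metrics["closeness"] >= hub.closeness)
    )
    is_connector = (
        ~is_hub
        & (metrics["degree"] <= connector.degree)
        & (metrics["betweenness"] >= connector.betweenness)
        & (metrics["closeness"] >= connector.closeness)
    )
    out = pd.Series("none", index=metrics.index, name="class")
    out[is_hub] = "hub"
    out[is_connector] = "connector"
    return out
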