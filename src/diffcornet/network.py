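"""Differential-correlation network construction and topological analysis.

The selected differential edges form an undirected simple graph whose nodes
are the incident metabolites.  Hubs are high-degree nodes; bottlenecks are
nodes of high betweenness or closeness, which control shortest-path
information flow.  Centralities are computed on the unweighted topology;
|r_diff| is kept as an edge attribute only.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffcorr import DifferentialEdge
from .errors import ConfigurationError, DataError

EDGE_COLUMNS = ["met_i", "met_j", "r_diff", "p_perm", "sign", "weight"]


def build_network(edges: list[DifferentialEdge]) -> nx.Graph:
    """Build the undirected simple graph of selected differential edges.

    Edge attributes carry ``r_diff``, ``sign``, ``p_perm`` and
    ``weight = |r_diff|``.  Duplicate unordered pairs violate the upstream
    contract and raise.
    """
    graph = nx.Graph()
    seen = set()
    for e in edges:
        key = tuple(sorted((e.met_i, e.met_j)))
        if key[0] == key[1]:
            raise DataError(f"self-loop edge for metabolite {key[0]!r}")
        if key in seen:
            raise DataError(f"duplicate edge {key}")
        seen.add(key)
        graph.add_edge(
            e.met_i, e.met_j,
            r_diff=float(e.r_diff), sign=e.sign, p_perm=float(e.p_perm),
            weight=abs(float(e.r_diff)),
        )
    return graph


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness and closeness on the unweighted graph.

    Degree is the raw neighbour count.  Betweenness uses shortest paths with
    endpoints excluded, normalized by ``(N-1)(N-2)/2``.  Closeness is the
    classical definition within each connected component,
    ``(n_comp - 1) / sum of distances``.
    """
    if graph.number_of_nodes() == 0:
        raise DataError("centralities require a non-empty network")
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True, weight=None)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    frame = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=int),
            "betweenness": pd.Series(betweenness, dtype=float),
            "closeness": pd.Series(closeness, dtype=float),
        }
    )
    return frame.sort_index()


def mean_degree(graph: nx.Graph) -> float:
    """Average node degree, 2E/N."""
    n = graph.number_of_nodes()
    if n == 0:
        raise DataError("mean degree undefined for an empty network")
    return 2.0 * graph.number_of_edges() / n


def identify_hubs(
    graph: nx.Graph, top_k: int, bottleneck_quantile: float = 0.9
) -> pd.DataFrame:
    """Rank nodes by degree (ties: betweenness, then name); flag bottlenecks.

    A node is flagged as a bottleneck when its betweenness or closeness lies
    in the top decile (configurable via ``bottleneck_quantile``).  If
    ``top_k`` exceeds the node count the ranking is truncated with a warning.
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be at least 1")
    scores = centralities(graph)
    if top_k > len(scores):
        warnings.warn(
            f"top_k={top_k} exceeds node count {len(scores)}; truncating", stacklevel=2
        )
        top_k = len(scores)
    b_cut = float(np.quantile(scores["betweenness"], bottleneck_quantile))
    c_cut = float(np.quantile(scores["closeness"], bottleneck_quantile))
    scores = scores.copy()
    scores["bottleneck"] = (scores["betweenness"] >= b_cut) | (scores["closeness"] >= c_cut)
    ranked = scores.sort_values(
        by=["degree", "betweenness"], ascending=[False, False], kind="mergesort"
    )
    # stable mergesort on a name-sorted frame gives the name tie-break
    return ranked.head(top_k)


def topology_report(graph: nx.Graph, top_k: int = 10) -> dict:
    """JSON-ready summary: N, E, mean degree, component sizes, hubs/bottlenecks."""
    if graph.number_of_nodes() == 0:
        return {"n_nodes": 0, "n_edges": 0, "mean_degree": None,
                "component_sizes": [], "hubs": [], "bottlenecks": []}
    hubs = identify_hubs(graph, top_k=min(top_k, graph.number_of_nodes()))
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "mean_degree": mean_degree(graph),
        "component_sizes": sorted(
            (len(c) for c in nx.connected_components(graph)), reverse=True
        ),
        "hubs": [
            {"metabolite": name, "degree": int(row["degree"]),
             "betweenness": float(row["betweenness"]), "closeness": float(row["closeness"])}
            for name, row in hubs.iterrows()
        ],
        "bottlenecks": sorted(hubs.index[hubs["bottleneck"]].tolist()),
    }


def export_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Export as GraphML or edge-list CSV; round-trip safe via :func:`import_network`."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "csv":
        rows = [
            {"met_i": u, "met_j": v, "r_diff": d["r_diff"], "p_perm": d["p_perm"],
             "sign": d["sign"], "weight": d["weight"]}
            for u, v, d in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, index=False)
    else:
        raise ConfigurationError(f"unknown export format {fmt!r}; use 'graphml' or 'csv'")


def import_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"network file not found: {path}")
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        return nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    if fmt == "csv":
        frame = pd.read_csv(path)
        graph = nx.Graph()
        for _, row in frame.iterrows():
            graph.add_edge(
                row["met_i"], row["met_j"],
                r_diff=float(row["r_diff"]), p_perm=float(row["p_perm"]),
                sign=str(row["sign"]), weight=float(row["weight"]),
            )
        return graph
    raise ConfigurationError(f"unknown import format {fmt!r}; use 'graphml' or 'csv'")


def write_topology_report(graph: nx.Graph, path: str | Path, top_k: int = 10) -> None:
    Path(path).write_text(json.dumps(topology_report(graph, top_k=top_k), indent=2, sort_keys=True))
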