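"""Whole-network metrics for per-pen affinity graphs.

Edges are the strictly positive affinity scores.  Following the convention of
the classical SNA toolchain on weighted graphs, edge weights are treated as
path *lengths* for diameter and betweenness — so a higher-affinity edge is a
longer step under this convention.  That matches how dense pen networks end
up with diameters in the hundreds; ``distance="inverse"`` is available for
the more intuitive strong-tie-is-close reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .scoring import AffinityNetwork

__all__ = ["NetworkMetrics", "compute_metrics", "top_relationships", "edge_percentile_subgraph"]


@dataclass
class NetworkMetrics:
    """Summary metrics of one pen's affinity network."""

    pen_id: str
    n_nodes: int
    n_edges: int
    density: float
    diameter: float
    connected: bool
    degree: dict[str, int]
    degree_max: int
    degree_min: int
    degree_mean: float
    n_at_max_degree: int
    betweenness: dict[str, float]

    def to_row(self) -> dict:
        return {
            "pen_id": self.pen_id,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "diameter": self.diameter,
            "density": self.density,
            "degree_max": self.degree_max,
            "degree_min": self.degree_min,
            "degree_mean": self.degree_mean,
            "n_at_max": self.n_at_max_degree,
            "connected": self.connected,
        }


def _distance_graph(network: AffinityNetwork, distance: str) -> nx.Graph:
    g = network.as_graph()
    if distance == "weight":
        for _, _, d in g.edges(data=True):
            d["length"] = d["weight"]
    elif distance == "inverse":
        for _, _, d in g.edges(data=True):
            d["length"] = 1.0 / d["weight"]
    else:
        raise ValueError(f"unknown distance convention {distance!r}")
    return g


def compute_metrics(network: AffinityNetwork, distance: str = "weight") -> NetworkMetrics:
    """Density, diameter, degree and betweenness of a pen network.

    * density = 2E / (N(N-1)) over strictly positive edges;
    * degree = number of incident positive edges per cow;
    * diameter = the longest shortest path (edge length per ``distance``),
      over the largest connected component when the graph is disconnected
      (flagged via ``connected=False``); NaN for an empty graph;
    * betweenness = networkx shortest-path betweenness (normalised by the
      number of node pairs) under the same edge-length convention.
    """
    n = network.n_cows
    if n < 2:
        raise ValueError("network metrics need at least 2 cows")
    g = _distance_graph(network, distance)
    n_edges = g.number_of_edges()
    density = 2.0 * n_edges / (n * (n - 1))

    degree = {c: int(d) for c, d in g.degree()}
    deg_values = np.array(list(degree.values()))
    degree_max = int(deg_values.max())
    degree_min = int(deg_values.min())

    components = list(nx.connected_components(g))
    nontrivial = [c for c in components if len(c) > 1]
    connected = len(components) == 1
    if not nontrivial:
        diameter = math.nan
    else:
        giant = max(nontrivial, key=lambda c: (len(c), sorted(c)[0]))
        sub = g.subgraph(giant)
        ecc = nx.eccentricity(sub, sp=dict(nx.all_pairs_dijkstra_path_length(sub, weight="length")))
        diameter = float(max(ecc.values()))

    betweenness = nx.betweenness_centrality(g, weight="length", normalized=True)
    return NetworkMetrics(
        pen_id=network.pen_id,
        n_nodes=n,
        n_edges=n_edges,
        density=density,
        diameter=diameter,
        connected=connected,
        degree=degree,
        degree_max=degree_max,
        degree_min=degree_min,
        degree_mean=float(deg_values.mean()),
        n_at_max_degree=int((deg_values == degree_max).sum()),
        betweenness={c: float(b) for c, b in betweenness.items()},
    )


def top_relationships(network: AffinityNetwork, cow: str, k: int = 5) -> list[tuple[str, float]]:
    """A cow's strongest partners, descending by score, ties by ascending id.

    Zero-score partners are not relationships and are omitted, so fewer than
    ``k`` entries may be returned.
    """
    if cow not in network.cows:
        raise KeyError(f"cow {cow!r} not in network")
    i = network.cows.index(cow)
    scored = [
        (partner, float(s))
        for partner, s in zip(network.cows, network.weights[i])
        if partner != cow and s > 0
    ]
    scored.sort(key=lambda ps: (-ps[1], ps[0]))
    return scored[:k]


def edge_percentile_subgraph(network: AffinityNetwork, top_fraction: float = 0.10) -> AffinityNetwork:
    """Keep only the strongest fraction of edges (node set unchanged).

    The threshold is the ``ceil(top_fraction * m)``-th largest nonzero
    weight; edges at the threshold are kept, so ties may retain more than
    the nominal fraction.  Used to declutter network plots.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    iu, ju = np.triu_indices(network.n_cows, k=1)
    vals = network.weights[iu, ju]
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("network has no edges")
    k = max(1, math.ceil(top_fraction * nonzero.size))
    threshold = np.sort(nonzero)[::-1][k - 1]
    kept = np.where(network.weights >= threshold, network.weights, 0.0)
    np.fill_diagonal(kept, 0.0)
    return network.with_weights(kept)


def metrics_frame(metrics: dict[str, NetworkMetrics]) -> pd.DataFrame:
    """Stack per-pen metrics into one table (one row per pen)."""
    return pd.DataFrame([m.to_row() for m in metrics.values()]).reset_index(drop=True)
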