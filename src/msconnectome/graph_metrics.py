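"""Local nodal graph metrics in binary and weighted variants.

The four measures — degree/strength, clustering coefficient, local
efficiency, betweenness centrality — follow the Rubinov–Sporns brain
connectivity conventions:

* weights are scaled by the largest weight in the graph before entering
  clustering and efficiency (``w~ = w / max w``);
* triangle contributions are geometric means, ``(w~_ij w~_jh w~_hi)^(1/3)``;
* weighted shortest paths treat weights as affinities, so path lengths use
  ``1/w`` (betweenness) or ``(1/w~)^(1/3)`` (local efficiency, so that the
  printed cube root distributes over the inverse path length);
* with all-equal weights each weighted variant reduces exactly to its binary
  counterpart on the same support.

Nodes of degree < 2 take clustering and efficiency 0; pairs with no
connecting path contribute 0 to efficiency and betweenness.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectome import BrainGraph

__all__ = [
    "NodeMetricVector",
    "node_degree",
    "clustering_coefficient",
    "local_efficiency",
    "betweenness_centrality",
    "all_local_metrics",
    "METRIC_ORDER",
]

#: canonical order of the metric collection: degree, betweenness, clustering,
#: efficiency — the order used by feature assembly and CSV export.
METRIC_ORDER = ("degree", "betweenness", "clustering", "efficiency")


@dataclass(frozen=True)
class NodeMetricVector:
    metric_name: str
    weighted: bool
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)


def _weights(graph: BrainGraph) -> np.ndarray:
    """Adjacency as used by the requested variant (binary support or weights)."""
    a = graph.adjacency
    return np.where(a > 0, a, 0.0)


def _scaled_weights(w: np.ndarray) -> np.ndarray:
    """Divide by the largest weight of the (thresholded) graph."""
    wmax = w.max(initial=0.0)
    return w / wmax if wmax > 0 else w


def node_degree(graph: BrainGraph, weighted: bool) -> NodeMetricVector:
    """Number of connections per node, or their weight sum (strength)."""
    w = _weights(graph)
    values = w.sum(axis=1) if weighted else (w > 0).sum(axis=1).astype(float)
    return NodeMetricVector("degree", weighted, values)


def clustering_coefficient(graph: BrainGraph, weighted: bool) -> NodeMetricVector:
    """Fraction of triangles around each node.

    Weighted variant replaces the triangle count with the sum of triangle
    intensities ``(w~_ij w~_jh w~_hi)^(1/3)``.
    """
    w = _weights(graph)
    support = (w > 0).astype(float)
    k = support.sum(axis=1)
    cyc = np.cbrt(_scaled_weights(w)) if weighted else support
    # diag(C^3) counts each (ordered pair) triangle contribution twice = 2*t_i
    two_t = np.einsum("ij,jh,hi->i", cyc, cyc, cyc)
    denom = k * (k - 1)
    values = np.divide(two_t, denom, out=np.zeros_like(two_t), where=denom > 0)
    return NodeMetricVector("clustering", weighted, values)


def local_efficiency(graph: BrainGraph, weighted: bool) -> NodeMetricVector:
    """Efficiency of the subgraph induced by each node's neighbors.

    For node i with neighbors N_i, sums ``(w~_ij w~_ih)^(1/3) / d_jh`` over
    ordered pairs j != h in N_i, where d_jh is the shortest-path length in the
    subgraph restricted to N_i; unreachable pairs contribute 0.  Normalized by
    k_i (k_i - 1).
    """
    w = _scaled_weights(_weights(graph)) if weighted else (_weights(graph) > 0).astype(float)
    q = graph.q
    k = (w > 0).sum(axis=1)
    values = np.zeros(q)
    # path lengths: hop counts for binary, cube-rooted inverse weights otherwise
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, np.cbrt(1.0 / np.where(w > 0, w, 1.0)), 0.0)
    for i in range(q):
        if k[i] < 2:
            continue
        nbrs = np.flatnonzero(w[i] > 0)
        sub = lengths[np.ix_(nbrs, nbrs)]
        dist = shortest_path(sub, method="D", directed=False, unweighted=not weighted)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
        conn = np.cbrt(w[i, nbrs])
        values[i] = (conn[:, None] * conn[None, :] * inv).sum() / (k[i] * (k[i] - 1))
    return NodeMetricVector("efficiency", weighted, values)


def betweenness_centrality(graph: BrainGraph, weighted: bool) -> NodeMetricVector:
    """Fraction of all shortest paths passing through each node.

    Normalized by (n-1)(n-2) over ordered endpoint pairs; weighted paths use
    edge length 1/w.
    """
    w = _weights(graph)
    g = nx.from_numpy_array(w)
    if weighted:
        for _, _, data in g.edges(data=True):
            data["length"] = 1.0 / data["weight"]
        bc = nx.betweenness_centrality(g, normalized=True, weight="length")
    else:
        bc = nx.betweenness_centrality(g, normalized=True, weight=None)
    values = np.array([bc[i] for i in range(graph.q)])
    return NodeMetricVector("betweenness", weighted, values)


def all_local_metrics(graph: BrainGraph, weighted: bool) -> dict[str, NodeMetricVector]:
    """All four metrics on the same graph, keyed in :data:`METRIC_ORDER`."""
    return {
        "degree": node_degree(graph, weighted),
        "betweenness": betweenness_centrality(graph, weighted),
        "clustering": clustering_coefficient(graph, weighted),
        "efficiency": local_efficiency(graph, weighted),
    }
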