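"""Connectivity-matrix data model and proportional edge thresholding.

A structural connectome is a symmetric, non-negative matrix of fiber counts
between ``q`` parcellated gray-matter regions.  The analysis graph is obtained
by proportional thresholding: keep the fraction ``tau`` of strongest possible
edges, i.e. the ``T = floor((q^2 - q) * tau / 2)`` unordered node pairs with
the largest weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "BrainGraph",
    "load_connectivity",
    "save_connectivity",
    "threshold_graph",
    "binarize",
    "edge_density",
    "to_graphml",
    "from_graphml",
]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Raw symmetric fiber-count matrix with region labels.

    Parameters
    ----------
    values : ndarray of shape (q, q)
        Non-negative symmetric matrix with zero diagonal; entry ``(i, j)``
        is the number of tractography streamlines linking regions i and j.
    node_labels : tuple of str
        Region names, one per node.
    """

    values: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got shape {values.shape}")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(f"NaN entry at cell ({i}, {j})")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(f"negative entry {values[i, j]} at cell ({i}, {j})")
        asym = np.abs(values - values.T)
        if asym.max(initial=0.0) > _SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"asymmetric entries at cells ({i}, {j})/({j}, {i}): "
                f"{values[i, j]} vs {values[j, i]}"
            )
        # symmetrize residual numerical noise, clear the diagonal
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        labels = tuple(self.node_labels) if self.node_labels else tuple(
            f"region_{i}" for i in range(values.shape[0])
        )
        if len(labels) != values.shape[0]:
            raise ValueError("node_labels length must match matrix size")
        object.__setattr__(self, "node_labels", labels)

    @property
    def q(self) -> int:
        """Number of nodes."""
        return self.values.shape[0]


@dataclass(frozen=True)
class BrainGraph:
    """Thresholded undirected analysis graph (weighted or binary)."""

    adjacency: np.ndarray
    weighted: bool
    tau: float
    n_edges_kept: int
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        adjacency = np.asarray(self.adjacency, dtype=float)
        adjacency.flags.writeable = False
        object.__setattr__(self, "adjacency", adjacency)
        labels = tuple(self.node_labels) if self.node_labels else tuple(
            f"region_{i}" for i in range(adjacency.shape[0])
        )
        object.__setattr__(self, "node_labels", labels)

    @property
    def q(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        """Export as a networkx graph with ``weight`` edge attributes."""
        g = nx.from_numpy_array(self.adjacency)
        nx.relabel_nodes(g, dict(enumerate(self.node_labels)), copy=False)
        return g


def load_connectivity(path, node_labels=None) -> ConnectivityMatrix:
    """Read a whitespace-delimited square matrix file.

    Asymmetry above 1e-9 and negative or NaN cells are errors naming the
    offending cell.
    """
    try:
        values = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:  # ragged rows / non-numeric tokens
        raise ValueError(f"could not parse {path} as a numeric matrix: {exc}") from exc
    return ConnectivityMatrix(values, tuple(node_labels) if node_labels else ())


def save_connectivity(matrix: ConnectivityMatrix, path) -> None:
    """Write the matrix as whitespace-delimited text (round-trips with load)."""
    np.savetxt(path, matrix.values, fmt="%.10g")


def threshold_graph(matrix: ConnectivityMatrix, tau: float) -> BrainGraph:
    """Proportional threshold: keep the ``T = floor((q^2-q)*tau/2)`` heaviest edges.

    Only node pairs with positive weight are eligible; if fewer than ``T``
    exist, all of them are kept.  Ties at the cutoff weight are broken by
    lexicographic node-pair order so the result is deterministic and the edge
    set is monotone in ``tau``.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    q = matrix.q
    t_edges = math.floor((q * q - q) * tau / 2.0)
    iu, ju = np.triu_indices(q, k=1)
    weights = matrix.values[iu, ju]
    positive = weights > 0
    iu, ju, weights = iu[positive], ju[positive], weights[positive]
    # stable sort on (-weight, i, j): lexsort keys are last-key-primary
    order = np.lexsort((ju, iu, -weights))[:t_edges]
    kept = np.zeros((q, q), dtype=float)
    kept[iu[order], ju[order]] = weights[order]
    kept += kept.T
    return BrainGraph(
        adjacency=kept,
        weighted=True,
        tau=tau,
        n_edges_kept=int(order.size),
        node_labels=matrix.node_labels,
    )


def binarize(graph: BrainGraph) -> BrainGraph:
    """Replace every positive weight with 1; edge set unchanged."""
    return BrainGraph(
        adjacency=(graph.adjacency > 0).astype(float),
        weighted=False,
        tau=graph.tau,
        n_edges_kept=graph.n_edges_kept,
        node_labels=graph.node_labels,
    )


def edge_density(graph: BrainGraph) -> float:
    """Fraction of possible unordered node pairs that are edges: 2|E|/(q^2-q)."""
    q = graph.q
    if q < 2:
        raise ValueError("edge density requires at least 2 nodes")
    n_edges = int(np.count_nonzero(np.triu(graph.adjacency, k=1)))
    return 2.0 * n_edges / (q * q - q)


def to_graphml(graph: BrainGraph, path) -> None:
    """Write the graph as GraphML with ``weight`` edge attributes."""
    nx.write_graphml(graph.to_networkx(), path)


def from_graphml(path, tau: float = 1.0) -> BrainGraph:
    """Read a GraphML file written by :func:`to_graphml`."""
    g = nx.read_graphml(path)
    labels = tuple(str(n) for n in g.nodes())
    adjacency = nx.to_numpy_array(g, nodelist=list(g.nodes()), weight="weight")
    n_edges = int(np.count_nonzero(np.triu(adjacency, k=1)))
    weighted = bool(np.any((adjacency != 0) & (adjacency != 1)))
    return BrainGraph(adjacency, weighted=weighted, tau=tau,
                      n_edges_kept=n_edges, node_labels=labels)
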