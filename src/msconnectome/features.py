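"""Node-feature matrix assembly for the classification experiments.

Six conditions are supported: ``identity`` (featureless — the identity matrix,
so the classifier relies on graph structure alone), one column per single
metric (``D``, ``BC``, ``CC``, ``E``), and ``all-graphs`` (the four metric
columns together).  Metric columns are min-max normalized to [0, 1] per graph,
per column; identity features are already in {0, 1} and are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import BrainGraph
from .graph_metrics import (
    METRIC_ORDER,
    all_local_metrics,
    betweenness_centrality,
    clustering_coefficient,
    local_efficiency,
    node_degree,
)

__all__ = ["NodeFeatureMatrix", "build_feature_matrix", "minmax_normalize", "CONDITIONS"]

CONDITIONS = ("identity", "D", "BC", "CC", "E", "all-graphs")

_SINGLE_METRIC = {
    "D": node_degree,
    "BC": betweenness_centrality,
    "CC": clustering_coefficient,
    "E": local_efficiency,
}


@dataclass(frozen=True)
class NodeFeatureMatrix:
    """q x d node descriptor matrix with every entry in [0, 1]."""

    values: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def d(self) -> int:
        return self.values.shape[1]


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Map to [0, 1] by (v - min) / (max - min); constant vectors map to zeros."""
    v = np.asarray(v, dtype=float)
    if np.isnan(v).any():
        raise ValueError("cannot normalize a vector containing NaN")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def build_feature_matrix(graph: BrainGraph, condition: str, weighted: bool) -> NodeFeatureMatrix:
    """Assemble the node-feature matrix X for one experimental condition."""
    if condition == "identity":
        return NodeFeatureMatrix(np.eye(graph.q), condition)
    if condition in _SINGLE_METRIC:
        col = _SINGLE_METRIC[condition](graph, weighted).values
        return NodeFeatureMatrix(minmax_normalize(col)[:, None], condition)
    if condition == "all-graphs":
        metrics = all_local_metrics(graph, weighted)
        cols = [minmax_normalize(metrics[name].values) for name in METRIC_ORDER]
        return NodeFeatureMatrix(np.column_stack(cols), condition)
    raise ValueError(f"unknown feature condition {condition!r}; expected one of {CONDITIONS}")
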