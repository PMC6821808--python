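"""Ollivier-Ricci curvature of weighted graphs and node-level aggregates.

Each node x of an undirected weighted graph carries a neighbourhood
probability measure

    p_x(y) = w_xy / d_x,    d_x = sum_{y in N(x)} w_xy,

i.e. mass proportional to edge weight on the adjacent nodes.  The
Ollivier-Ricci curvature of an edge (x, y) compares these measures through
optimal transport:

    kappa(x, y) = 1 - W1(p_x, p_y) / d(x, y),

where W1 is the earth mover's distance and d the hop (shortest-path edge
count) distance on the whole graph — weights enter only through the
measures, never through the geodesic.  For adjacent nodes d(x, y) = 1, so
kappa = 1 - W1.  Positive curvature flags edges whose endpoint
neighbourhoods overlap or are cheaply transportable into one another
(redundant, well-clustered connectivity); negative curvature flags
bridge-like, fragile edges.

Node-level summaries: the scalar node curvature sums kappa over incident
edges; the weighted variant averages it under p_x.  Both are 0 by
convention for isolated nodes (deletion cascades produce such nodes
routinely and must stay total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netio import NodeMeasureVector, WeightedGraph, hop_distances
from .transport import DiscreteMeasure, emd

logger = logging.getLogger(__name__)


class IsolatedNodeError(ValueError):
    """Raised when a neighbourhood measure is requested for a degree-0 node."""


class NotAdjacentError(ValueError):
    """Edge curvature is defined only for pairs with positive weight."""


def node_distribution(g: WeightedGraph, x: int) -> DiscreteMeasure:
    """Neighbourhood measure p_x supported exactly on the neighbours of x."""
    nbrs = g.neighbors(x)
    if nbrs.size == 0:
        raise IsolatedNodeError(f"node {g.node_ids[x]} has no neighbours")
    w = g.weights[x, nbrs]
    return DiscreteMeasure(support=nbrs.tolist(), masses=w / w.sum())


def edge_curvature(
    g: WeightedGraph, x: int, y: int, hop: np.ndarray | None = None
) -> float:
    """Ollivier-Ricci curvature kappa(x, y) of a single edge.

    Symmetric in (x, y) exactly: the endpoint order is canonicalized so
    both orientations solve the identical transport problem.  ``hop`` may
    carry a precomputed hop-distance matrix to avoid recomputation.
    """
    if g.weights[x, y] <= 0:
        raise NotAdjacentError(f"nodes {x} and {y} are not adjacent")
    x, y = min(x, y), max(x, y)
    if hop is None:
        hop = hop_distances(g)
    px, py = node_distribution(g, x), node_distribution(g, y)
    cost = hop[np.ix_(px.support, py.support)]
    w1, _ = emd(px, py, cost, assume_metric=True)
    return 1.0 - w1  # d(x, y) = 1 for adjacent nodes under the hop metric


@dataclass
class CurvatureTable:
    """Per-edge and per-node curvature of one graph.

    ``edges`` holds one row per unordered positive-weight edge; the scalar
    node curvature equals the per-node sum of incident edge rows, the
    weighted version the p_x-weighted sum.
    """

    node_ids: list[str]
    edges: list[tuple[int, int, float]]
    node_scalar: np.ndarray
    node_weighted: np.ndarray

    @property
    def network_average(self) -> float:
        """Mean scalar node curvature over non-isolated nodes."""
        deg = self._degrees
        return float(self.node_scalar[deg > 0].mean())

    @property
    def _degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.node_ids), dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_curvatures(self) -> np.ndarray:
        return np.array([k for _, _, k in self.edges])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "record": "edge",
                "id_a": self.node_ids[i],
                "id_b": self.node_ids[j],
                "kappa": k,
                "kappa_weighted": np.nan,
            }
            for i, j, k in self.edges
        ]
        rows += [
            {
                "record": "node",
                "id_a": nid,
                "id_b": "",
                "kappa": ks,
                "kappa_weighted": kw,
            }
            for nid, ks, kw in zip(self.node_ids, self.node_scalar, self.node_weighted)
        ]
        return pd.DataFrame(rows)


def curvature_table(g: WeightedGraph) -> CurvatureTable:
    """Compute kappa for every edge plus both node aggregates in one pass.

    Hop distances and all neighbourhood measures are computed once; each
    unordered edge then solves a single transport LP.
    """
    n = g.n_nodes
    hop = hop_distances(g)
    dist = {}
    for x in range(n):
        if g.degree(x) > 0:
            dist[x] = node_distribution(g, x)
    edges = []
    node_scalar = np.zeros(n)
    node_weighted = np.zeros(n)
    for i, j in g.edge_list():
        px, py = dist[i], dist[j]
        cost = hop[np.ix_(px.support, py.support)]
        w1, _ = emd(px, py, cost, assume_metric=True)
        k = 1.0 - w1
        edges.append((i, j, k))
        node_scalar[i] += k
        node_scalar[j] += k
        node_weighted[i] += px.masses[px.support.index(j)] * k
        node_weighted[j] += py.masses[py.support.index(i)] * k
    isolated = [g.node_ids[x] for x in range(n) if x not in dist]
    if isolated:
        logger.info("%d isolated node(s) assigned curvature 0", len(isolated))
    return CurvatureTable(
        node_ids=list(g.node_ids),
        edges=edges,
        node_scalar=node_scalar,
        node_weighted=node_weighted,
    )


def node_curvature(g: WeightedGraph, table: CurvatureTable | None = None) -> NodeMeasureVector:
    """Scalar node curvature: sum of kappa over incident edges (0 if isolated)."""
    table = table or curvature_table(g)
    return NodeMeasureVector("curvature", list(g.node_ids), table.node_scalar)


def weighted_node_curvature(
    g: WeightedGraph, table: CurvatureTable | None = None
) -> NodeMeasureVector:
    """Weighted node curvature: expectation of kappa(x, .) under p_x."""
    table = table or curvature_table(g)
    return NodeMeasureVector(
        "weighted_curvature", list(g.node_ids), table.node_weighted
    )


def network_average_curvature(
    g: WeightedGraph, mode: str = "node_mean", table: CurvatureTable | None = None
) -> float:
    """Network-level curvature: mean over non-isolated nodes or over edges."""
    if g.n_edges == 0:
        raise ValueError("network average curvature requires at least one edge")
    table = table or curvature_table(g)
    if mode == "node_mean":
        return table.network_average
    if mode == "edge_mean":
        return float(table.edge_curvatures().mean())
    raise ValueError(f"unknown mode {mode!r} (use node_mean or edge_mean)")
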