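"""Classical nodal and global network measures used as comparators.

Node strength, betweenness centrality and the (binary) clustering
coefficient are the standard nodal importance measures of the connectome
literature; global efficiency and the random-walk entropy rate are the
global integration metrics tracked along deletion cascades.

Conventions, chosen once and used everywhere:

* Betweenness sums over unordered pairs and is reported unnormalized.
  Shortest paths are measured either in hops (``length_mode="hop"``) or
  with edge length ``1/w`` (``"inverse_weight"``, the default: strong
  connections are short).  All co-optimal paths are counted fractionally.
* Clustering binarizes the graph: C_i = 2 T_i / (k_i (k_i - 1)) with T_i
  the number of edges among i's neighbours; C_i = 0 for degree < 2.
* Global efficiency averages 1/length over all ordered pairs of the
  *current* node set; unreachable pairs contribute 0.
* The entropy is the entropy rate of the weight-proportional random walk,
  S = -sum_x pi_x sum_y p_x(y) ln p_x(y), with stationary distribution
  pi_x = d_x / sum_z d_z; isolated nodes are excluded.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.stats import pearsonr

from .netio import NodeMeasureVector, WeightedGraph, hop_distances


class ConstantMeasureError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def strength(g: WeightedGraph) -> NodeMeasureVector:
    """Node strength s_i: sum of incident edge weights (matrix row sums)."""
    return NodeMeasureVector("strength", list(g.node_ids), g.weights.sum(axis=1))


def _to_networkx(g: WeightedGraph, length_mode: str) -> nx.Graph:
    gx = nx.Graph()
    gx.add_nodes_from(range(g.n_nodes))
    for i, j in g.edge_list():
        w = g.weights[i, j]
        gx.add_edge(i, j, length=(1.0 if length_mode == "hop" else 1.0 / w))
    return gx


def betweenness(
    g: WeightedGraph, length_mode: str = "inverse_weight"
) -> NodeMeasureVector:
    """Unnormalized betweenness centrality g_i over unordered node pairs.

    g_i = sum over pairs {j, k} of sigma_jk(i) / sigma_jk, the fraction of
    shortest j-k paths through i; pairs with no connecting path contribute
    nothing.
    """
    _check_length_mode(length_mode)
    gx = _to_networkx(g, length_mode)
    bc = nx.betweenness_centrality(
        gx, normalized=False, weight=None if length_mode == "hop" else "length"
    )
    return NodeMeasureVector(
        "betweenness", list(g.node_ids), [bc[i] for i in range(g.n_nodes)]
    )


def clustering(g: WeightedGraph) -> NodeMeasureVector:
    """Binary clustering coefficient: realized fraction of neighbour edges."""
    a = (g.weights > 0).astype(float)
    k = a.sum(axis=1)
    # triangles through i = (A^3)_ii / 2; denominator k(k-1)/2
    tri = np.diag(a @ a @ a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * tri / (k * (k - 1)), 0.0)
    return NodeMeasureVector("clustering", list(g.node_ids), c)


def _check_length_mode(length_mode: str) -> None:
    if length_mode not in ("hop", "inverse_weight"):
        raise ValueError(f"unknown length_mode {length_mode!r}")


def _path_lengths(g: WeightedGraph, length_mode: str) -> np.ndarray:
    if length_mode == "hop":
        return hop_distances(g)
    w = g.weights
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def global_efficiency(g: WeightedGraph, length_mode: str = "hop") -> float:
    """E = mean of 1/l_ij over ordered node pairs; 0 for unreachable pairs.

    Normalized by N(N-1) with N the current node count, so the value is
    comparable across the shrinking graphs of a deletion cascade.
    """
    _check_length_mode(length_mode)
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = _path_lengths(g, length_mode)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def entropy(g: WeightedGraph) -> float:
    """Entropy rate of the weight-proportional random walk on the graph.

    S = -sum_x pi_x sum_y p_x(y) ln p_x(y) in nats, with p_x(y) = w_xy/d_x
    and pi_x = d_x / sum_z d_z the walk's stationary distribution.
    Isolated nodes carry no stationary mass and are excluded.
    """
    d = g.weights.sum(axis=1)
    if d.sum() == 0:
        raise ValueError("entropy requires at least one edge")
    pi = d / d.sum()
    s = 0.0
    for x in np.flatnonzero(d > 0):
        p = g.weights[x, g.weights[x] > 0] / d[x]
        s += pi[x] * float(-(p * np.log(p)).sum())
    return s


def pearson_correlation(a: NodeMeasureVector, b: NodeMeasureVector) -> float:
    """Sample Pearson r between two nodal measures across nodes."""
    if len(a.values) != len(b.values):
        raise ValueError("measure vectors have different lengths")
    if len(a.values) < 3:
        raise ValueError("correlation requires at least 3 nodes")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise ConstantMeasureError(
            f"correlation undefined: {a.measure_name if np.ptp(a.values) == 0 else b.measure_name} is constant"
        )
    return float(pearsonr(a.values, b.values).statistic)
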