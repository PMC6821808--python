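"""Graph data model, matrix I/O, validation and elementary topology.

The universal substrate is :class:`WeightedGraph`: an undirected graph on
``N`` labelled nodes stored as a dense symmetric nonnegative weight matrix
(weights are tractography streamline counts or densities, treated as
dimensionless).  Adjacency is implied by positive weight: ``y`` is a
neighbour of ``x`` iff ``w[x, y] > 0``.  Matrices at connectome scale
(N <= ~1000) are kept dense throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

logger = logging.getLogger(__name__)

#: Sentinel for the hop distance between nodes in different components.
#: Kept as floating infinity, never a large finite stand-in, so that
#: downstream efficiency sums can treat unreachable pairs as contributing 0.
INF = np.inf

#: Relative asymmetry below which a matrix is silently symmetrized by
#: averaging; above _ASYM_HARD the file is considered corrupt.
_ASYM_TOL = 1e-9
_ASYM_HARD = 1e-6


class ValidationError(ValueError):
    """A connectivity matrix violated a structural requirement."""


class NonSquareError(ValidationError):
    pass


class NegativeWeightError(ValidationError):
    pass


class NaNWeightError(ValidationError):
    pass


class AsymmetryError(ValidationError):
    pass


@dataclass
class WeightedGraph:
    """Undirected weighted graph with stable node identifiers.

    Parameters
    ----------
    weights
        Dense symmetric ``(N, N)`` nonnegative matrix with zero diagonal.
    node_ids
        Ordered stable identifiers; defaults to ``"n0" .. n{N-1}``.
        All vectors and matrices produced elsewhere in the package are
        aligned to this order.
    labels, metadata
        Optional per-node annotation (anatomical label, coordinates,
        community tag).
    """

    weights: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    labels: list[str] | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareError(f"weight matrix must be square, got shape {w.shape}")
        if np.isnan(w).any():
            i, j = np.argwhere(np.isnan(w))[0]
            raise NaNWeightError(f"NaN weight at cell ({i}, {j})")
        if (w < 0).any():
            i, j = np.argwhere(w < 0)[0]
            raise NegativeWeightError(f"negative weight {w[i, j]} at cell ({i}, {j})")
        w = _symmetrize(w)
        if np.diag(w).any():
            logger.warning("nonzero diagonal forced to 0 (no self-loops)")
            np.fill_diagonal(w, 0.0)
        self.weights = w
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(w.shape[0])]
        if len(self.node_ids) != w.shape[0]:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for {w.shape[0]} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights)))

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of nodes adjacent to node ``i`` (positive weight)."""
        return np.flatnonzero(self.weights[i] > 0)

    def degree(self, i: int) -> int:
        return int((self.weights[i] > 0).sum())

    def edge_list(self) -> list[tuple[int, int]]:
        """Unordered edges as index pairs ``(i, j)`` with ``i < j``."""
        iu, ju = np.nonzero(np.triu(self.weights))
        return list(zip(iu.tolist(), ju.tolist()))

    def subgraph_without(self, drop: list[int]) -> "WeightedGraph":
        """Copy with the given node indices (rows+columns) removed."""
        keep = np.setdiff1d(np.arange(self.n_nodes), np.asarray(drop, dtype=int))
        return WeightedGraph(
            weights=self.weights[np.ix_(keep, keep)],
            node_ids=[self.node_ids[k] for k in keep],
            labels=[self.labels[k] for k in keep] if self.labels else None,
        )

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


@dataclass
class NodeMeasureVector:
    """A named per-node scalar measure aligned to a graph's node order."""

    measure_name: str
    node_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.node_ids) != self.values.shape[0]:
            raise ValidationError("measure length does not match node count")
        if not np.isfinite(self.values).all():
            raise ValidationError(f"non-finite entries in measure {self.measure_name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": self.node_ids, self.measure_name: self.values}
        )


def _symmetrize(w: np.ndarray) -> np.ndarray:
    """Average-symmetrize within tolerance; hard error on gross asymmetry."""
    if w.size == 0:
        return w
    asym = np.abs(w - w.T)
    scale = max(np.abs(w).max(), 1.0)
    rel = asym.max() / scale
    if rel > _ASYM_HARD:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise AsymmetryError(
            f"matrix asymmetric beyond tolerance at cell ({i}, {j}): "
            f"{w[i, j]} vs {w[j, i]}"
        )
    if rel > _ASYM_TOL:
        logger.warning("asymmetric input symmetrized by averaging (max rel %.2e)", rel)
    return (w + w.T) / 2.0


def _detect_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    for delim in ("\t", ","):
        if delim in first:
            return delim
    return " "


def load_matrix(
    path: str | Path,
    delimiter: str | None = None,
    has_header: bool | None = None,
) -> WeightedGraph:
    """Read a dense N x N connectivity matrix from delimited text.

    The delimiter is auto-detected among tab/comma/space unless given.  If
    the first row is non-numeric it is taken as node labels (with a
    matching leading label column).  Validation errors are specific:
    non-square tables, negative weights and NaN cells each raise their own
    exception naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = delimiter or _detect_delimiter(path)
    sep = r"\s+" if delim == " " else delim
    probe = pd.read_csv(path, sep=sep, header=None, nrows=1, dtype=str)

    def _is_float(x) -> bool:
        try:
            float(x)  # "nan"/"inf" count as numeric, not as labels
            return True
        except (TypeError, ValueError):
            return False

    first_numeric = all(_is_float(x) for x in probe.iloc[0])
    header = (not first_numeric) if has_header is None else has_header
    if header:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        node_ids = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        node_ids = []
    try:
        w = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric entry in {path}: {exc}") from exc
    if w.shape[0] != w.shape[1]:
        raise NonSquareError(
            f"{path} parsed to a {w.shape[0]}x{w.shape[1]} table; expected square"
        )
    return WeightedGraph(weights=w, node_ids=node_ids)


def save_matrix(g: WeightedGraph, path: str | Path, delimiter: str = "\t") -> None:
    """Write the weight matrix with a label header row and column."""
    df = pd.DataFrame(g.weights, index=g.node_ids, columns=g.node_ids)
    df.to_csv(path, sep=delimiter, float_format="%.12g")


def load_node_metadata(path: str | Path) -> pd.DataFrame:
    """Read a node metadata TSV (node_id, label, x, y, z, community)."""
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    if "node_id" not in df.columns:
        raise ValidationError("node metadata must have a node_id column")
    return df


def hop_distances(g: WeightedGraph) -> np.ndarray:
    """All-pairs hop distance of the binarized graph (BFS per source).

    Returns an ``(N, N)`` float matrix: minimum number of edges on a path,
    0 on the diagonal, ``inf`` for pairs in different components.
    """
    adj = csr_matrix((g.weights > 0).astype(np.int8))
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def component_labels(g: WeightedGraph) -> tuple[int, np.ndarray]:
    adj = csr_matrix((g.weights > 0).astype(np.int8))
    return connected_components(adj, directed=False)


def largest_component_size(g: WeightedGraph) -> int:
    """Node count of the largest connected component (0 for empty graph).

    Isolated nodes count as singleton components.
    """
    if g.n_nodes == 0:
        return 0
    n_comp, labels = component_labels(g)
    return int(np.bincount(labels).max())


def save_table(obj, path: str | Path) -> None:
    """Write any tabular result type as TSV (12 significant digits).

    Accepts :class:`NodeMeasureVector`, a curvature table, a deletion
    trajectory, a group comparison, or a plain DataFrame — anything with a
    ``to_frame()`` method.  Round-trips losslessly at 12 significant digits.
    """
    df = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
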