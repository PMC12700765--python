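"""Network structures for influence simulations.

The unit of analysis throughout the package is an undirected, unweighted
social network: a set of nodes (individuals) joined by binary ties.  Traits
diffuse along ties, and every nonindependence correction consumes some
transformation of the tie structure — the raw adjacency matrix ``W``, the
matrix of geodesic (shortest-path) distances, a community partition, a
low-dimensional embedding, or an ultrametric tree.

Synthetic networks are grown by linear preferential attachment (the
Barabási–Albert process): each new node attaches to existing nodes with
probability proportional to their current degree, which produces the
heavy-tailed degree distributions typical of real social networks.  With
one edge per arriving node (the default) the result is a random tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "CommunityPartition",
    "generate_pa_network",
    "geodesic_distances",
    "finite_distances",
    "walktrap_communities",
    "read_network",
    "write_network",
]


class Network:
    """An undirected simple graph with a dense binary adjacency matrix.

    Parameters
    ----------
    adjacency:
        ``(n, n)`` symmetric 0/1 matrix with zero diagonal.
    node_ids:
        Optional external labels, preserved through file round-trips.
        Internally nodes are always indexed ``0..n-1``.
    """

    def __init__(self, adjacency, node_ids=None, validate: bool = True):
        A = np.asarray(adjacency)
        if validate:
            if A.ndim != 2 or A.shape[0] != A.shape[1]:
                raise ValueError("adjacency must be a square matrix")
            if A.shape[0] < 2:
                raise ValueError("a network needs at least 2 nodes")
            if not np.array_equal(A, A.T):
                raise ValueError("adjacency must be symmetric")
            if np.any(np.diag(A) != 0):
                raise ValueError("adjacency must have a zero diagonal (no self-loops)")
            if not np.isin(A, (0, 1)).all():
                raise ValueError("adjacency must be binary")
        self.adjacency = A.astype(np.int8)
        if node_ids is not None and len(node_ids) != A.shape[0]:
            raise ValueError("node_ids length must equal the number of nodes")
        self.node_ids = list(node_ids) if node_ids is not None else None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Unordered edge set as ``(i, j)`` tuples with ``i < j``."""
        i, j = np.nonzero(np.triu(self.adjacency))
        return set(zip(i.tolist(), j.tolist()))

    @property
    def labeled_edges(self) -> set[frozenset]:
        """Edge set under external labels (stable across re-indexing)."""
        labels = self.node_ids or [str(i) for i in range(self.n_nodes)]
        return {frozenset((labels[i], labels[j])) for i, j in self.edges}

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def is_connected(self) -> bool:
        n_comp = ig.Graph(self.n_nodes, list(self.edges)).connected_components().__len__()
        return n_comp == 1

    # -- constructors / converters ------------------------------------
    @classmethod
    def from_edges(cls, n_nodes: int, edges, node_ids=None) -> "Network":
        A = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for i, j in edges:
            if i == j:
                continue
            A[i, j] = A[j, i] = 1
        return cls(A, node_ids=node_ids)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        nodes = list(g.nodes())
        index = {v: k for k, v in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in g.edges() if u != v]
        ids = None if nodes == list(range(len(nodes))) else [str(v) for v in nodes]
        return cls.from_edges(len(nodes), edges, node_ids=ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        labels = self.node_ids or list(range(self.n_nodes))
        g.add_nodes_from(labels)
        g.add_edges_from((labels[i], labels[j]) for i, j in self.edges)
        return g

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(self.n_nodes, list(self.edges))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class CommunityPartition:
    """Assignment of every node to exactly one community (labels ``0..k-1``)."""

    labels: np.ndarray
    n_communities: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(self.n_communities)):
            raise ValueError("community labels must be contiguous integers 0..k-1")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_communities)


def generate_pa_network(n_nodes: int, edges_per_step: int = 1, seed=None) -> Network:
    """Grow an undirected network by linear preferential attachment.

    Each arriving node attaches ``edges_per_step`` ties to existing nodes with
    probability proportional to degree (attachment exponent 1).  With the
    default ``edges_per_step=1`` the result is a tree on ``n_nodes`` nodes
    with ``n_nodes - 1`` edges, always connected.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if edges_per_step < 1:
        raise ValueError("edges_per_step must be >= 1")
    g = nx.barabasi_albert_graph(n_nodes, edges_per_step, seed=seed)
    return Network.from_networkx(g)


def geodesic_distances(net: Network) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths.

    Disconnected pairs get ``np.inf``; see :func:`finite_distances` for the
    finite substitution used by embeddings and tree building.
    """
    sparse = csr_array(net.adjacency)
    return shortest_path(sparse, method="D", unweighted=True, directed=False)


def finite_distances(D: np.ndarray) -> np.ndarray:
    """Replace infinite (disconnected-pair) distances by diameter + 1."""
    D = np.asarray(D, dtype=float)
    if np.isinf(D).any():
        diameter = D[np.isfinite(D)].max()
        D = np.where(np.isinf(D), diameter + 1.0, D)
    return D


def walktrap_communities(net: Network, steps: int = 4) -> CommunityPartition:
    """Random-walk (walktrap) community detection.

    Agglomerates nodes along short random walks of length ``steps`` and cuts
    the merge sequence at maximum modularity.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    dendrogram = net.to_igraph().community_walktrap(steps=steps)
    clustering = dendrogram.as_clustering()
    labels = np.asarray(clustering.membership, dtype=np.int64)
    # igraph guarantees contiguous labels but renumber defensively
    _, labels = np.unique(labels, return_inverse=True)
    return CommunityPartition(labels=labels, n_communities=int(labels.max()) + 1)


# ---------------------------------------------------------------------------
# file I/O: two-column edge-list TSV and GraphML
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt", ".edges", ".edgelist"}:
        return "edge_list_tsv"
    if suffix == ".graphml":
        return "graphml"
    raise ValueError(f"cannot infer network format from '{path.name}'; pass format=")


def read_network(path, format: str | None = None) -> Network:
    """Read a network from an edge-list TSV or GraphML file.

    Edge lists are two whitespace/tab-separated columns of node labels;
    lines starting with ``#`` are ignored.  Self-loops are dropped and
    duplicate edges collapsed, both with a logged warning.  Node labels are
    preserved in ``node_ids`` in order of first appearance.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "graphml":
        return Network.from_networkx(nx.read_graphml(path))
    if fmt != "edge_list_tsv":
        raise ValueError(f"unknown network format: {fmt}")

    index: dict[str, int] = {}
    raw_edges: list[tuple[int, int]] = []
    n_self, n_dup = 0, 0
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path.name}:{lineno}: expected two columns, got {len(parts)}"
                )
            u, v = parts
            iu = index.setdefault(u, len(index))
            iv = index.setdefault(v, len(index))
            if iu == iv:
                n_self += 1
                continue
            key = (min(iu, iv), max(iu, iv))
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            raw_edges.append(key)
    if n_self:
        warnings.warn(f"{path.name}: dropped {n_self} self-loop(s)", stacklevel=2)
        logger.warning("%s: dropped %d self-loop(s)", path.name, n_self)
    if n_dup:
        warnings.warn(f"{path.name}: collapsed {n_dup} duplicate edge(s)", stacklevel=2)
        logger.warning("%s: collapsed %d duplicate edge(s)", path.name, n_dup)
    labels = list(index)
    ids = None if labels == [str(i) for i in range(len(labels))] else labels
    return Network.from_edges(len(index), raw_edges, node_ids=ids)


def write_network(net: Network, path, format: str | None = None) -> None:
    """Write a network as an edge-list TSV or GraphML file."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    if fmt != "edge_list_tsv":
        raise ValueError(f"unknown network format: {fmt}")
    labels = net.node_ids or [str(i) for i in range(net.n_nodes)]
    with open(path, "w") as fh:
        for i, j in sorted(net.edges):
            fh.write(f"{labels[i]}\t{labels[j]}\n")
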