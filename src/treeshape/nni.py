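"""The nearest-neighbor-interchange (NNI) Cayley graph over a shape space.

Vertices are the shapes on ``l`` leaves; edges join shapes one NNI move apart.
An NNI move acts on an internal edge (parent u, internal child v): the sibling
of v is exchanged with one of v's two children, giving two candidate
rearrangements per internal edge.  Moves whose result is isomorphic to the
source are dropped, so the graph is simple.

The graph's Laplacian drives the spectral resolution R_L; breadth-first
all-pairs shortest paths over the graph give the unlabeled NNI distance matrix
that drives the geometric resolution R_D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.csgraph import connected_components

from .shapes import ShapeSpace, TreeShape, make_shape

__all__ = ["CayleyGraph", "DistanceMatrix", "nni_neighbors", "build_cayley_graph",
           "laplacian", "distance_matrix"]


def nni_neighbors(shape: TreeShape) -> set[TreeShape]:
    """All shapes one NNI move away from ``shape`` (excluding itself).

    Shapes with fewer than 3 leaves have no internal edge and return the
    empty set.
    """
    out: set[TreeShape] = set()
    for alt in _rearranged(shape):
        if alt is not shape:
            out.add(alt)
    return out


def _rearranged(node: TreeShape) -> list[TreeShape]:
    """Every shape obtained by one NNI move somewhere inside ``node``."""
    if node.is_leaf:
        return []
    a, b = node.children
    results: list[TreeShape] = []
    # moves across the edge from this node down to an internal child:
    # exchange the child's sibling with each of the child's own children
    for child, sibling in ((a, b), (b, a)):
        if child.is_leaf:
            continue
        x, y = child.children
        results.append(make_shape(make_shape(sibling, y), x))
        results.append(make_shape(make_shape(x, sibling), y))
    # moves strictly inside either subtree
    for alt in _rearranged(a):
        results.append(make_shape(alt, b))
    for alt in _rearranged(b):
        results.append(make_shape(a, alt))
    return results


@dataclass(frozen=True)
class CayleyGraph:
    """NNI Cayley graph over a shape space, as a symmetric sparse 0/1 adjacency."""

    space: ShapeSpace
    adjacency: sp.csr_matrix = field(repr=False)

    @property
    def num_vertices(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def num_edges(self) -> int:
        return int(self.adjacency.nnz) // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def is_connected(self) -> bool:
        if self.num_vertices <= 1:
            return True
        ncomp, _ = connected_components(self.adjacency, directed=False)
        return ncomp == 1

    def edge_list(self) -> list[tuple[int, int]]:
        """Sorted (i, j) pairs with i < j."""
        coo = sp.triu(self.adjacency).tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))


def build_cayley_graph(space: ShapeSpace) -> CayleyGraph:
    """Build the NNI Cayley graph over an enumerated space.

    Every generated neighbor must be present in the space's index; a miss
    signals an enumeration/move inconsistency and raises RuntimeError.
    NNI reversibility is asserted by symmetrizing only after checking the
    directed edge sets coincide.
    """
    rows: list[int] = []
    cols: list[int] = []
    for i, shape in enumerate(space.shapes):
        for nb in nni_neighbors(shape):
            try:
                j = space.index[nb.canonical_key]
            except KeyError:
                raise RuntimeError(
                    f"NNI neighbor {nb.canonical_key}; of shape {i} not found in the "
                    f"space on {space.leaf_count} leaves — enumeration/move mismatch"
                ) from None
            rows.append(i)
            cols.append(j)
    n = space.num_shapes
    adj = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    ).tocsr()
    if (adj != adj.T).nnz:
        raise RuntimeError("NNI move set is not symmetric — move generation bug")
    return CayleyGraph(space=space, adjacency=adj)


def laplacian(graph: CayleyGraph) -> sp.csr_matrix:
    """Graph Laplacian L = Diag(degrees) - Adjacency (sparse, symmetric PSD)."""
    adj = graph.adjacency.astype(np.float64)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(deg) - adj).tocsr()


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs unlabeled NNI distances over a shape space.

    distances: integer matrix of shortest-path lengths in the Cayley graph.
    """

    space: ShapeSpace
    distances: np.ndarray = field(repr=False)

    @property
    def squared(self) -> np.ndarray:
        """Elementwise square D_s, as float64 (materialized on demand)."""
        return self.distances.astype(np.float64) ** 2

    def apply_neg_half_squared(self, X: np.ndarray) -> np.ndarray:
        """Compute (-1/2 D_s) X without materializing the float64 D_s.

        X is (n,) or (n, k); the squared distances are formed blockwise from
        the integer distance matrix, keeping peak memory at one row block.
        Exact: BFS distances square to small integers.
        """
        X = np.asarray(X, dtype=np.float64)
        one_d = X.ndim == 1
        if one_d:
            X = X[:, None]
        n = self.distances.shape[0]
        if X.shape[0] != n:
            raise ValueError(f"operand has {X.shape[0]} rows, expected {n}")
        W = np.empty_like(X)
        block = max(1, 4_000_000 // max(n, 1))
        for start in range(0, n, block):
            stop = min(start + block, n)
            Db = self.distances[start:stop].astype(np.float64)
            np.multiply(Db, Db, out=Db)
            W[start:stop] = Db @ X
        W *= -0.5
        return W[:, 0] if one_d else W

    def neg_half_quadform(self, X: np.ndarray) -> np.ndarray | float:
        """X^t (-1/2 D_s) X, blockwise; scalar for a vector, (k, k) for (n, k)."""
        X = np.asarray(X, dtype=np.float64)
        W = self.apply_neg_half_squared(X)
        if X.ndim == 1:
            return float(X @ W)
        return X.T @ W


def distance_matrix(graph: CayleyGraph) -> DistanceMatrix:
    """BFS all-pairs shortest paths over the Cayley graph.

    Raises ValueError on a disconnected graph (which would indicate a
    neighbor-generation bug), naming the components.
    """
    n = graph.num_vertices
    ncomp, labels = connected_components(graph.adjacency, directed=False)
    if ncomp != 1 and n > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"Cayley graph is disconnected: {ncomp} components with sizes "
            f"{sizes.tolist()}"
        )
    adj = graph.adjacency
    dist = _bfs_all_pairs(adj.indptr.astype(np.int64),
                          adj.indices.astype(np.int32), n)
    return DistanceMatrix(space=graph.space, distances=dist)


@njit(cache=True)
def _bfs_all_pairs(indptr, indices, n):  # pragma: no cover - exercised via wrapper
    """Level-order BFS from every source over a CSR adjacency; int16 output
    (NNI diameters are far below 2^15)."""
    dist = np.full((n, n), -1, dtype=np.int16)
    queue = np.empty(n, dtype=np.int32)
    for src in range(n):
        row = dist[src]
        row[src] = 0
        queue[0] = src
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = row[u]
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if row[v] < 0:
                    row[v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist
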