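"""Census of small connected induced subgraphs (k = 3, 4).

The type catalog A(k) covers every isomorphism class of connected simple
graphs on k nodes: 2 classes for k = 3 (path, triangle) and 6 for k = 4
(path, claw, cycle, paw, diamond, complete).  Counts are *induced*: each
k-subset of nodes whose induced subgraph is connected contributes to exactly
one class, so the class counts partition the connected k-sets.

Two counting routes are provided:

``count_induced``
    The production path.  Non-induced (subgraph) counts are obtained from
    closed-form expressions in degrees, per-pair common-neighbour counts and
    per-node triangle counts, then converted to induced counts by inverting
    the fixed subgraph-inclusion matrix between the 6 classes.  Cost is
    polynomial in edges and insensitive to how many subgraphs exist, which
    matters for hub-containing ego-networks.

``count_by_enumeration``
    A brute-force oracle: iterate all k-subsets, test connectivity, classify
    by (sorted degree sequence, triangle count).  Used to validate the fast
    path; quadratic-to-quartic in nodes, intended for n <= ~2,000.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "catalog",
    "count_induced",
    "count_by_enumeration",
    "GRAPHLETS_3",
    "GRAPHLETS_4",
]

GRAPHLETS_3 = ("P3", "K3")
GRAPHLETS_4 = ("P4", "claw", "C4", "paw", "diamond", "K4")

# Prototype edge lists on vertex set {0..k-1}, in catalog order.
_PROTOTYPES = {
    "P3": ((0, 1), (1, 2)),
    "K3": ((0, 1), (1, 2), (0, 2)),
    "P4": ((0, 1), (1, 2), (2, 3)),
    "claw": ((0, 1), (0, 2), (0, 3)),
    "C4": ((0, 1), (1, 2), (2, 3), (3, 0)),
    "paw": ((0, 1), (1, 2), (0, 2), (2, 3)),
    "diamond": ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3)),
    "K4": ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)),
}


class UnsupportedOrderError(ValueError):
    """Raised for a subgraph order outside {3, 4}."""


def catalog(k: int) -> tuple:
    """The ordered catalog of connected k-node graph classes."""
    if k == 3:
        return GRAPHLETS_3
    if k == 4:
        return GRAPHLETS_4
    raise UnsupportedOrderError(f"subgraph order must be 3 or 4, got {k}")


# ---------------------------------------------------------------------------
# Classification of tiny graphs (used by the enumeration oracle and by the
# inclusion-matrix construction).


def _classify(k: int, degs: tuple, n_tri: int) -> str | None:
    """Isomorphism class of a *connected* graph on k nodes from its sorted
    degree sequence and triangle count; None if disconnected/unknown."""
    if k == 3:
        return {(1, 1, 2): "P3", (2, 2, 2): "K3"}.get(degs)
    sig = {
        ((1, 1, 2, 2), 0): "P4",
        ((1, 1, 1, 3), 0): "claw",
        ((2, 2, 2, 2), 0): "C4",
        ((1, 2, 2, 3), 1): "paw",
        ((2, 2, 3, 3), 2): "diamond",
        ((3, 3, 3, 3), 4): "K4",
    }
    return sig.get((degs, n_tri))


def _small_graph_stats(nodes, edge_set):
    """(connected?, sorted degree sequence, triangle count) of a graph given
    as an explicit node tuple and a set of frozenset edges."""
    k = len(nodes)
    adj = {v: set() for v in nodes}
    for e in edge_set:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    # connectivity by BFS
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    connected = len(seen) == k
    degs = tuple(sorted(len(adj[v]) for v in nodes))
    n_tri = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if b in adj[a] and c in adj[a] and c in adj[b]
    )
    return connected, degs, n_tri


@lru_cache(maxsize=None)
def _inclusion_matrix(k: int) -> np.ndarray:
    """Matrix M with M[i, j] = number of spanning subgraphs of catalog type j
    isomorphic to catalog type i, so that noninduced = M @ induced.

    Built by enumerating edge subsets of the prototypes; upper triangular
    under the catalog's edge-count ordering, hence invertible.
    """
    names = catalog(k)
    M = np.zeros((len(names), len(names)), dtype=np.int64)
    nodes = tuple(range(k))
    for j, host in enumerate(names):
        host_edges = [frozenset(e) for e in _PROTOTYPES[host]]
        for r in range(1, len(host_edges) + 1):
            for sub in itertools.combinations(host_edges, r):
                conn, degs, n_tri = _small_graph_stats(nodes, set(sub))
                if not conn:
                    continue
                cls = _classify(k, degs, n_tri)
                if cls is not None:
                    M[names.index(cls), j] += 1
    return M


# ---------------------------------------------------------------------------
# Fast counting from closed-form expressions.


def _edge_array(G: nx.Graph):
    """(n, m x 2 int array of edges over 0..n-1)."""
    idx = {v: i for i, v in enumerate(G)}
    edges = np.array(
        [(idx[u], idx[v]) for u, v in G.edges()], dtype=np.int64
    ).reshape(-1, 2)
    return len(idx), edges


def counts_from_edge_array(n: int, edges: np.ndarray, k: int) -> np.ndarray:
    """Induced connected k-subgraph counts for a graph given as an integer
    edge array on nodes 0..n-1.  This is the kernel behind
    :func:`count_induced` and the per-ego census."""
    names = catalog(k)
    if n < k:
        return np.zeros(len(names), dtype=np.int64)
    m = len(edges)
    if m == 0:
        return np.zeros(len(names), dtype=np.int64)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sp.csr_matrix(
        (np.ones(2 * m, dtype=np.int64), (rows, cols)), shape=(n, n)
    )
    A.data[:] = 1  # collapse any duplicate edges
    d = np.asarray(A.sum(axis=1)).ravel()
    C = A @ A  # common-neighbour counts; diagonal holds degrees
    tri_edge = A.multiply(C).tocsr()  # common neighbours per adjacent pair
    t3 = int(tri_edge.sum()) // 6
    choose2 = lambda x: x * (x - 1) // 2  # noqa: E731
    if k == 3:
        p2 = int(choose2(d).sum())
        return np.array([p2 - 3 * t3, t3], dtype=np.int64)

    tri_node = np.asarray(tri_edge.sum(axis=1)).ravel() // 2
    du, dv = d[edges[:, 0]], d[edges[:, 1]]
    p4_n = int(((du - 1) * (dv - 1)).sum()) - 3 * t3
    claw_n = int((d * (d - 1) * (d - 2) // 6).sum())
    # off-diagonal pairs only: subtract the diagonal's C(d_i, 2) terms
    c4_n = (int(choose2(C.data).sum()) - int(choose2(d).sum())) // 4
    paw_n = int((tri_node * (d - 2)).sum())
    diamond_n = int(choose2(tri_edge.data).sum()) // 2
    # K4: count each at its vertex of lowest degree-rank -- a K4 {v,a,b,c}
    # with v ranked lowest is a triangle among v's higher-ranked
    # neighbours.  Ranking by degree keeps those neighbour sets small even
    # around hubs (the standard degeneracy-ordering trick).
    k4 = 0
    cand = np.flatnonzero((tri_node >= 3) & (d >= 3))
    if len(cand):
        rank = np.empty(n, dtype=np.int64)
        rank[np.argsort(d, kind="stable")] = np.arange(n)
        dense_ok = n <= 4000
        B = None
        if dense_ok:
            B = np.zeros((n, n), dtype=np.float64)
            B[rows, cols] = 1.0
        indptr, indices = A.indptr, A.indices
        for v in cand:
            nbrs = indices[indptr[v]: indptr[v + 1]]
            later = nbrs[rank[nbrs] > rank[v]]
            if len(later) < 3:
                continue
            if B is not None:
                sub = B[later[:, None], later]
                k4 += int(round(((sub @ sub) * sub).sum())) // 6
            else:
                sub = A[later][:, later]
                k4 += int((sub @ sub).multiply(sub).sum()) // 6
    noninduced = np.array(
        [p4_n, claw_n, c4_n, paw_n, diamond_n, k4], dtype=np.int64
    )
    M = _inclusion_matrix(4)
    induced = np.linalg.solve(M.astype(float), noninduced.astype(float))
    return np.rint(induced).astype(np.int64)


def count_induced(G: nx.Graph, k: int) -> np.ndarray:
    """Counts of connected induced k-node subgraphs of ``G``, one entry per
    catalog class (graphs with fewer than k nodes give all zeros)."""
    catalog(k)  # validate k
    n, edges = _edge_array(G)
    return counts_from_edge_array(n, edges, k)


def count_by_enumeration(G: nx.Graph, k: int) -> np.ndarray:
    """Brute-force oracle: classify every connected k-subset explicitly."""
    names = catalog(k)
    counts = dict.fromkeys(names, 0)
    nodes = list(G)
    adj = {v: set(G[v]) for v in nodes}
    for subset in itertools.combinations(nodes, k):
        edge_set = {
            frozenset((u, v))
            for u, v in itertools.combinations(subset, 2)
            if v in adj[u]
        }
        if len(edge_set) < k - 1:
            continue  # cannot be connected
        conn, degs, n_tri = _small_graph_stats(subset, edge_set)
        if not conn:
            continue
        cls = _classify(k, degs, n_tri)
        counts[cls] += 1
    return np.array([counts[name] for name in names], dtype=np.int64)
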