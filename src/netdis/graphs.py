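"""Core graph handling: edge-list I/O, two-step ego-networks, density.

Graphs are plain :class:`networkx.Graph` objects with opaque string node
labels.  All inputs are treated as simple undirected graphs: self-loops are
dropped (with a logged count) and duplicate / reversed edges collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("netdis")

__all__ = [
    "EgoNetwork",
    "read_edge_list",
    "write_edge_list",
    "density",
    "two_step_ego",
    "two_step_ego_nodes",
    "adjacency_sets",
]


class EmptyGraphError(ValueError):
    """Raised when an input file describes no nodes and no edges."""


@dataclass(frozen=True)
class EgoNetwork:
    """A two-step ego-network: the induced subgraph on all nodes within two
    edges of ``ego``, including the ego itself and every edge among them."""

    ego: str
    graph: nx.Graph
    density: float


def density(G: nx.Graph) -> float:
    """Edge density 2|E| / (|V|(|V|-1)); 0 for graphs with fewer than 2 nodes."""
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def read_edge_list(path: str | Path, name: str | None = None) -> nx.Graph:
    """Read a whitespace-separated edge list into a simple undirected graph.

    One edge per line (extra tokens beyond the first two are ignored, with a
    one-time warning since they may be weights); ``#`` starts a comment line;
    a single-token line declares an isolated node.  Self-loop lines are
    dropped and counted in a warning.

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptyGraphError
        If the file contains no nodes and no edges.
    """
    path = Path(path)
    G = nx.Graph()
    n_self_loops = 0
    warned_extra = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) == 1:
                G.add_node(tokens[0])
                continue
            if len(tokens) > 2 and not warned_extra:
                logger.warning(
                    "%s: extra tokens on edge lines are ignored "
                    "(edge weights are not supported)", path
                )
                warned_extra = True
            u, v = tokens[0], tokens[1]
            if u == v:
                n_self_loops += 1
                G.add_node(u)
                continue
            G.add_edge(u, v)
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_self_loops)
    if G.number_of_nodes() == 0:
        raise EmptyGraphError(f"{path}: no nodes and no edges")
    G.graph["name"] = name if name is not None else path.stem
    return G


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    """Write a graph as a whitespace-separated edge list.

    Isolated nodes are written as single-token lines so that a round-trip
    preserves the node set exactly.
    """
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in G.edges()):
            fh.write(f"{u} {v}\n")
        for v in sorted(str(v) for v in nx.isolates(G)):
            fh.write(f"{v}\n")


def adjacency_sets(G: nx.Graph) -> dict:
    """Adjacency as a dict of neighbour sets (the workhorse representation
    for repeated ego-network extraction)."""
    return {v: set(G[v]) for v in G}


def two_step_ego_nodes(adj: Mapping, v) -> set:
    """Node set of the two-step ego-network of ``v``: all nodes at hop
    distance <= 2, including ``v`` itself.

    ``adj`` is an adjacency mapping as produced by :func:`adjacency_sets`.
    """
    if v not in adj:
        raise KeyError(f"node {v!r} not in graph")
    nodes = {v} | adj[v]
    for u in adj[v]:
        nodes |= adj[u]
    return nodes


def two_step_ego(G: nx.Graph, v) -> EgoNetwork:
    """Extract the two-step ego-network of ``v`` as an induced subgraph.

    Raises ``KeyError`` for a node not in ``G``.
    """
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    nodes = {v} | set(G[v])
    for u in set(G[v]):
        nodes |= set(G[u])
    sub = G.subgraph(nodes).copy()
    return EgoNetwork(ego=v, graph=sub, density=density(sub))


def ego_sizes(G: nx.Graph, nodes: Iterable | None = None) -> dict:
    """Two-step ego-network size (node count) for each requested node."""
    adj = adjacency_sets(G)
    targets = list(nodes) if nodes is not None else list(G)
    return {v: len(two_step_ego_nodes(adj, v)) for v in targets}
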