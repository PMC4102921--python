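"""Undirected simple-graph container and the edge-count primitives.

Every community definition in this package reduces to counting edges
inside a node set, leaving it, or running between two sets, so those
primitives live here next to the adjacency structure itself.  The graph
is deliberately minimal: an ordered node tuple, a dict of neighbor
sets, and the edge count.  Node identifiers are canonicalized to
strings so that mixed int/str input cannot perturb the (sorted) node
order the detection sweeps rely on.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

__all__ = [
    "Graph",
    "ComponentDecomposition",
    "GraphParseError",
    "build_graph",
    "connected_components",
    "shortest_path_length",
    "bfs_distances",
    "edge_counts",
    "edges_between",
]


class GraphParseError(ValueError):
    """Raised when raw edge data cannot be interpreted as (source, target) pairs."""


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with canonical (sorted) node order.

    Invariants: adjacency is symmetric, loop-free and duplicate-free;
    ``sum(degree) == 2 * m``.
    """

    nodes: Tuple[str, ...]
    adj: Dict[str, FrozenSet[str]]
    m: int

    def degree(self, v: str) -> int:
        return len(self.adj[v])

    def neighbors(self, v: str) -> FrozenSet[str]:
        return self.adj[v]

    def __contains__(self, v: object) -> bool:
        return v in self.adj

    @property
    def n(self) -> int:
        return len(self.nodes)

    def edges(self) -> List[Tuple[str, str]]:
        """Canonical edge list: each edge once, endpoints sorted, list sorted."""
        out = []
        for u in self.nodes:
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        out.sort()
        return out

    def isolated_nodes(self) -> Set[str]:
        return {v for v in self.nodes if not self.adj[v]}


@dataclass(frozen=True)
class ComponentDecomposition:
    """Connected components of size >= 2 plus the degree-0 nodes.

    Components are ordered by (size desc, smallest member id) so the
    decomposition is deterministic; singletons are reported as
    ``isolated``, never as one-node components.
    """

    components: Tuple[FrozenSet[str], ...]
    isolated: FrozenSet[str]


def _canon(token) -> str:
    return token if isinstance(token, str) else str(token)


def build_graph(
    edges: Iterable[Sequence],
    directed: bool = False,
    nodes: Iterable = (),
) -> Graph:
    """Build a canonical undirected simple graph from raw edge pairs.

    Self-loops are dropped, parallel/reciprocal edges collapse to one,
    and directed arcs are symmetrized.  ``nodes`` may add vertices that
    carry no edge (they surface later as isolated nodes).  The result
    depends only on the edge *set*, not on input order.
    """
    adj: Dict[str, Set[str]] = {}
    for v in nodes:
        adj.setdefault(_canon(v), set())
    for record in edges:
        try:
            u, v = record
        except (TypeError, ValueError):
            raise GraphParseError(
                f"edge record {record!r} is not a (source, target) pair"
            ) from None
        u, v = _canon(u), _canon(v)
        adj.setdefault(u, set())
        adj.setdefault(v, set())
        if u == v:
            continue  # self-regulation / self-loop: contributes no edge
        adj[u].add(v)
        adj[v].add(u)
    ordered = tuple(sorted(adj))
    frozen = {v: frozenset(adj[v]) for v in ordered}
    m = sum(len(s) for s in frozen.values()) // 2
    return Graph(nodes=ordered, adj=frozen, m=m)


def connected_components(g: Graph) -> ComponentDecomposition:
    seen: Set[str] = set()
    comps: List[FrozenSet[str]] = []
    isolated: Set[str] = set()
    for start in g.nodes:
        if start in seen:
            continue
        seen.add(start)
        if not g.adj[start]:
            isolated.add(start)
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for w in g.adj[u]:
                if w not in seen:
                    seen.add(w)
                    comp.add(w)
                    queue.append(w)
        comps.append(frozenset(comp))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ComponentDecomposition(components=tuple(comps), isolated=frozenset(isolated))


def bfs_distances(g: Graph, source: str) -> Dict[str, int]:
    """Unweighted BFS distances from ``source`` to every reachable node."""
    if source not in g.adj:
        raise KeyError(f"unknown node {source!r}")
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        d = dist[u] + 1
        for w in g.adj[u]:
            if w not in dist:
                dist[w] = d
                queue.append(w)
    return dist


def shortest_path_length(g: Graph, u: str, v: str) -> float:
    """BFS distance between u and v; ``math.inf`` across components."""
    if u not in g.adj:
        raise KeyError(f"unknown node {u!r}")
    if v not in g.adj:
        raise KeyError(f"unknown node {v!r}")
    if u == v:
        return 0
    dist = {u: 0}
    queue = deque([u])
    while queue:
        x = queue.popleft()
        d = dist[x] + 1
        for w in g.adj[x]:
            if w == v:
                return d
            if w not in dist:
                dist[w] = d
                queue.append(w)
    return math.inf


def edge_counts(g: Graph, S: Iterable[str]) -> Tuple[int, int]:
    """(internal, external) edge counts of a node set.

    internal: edges with both endpoints in S; external: edges with
    exactly one endpoint in S.
    """
    S = set(S)
    internal2 = 0
    external = 0
    for v in S:
        nbrs = g.adj[v]
        inside = len(nbrs & S)
        internal2 += inside
        external += len(nbrs) - inside
    return internal2 // 2, external


def edges_between(g: Graph, S: Iterable[str], T: Iterable[str]) -> int:
    """Edges with one endpoint in S and the other in T (S, T disjoint)."""
    S, T = set(S), set(T)
    if S & T:
        raise ValueError(f"node sets overlap: {sorted(S & T)}")
    return sum(len(g.adj[v] & T) for v in S)
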