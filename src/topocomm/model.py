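"""Community definitions: strong/weak sense, hubs, membership, overlap types.

A *strong-sense* community has strictly more internal edges than
external ones.  A *weak-sense* community fails that global test but
still has more internal edges than it shares with any single other
community.  A *hub member* is a node with the most neighbors inside
its community.  The *membership property* says every non-overlapping
node sits in the community holding the maximum number of its
neighbors.

Two kinds of overlapping nodes are recognised on a converged cover:

* type 1 — the node's maximum neighbor count is attained by two or
  more communities *and* its shortest-path distance to the hub members
  of those communities is the same for each of them;
* type 2 — a bridge node attached by at least two edges to each of two
  communities that would share fewer direct edges than either of those
  attachments if the node were removed.

The type-2 thresholds ("tightly" = >=2 edges into each side, "few" =
residual inter-community edges strictly below the node's smaller
attachment) are this package's parameter-free operationalization of a
qualitative definition; see docs/methods.md.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .graph import Graph, bfs_distances, edge_counts, edges_between

__all__ = [
    "Community",
    "Cover",
    "OverlapRecord",
    "is_strong_sense",
    "is_weak_sense",
    "hub_members",
    "membership_counts",
    "hub_distance",
    "classify_type1",
    "classify_type2",
    "classify_overlaps",
    "community_labels",
]

#: overlap-record types: 1 and 2 per the definitions above; 0 marks a
#: planted (ground-truth) overlap in a benchmark instance, where the
#: generator rather than the classifier decided the multi-membership.
OVERLAP_TYPES = (0, 1, 2)


@dataclass(frozen=True)
class OverlapRecord:
    node: str
    community_ids: FrozenSet[int]
    type: int

    def __post_init__(self):
        if self.type not in OVERLAP_TYPES:
            raise ValueError(f"overlap type must be one of {OVERLAP_TYPES}")
        if len(self.community_ids) < 2:
            raise ValueError("an overlap record must name at least 2 communities")


@dataclass(frozen=True)
class Community:
    id: int
    members: FrozenSet[str]
    hubs: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if not self.members:
            raise ValueError("community must be non-empty")
        if self.hubs and not self.hubs <= self.members:
            raise ValueError("hubs must be members")


@dataclass(frozen=True)
class Cover:
    """Detection output: communities, a primary assignment for every
    non-isolated node, overlap records, and the isolated nodes."""

    communities: Tuple[Community, ...]
    primary: Dict[str, int]
    overlaps: Tuple[OverlapRecord, ...] = ()
    isolated: FrozenSet[str] = frozenset()

    def community(self, cid: int) -> Community:
        for c in self.communities:
            if c.id == cid:
                return c
        raise KeyError(f"no community with id {cid}")

    def members_of(self, cid: int) -> FrozenSet[str]:
        return self.community(cid).members

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def sizes(self) -> List[int]:
        return [len(c.members) for c in self.communities]

    def as_partition(self) -> Dict[str, int]:
        """Flatten to a plain labeling: primary community for every
        non-isolated node, a unique singleton label per isolated node."""
        labels = dict(self.primary)
        next_id = min([-1] + [c.id for c in self.communities]) - 1
        for v in sorted(self.isolated):
            labels[v] = next_id
            next_id -= 1
        return labels


def is_strong_sense(g: Graph, S: Iterable[str]) -> bool:
    """True iff internal edge count strictly exceeds external edge count."""
    internal, external = edge_counts(g, S)
    return internal > external


def is_weak_sense(g: Graph, S: Iterable[str], others: Iterable[Iterable[str]]) -> bool:
    """True iff S is not strong-sense but beats every single other
    community: internal(S) <= external(S) and internal(S) >
    edges_between(S, T) for each T in ``others``."""
    S = set(S)
    internal, external = edge_counts(g, S)
    if internal > external:
        return False
    return all(internal > edges_between(g, S, T) for T in others)


def hub_members(g: Graph, S: Iterable[str]) -> FrozenSet[str]:
    """All members with the maximum number of neighbors inside S (ties kept)."""
    S = set(S)
    if not S:
        raise ValueError("community must be non-empty")
    counts = {v: len(g.adj[v] & S) for v in S}
    best = max(counts.values())
    return frozenset(v for v, c in counts.items() if c == best)


def membership_counts(g: Graph, v: str, cover: Cover) -> Dict[int, int]:
    """How many of v's neighbors fall in each community (by primary
    assignment).  Values sum to degree(v)."""
    return dict(Counter(cover.primary[u] for u in g.adj[v]))


def hub_distance(g: Graph, v: str, community: Community,
                 dist: Optional[Dict[str, int]] = None) -> float:
    """Shortest-path distance from v to the community's nearest hub.

    With several tied hubs the minimum over the hub set is used — the
    only choice that does not depend on hub enumeration order.
    """
    hubs = community.hubs or hub_members(g, community.members)
    if dist is None:
        dist = bfs_distances(g, v)
    return min((dist[h] for h in hubs if h in dist), default=float("inf"))


def classify_type1(g: Graph, v: str, cover: Cover) -> Optional[OverlapRecord]:
    """Type-1 test: >=2 communities tie for v's maximum neighbor count
    and v is equidistant from the hub members of all tied communities."""
    counts = membership_counts(g, v, cover)
    if not counts:
        return None
    best = max(counts.values())
    tied = sorted(cid for cid, c in counts.items() if c == best)
    if len(tied) < 2:
        return None
    dist = bfs_distances(g, v)
    dists = {hub_distance(g, v, cover.community(cid), dist) for cid in tied}
    if len(dists) == 1:
        return OverlapRecord(node=v, community_ids=frozenset(tied), type=1)
    return None


def classify_type2(g: Graph, v: str, cover: Cover) -> Optional[OverlapRecord]:
    """Type-2 test: v has >=2 edges into each of two communities whose
    residual direct connection (with v removed) is smaller than v's
    weaker attachment.  Among qualifying pairs the strongest bridge
    (largest min-attachment, then largest total, then smallest ids)
    is reported."""
    attach = {}
    for c in cover.communities:
        k = len(g.adj[v] & (c.members - {v}))
        if k >= 2:
            attach[c.id] = k
    if len(attach) < 2:
        return None
    best_pair = None
    best_key = None
    cids = sorted(attach)
    for i, a in enumerate(cids):
        for b in cids[i + 1:]:
            ka, kb = attach[a], attach[b]
            residual = edges_between(
                g,
                cover.members_of(a) - {v},
                cover.members_of(b) - {v},
            )
            if residual < min(ka, kb):
                key = (-min(ka, kb), -(ka + kb), a, b)
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (a, b)
    if best_pair is None:
        return None
    return OverlapRecord(node=v, community_ids=frozenset(best_pair), type=2)


def classify_overlaps(g: Graph, cover: Cover) -> Tuple[OverlapRecord, ...]:
    """Run the type-1 then type-2 classifier over every non-isolated
    node; a node carries at most one record."""
    records = []
    for v in g.nodes:
        if not g.adj[v]:
            continue
        rec = classify_type1(g, v, cover) or classify_type2(g, v, cover)
        if rec is not None:
            records.append(rec)
    return tuple(records)


def community_labels(g: Graph, cover: Cover) -> Dict[int, str]:
    """Label each community 'strong', 'weak' or 'neither' by the
    structure predicates, judged against the other communities of the
    same cover."""
    sets = {c.id: set(c.members) for c in cover.communities}
    labels = {}
    for cid, S in sets.items():
        others = [T for oid, T in sets.items() if oid != cid]
        if is_strong_sense(g, S):
            labels[cid] = "strong"
        elif is_weak_sense(g, S, others):
            labels[cid] = "weak"
        else:
            labels[cid] = "neither"
    return labels
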