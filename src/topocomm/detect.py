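"""The four-stage detection pipeline.

1. *Initialize*: the closed neighborhood of every node (its adjacency
   list plus the node itself) becomes a seed candidate, with cached
   internal/external edge counts.
2. *Strong seeds*: candidates are scanned greedily in a fixed order —
   (internal − external) descending, internal descending, anchor id
   ascending.  The unclaimed part of a candidate first sheds members
   with strictly more neighbors outside the set than inside; if the
   result is not yet strong-sense it is expanded by merging in the
   unclaimed neighbor that most improves internal − external, until it
   turns strong.  A candidate that is merely several strong
   communities glued at its anchor is rejected (its pieces seed
   separately); a residual that turns strong only by borrowing one
   claimed, tightly-attached bridge node seeds on its own, the bridge
   staying put for the overlap classifier.  A component in which no
   candidate survives contributes its single best candidate as a
   fallback seed, so every component is seeded.
3. *Weak growth*: every remaining node joins the seed community
   holding the most of its neighbors (ties: nearest hub, then smallest
   community id); nodes with no assigned neighbor yet are deferred and
   picked up on a later sweep, so chains hanging off a community are
   absorbed link by link.
4. *Membership iteration*: asynchronous sweeps in canonical node order
   move each node to its maximum-membership community until a full
   pass makes no move (or a safety cap of 100 passes).  Emptied
   communities are deleted.

All order choices are fixed by the canonical (sorted) node order, so
for a given topology the output is deterministic and invariant to the
order edges were supplied in.  Overlap classification runs once, on
the converged cover.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .graph import (
    Graph,
    bfs_distances,
    connected_components,
    edge_counts,
)
from .model import Community, Cover, classify_overlaps, hub_members

__all__ = [
    "SeedCandidate",
    "DetectionTrace",
    "seed_candidates",
    "extract_strong_seeds",
    "grow_weak_communities",
    "reassign_to_convergence",
    "detect_communities",
]

MAX_PASSES = 100


@dataclass(frozen=True)
class SeedCandidate:
    """Closed neighborhood of one node, with cached edge counts."""

    anchor: str
    members: FrozenSet[str]
    internal: int
    external: int

    @property
    def score(self) -> int:
        return self.internal - self.external


@dataclass
class DetectionTrace:
    """Observability record of the iterative stage."""

    passes: int = 0
    moves_per_pass: List[int] = field(default_factory=list)
    converged: bool = False


def seed_candidates(g: Graph) -> List[SeedCandidate]:
    """One candidate per non-isolated node, in canonical node order."""
    out = []
    for v in g.nodes:
        if not g.adj[v]:
            continue
        members = frozenset(g.adj[v]) | {v}
        internal, external = edge_counts(g, members)
        out.append(SeedCandidate(anchor=v, members=members,
                                 internal=internal, external=external))
    return out


def _candidate_order(c: SeedCandidate):
    return (-(c.internal - c.external), -c.internal, c.anchor)


def _trim_violators(g: Graph, members: Set[str], anchor: str) -> Set[str]:
    """Drop members that already break the membership property inside
    the candidate: strictly more neighbors outside the set than inside.

    A closed neighborhood sweeps up every neighbor of the anchor, even
    peripheral nodes whose own edges point elsewhere; keeping such
    nodes in a seed plants them on the wrong side of a boundary, and
    the later majority dynamics can then lock them in.  Nodes whose
    inside/outside counts tie are kept (ties are legitimate and are
    resolved by hub distance later).  The anchor is never dropped;
    removal is iterated to a fixpoint in canonical order.
    """
    members = set(members)
    changed = True
    while changed:
        changed = False
        for v in sorted(members):
            if v == anchor:
                continue
            inside = len(g.adj[v] & members)
            if inside < g.degree(v) - inside:
                members.discard(v)
                changed = True
    return members


def _expand_until_strong(g: Graph, S: Set[str], claimed: Set[str]) -> Optional[Set[str]]:
    """Merge unclaimed neighbors into S, best-attached first, until the
    set becomes strong-sense.

    A single adjacency list is rarely a strong-sense set inside a
    large sparse community — most of its edges run to the rest of the
    *same* community and count as external — so the candidate is
    enlarged one node at a time, always taking the unclaimed node with
    the best effect on internal − external (then highest attachment,
    then smallest id).  Preferring that delta over raw attachment
    keeps the expansion from drifting across a community boundary:
    outside nodes carry many edges that would become external.
    Returns the strong set, or None when the set runs out of attached
    unclaimed nodes before turning strong.
    """
    S = set(S)
    internal, external = edge_counts(g, S)
    # attachment counts of the unclaimed boundary, kept incrementally
    gains: Dict[str, int] = {}
    for v in S:
        for w in g.adj[v]:
            if w not in S and w not in claimed:
                gains[w] = gains.get(w, 0) + 1
    while internal <= external:
        best = None  # (neg delta, neg gain, node); delta = 3*gain - deg
        for w, gain in gains.items():
            key = (g.degree(w) - 3 * gain, -gain, w)
            if best is None or key < best:
                best = key
        if best is None:
            return None
        _, neg_gain, w = best
        gain = -neg_gain
        S.add(w)
        del gains[w]
        internal += gain
        external += g.degree(w) - 2 * gain
        for x in g.adj[w]:
            if x not in S and x not in claimed:
                gains[x] = gains.get(x, 0) + 1
    return S


def _is_anchor_glued(g: Graph, S: Set[str], anchor: str) -> bool:
    """True when S is really several strong communities sharing only
    the anchor: S minus the anchor falls into >=2 connected pieces and
    every piece, with the anchor added back, is strong-sense on its
    own.  Such a candidate must not become one seed — its pieces seed
    separately and the anchor surfaces as an overlapping node."""
    rest = S - {anchor}
    pieces: List[Set[str]] = []
    todo = set(rest)
    while todo:
        start = todo.pop()
        piece = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in g.adj[u] & rest:
                if w not in piece:
                    piece.add(w)
                    stack.append(w)
        todo -= piece
        pieces.append(piece)
    if len(pieces) < 2:
        return False
    for piece in pieces:
        internal, external = edge_counts(g, piece | {anchor})
        if internal <= external:
            return False
    return True


def _single_bridge_rescue(g: Graph, R: Set[str], claimed: Set[str]) -> bool:
    """True when R becomes strong-sense by borrowing one already-claimed
    node tightly attached to it (>=2 edges).  The bridge stays with its
    own community; R seeds on its own and the bridge is left for the
    overlap classifier."""
    bridges = sorted(
        (b for b in claimed if len(g.adj[b] & R) >= 2),
        key=lambda b: (-len(g.adj[b] & R), b),
    )
    for b in bridges[:8]:
        internal, external = edge_counts(g, R | {b})
        if internal > external:
            return True
    return False


def extract_strong_seeds(
    g: Graph, candidates: Sequence[SeedCandidate]
) -> List[Set[str]]:
    """Greedy disjoint strong-sense seed extraction with per-component
    fallback (see module docstring for the exact ordering)."""
    seeds: List[Set[str]] = []
    claimed: Set[str] = set()
    for cand in sorted(candidates, key=_candidate_order):
        residual = set(cand.members) - claimed
        if len(residual) < 2 or cand.anchor not in residual:
            continue
        core = _trim_violators(g, residual, cand.anchor)
        internal, external = edge_counts(g, core)
        if internal > external and len(core) >= 2:
            if _is_anchor_glued(g, core, cand.anchor):
                continue
        else:
            expanded = _expand_until_strong(g, core, claimed)
            if expanded is None or len(expanded) < 2:
                if (len(core) >= 2
                        and _single_bridge_rescue(g, core, claimed)):
                    seeds.append(core)
                    claimed |= core
                continue
            core = expanded
        seeds.append(core)
        claimed |= core
    # every component must carry at least one seed
    for comp in connected_components(g).components:
        if not any(seed <= comp for seed in seeds) and not (claimed & comp):
            comp_cands = [c for c in candidates if c.anchor in comp]
            best = min(comp_cands, key=_candidate_order)
            seeds.append(set(best.members))
            claimed |= best.members
    return seeds


def _hub_distance_to_set(g: Graph, v: str, members: Set[str],
                         dist_cache: Dict[str, Dict[str, int]]) -> float:
    if v not in dist_cache:
        dist_cache[v] = bfs_distances(g, v)
    dist = dist_cache[v]
    hubs = hub_members(g, members)
    return min((dist[h] for h in hubs if h in dist), default=float("inf"))


def _choose(g: Graph, v: str, counts: Dict[int, int],
            comms: Dict[int, Set[str]],
            dist_cache: Dict[str, Dict[str, int]]) -> int:
    """Maximum-membership community; ties broken by nearest hub, then
    smallest community id."""
    best = max(counts.values())
    tied = sorted(cid for cid, c in counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda cid: (
        _hub_distance_to_set(g, v, comms[cid], dist_cache), cid))


def grow_weak_communities(g: Graph, seeds: Sequence[Iterable[str]]) -> Cover:
    """Grow the seed sets over the whole graph by the membership rule.

    Assignments made earlier in a sweep are visible to later nodes, so
    nodes whose neighbors are all unassigned get claimed on a later
    sweep once the frontier reaches them.
    """
    comms: Dict[int, Set[str]] = {i: set(s) for i, s in enumerate(seeds)}
    primary: Dict[str, int] = {}
    for cid, members in comms.items():
        for v in members:
            primary[v] = cid
    isolated = frozenset(g.isolated_nodes())
    pending = [v for v in g.nodes if v not in primary and v not in isolated]
    dist_cache: Dict[str, Dict[str, int]] = {}
    while pending:
        progressed = False
        still = []
        for v in pending:
            counts = Counter(primary[u] for u in g.adj[v] if u in primary)
            if not counts:
                still.append(v)
                continue
            cid = _choose(g, v, counts, comms, dist_cache)
            comms[cid].add(v)
            primary[v] = cid
            progressed = True
        if not progressed:  # unreachable when every component is seeded
            raise RuntimeError(
                f"growth stalled with {len(still)} unclaimed nodes")
        pending = still
    return _finalize(g, comms, primary, isolated, classify=False)


def reassign_to_convergence(g: Graph, cover: Cover) -> Tuple[Cover, DetectionTrace]:
    """Iterate the membership property to a fixpoint.

    Asynchronous sweeps in canonical node order: a node moves to the
    community with the maximum number of its neighbors; if its current
    community ties that maximum and is a nearest-hub community among
    the ties, it stays.  Emptied communities are removed.  Stops on a
    zero-move pass or at the pass cap.
    """
    comms: Dict[int, Set[str]] = {c.id: set(c.members) for c in cover.communities}
    primary = dict(cover.primary)
    trace = DetectionTrace()
    sweep_nodes = [v for v in g.nodes if v in primary]
    for _ in range(MAX_PASSES):
        moves = 0
        dist_cache: Dict[str, Dict[str, int]] = {}
        for v in sweep_nodes:
            cur = primary[v]
            counts = Counter(primary[u] for u in g.adj[v])
            if not counts:
                continue
            best = max(counts.values())
            tied = sorted(cid for cid, c in counts.items() if c == best)
            if cur in tied:
                if len(tied) == 1:
                    continue
                key = lambda cid: (_hub_distance_to_set(g, v, comms[cid], dist_cache), cid)
                target = min(tied, key=key)
                if key(cur) == key(target):
                    continue
            else:
                target = _choose(g, v, counts, comms, dist_cache)
            comms[cur].discard(v)
            comms[target].add(v)
            primary[v] = target
            if not comms[cur]:
                del comms[cur]
            moves += 1
        trace.passes += 1
        trace.moves_per_pass.append(moves)
        if moves == 0:
            trace.converged = True
            break
    new_cover = _finalize(g, comms, primary, cover.isolated, classify=False)
    return new_cover, trace


def _finalize(g: Graph, comms: Dict[int, Set[str]], primary: Dict[str, int],
              isolated: FrozenSet[str], classify: bool) -> Cover:
    """Renumber communities canonically (component order, then size
    desc, then smallest member), compute hubs, optionally classify
    overlaps."""
    decomp = connected_components(g)
    comp_index = {}
    for i, comp in enumerate(decomp.components):
        for v in comp:
            comp_index[v] = i
    ordered = sorted(
        comms.items(),
        key=lambda kv: (comp_index[min(kv[1])], -len(kv[1]), min(kv[1])),
    )
    remap = {old: new for new, (old, _) in enumerate(ordered)}
    communities = tuple(
        Community(id=remap[old], members=frozenset(members),
                  hubs=hub_members(g, members))
        for old, members in ordered
    )
    new_primary = {v: remap[cid] for v, cid in primary.items()}
    cover = Cover(communities=communities, primary=new_primary,
                  overlaps=(), isolated=frozenset(isolated))
    if classify:
        cover = Cover(communities=communities, primary=new_primary,
                      overlaps=classify_overlaps(g, cover),
                      isolated=frozenset(isolated))
    return cover


def detect_communities(
    g: Graph, return_trace: bool = False
) -> Cover | Tuple[Cover, DetectionTrace]:
    """Run the full pipeline: seeds, growth, membership iteration,
    overlap classification."""
    if g.n == 0:
        empty = Cover(communities=(), primary={}, overlaps=(), isolated=frozenset())
        return (empty, DetectionTrace(converged=True)) if return_trace else empty
    isolated = frozenset(g.isolated_nodes())
    if len(isolated) == g.n:
        cover = Cover(communities=(), primary={}, overlaps=(), isolated=isolated)
        return (cover, DetectionTrace(converged=True)) if return_trace else cover
    seeds = extract_strong_seeds(g, seed_candidates(g))
    grown = grow_weak_communities(g, seeds)
    converged, trace = reassign_to_convergence(g, grown)
    final = _finalize(
        g,
        {c.id: set(c.members) for c in converged.communities},
        dict(converged.primary),
        converged.isolated,
        classify=True,
    )
    return (final, trace) if return_trace else final
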