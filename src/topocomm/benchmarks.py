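"""Synthetic graphs with planted ground truth.

Two generator families:

* planted-partition graphs — ``l`` groups of ``size`` nodes with
  independent Bernoulli edges, probability ``p_in`` within a group and
  ``p_out`` between groups;
* LFR-style benchmark graphs — power-law degree sequence (exponent
  ``tau1``, truncated at ``max_k``, mean ``avg_k``), power-law
  community sizes (exponent ``tau2``) bounded by ``[min_c, max_c]``, a
  mixing parameter ``mu`` giving the fraction of each node's edges
  that leave its community, and ``on`` overlapping nodes holding
  ``om`` community memberships with their internal edges split evenly
  across them.

Edges are realised by configuration-model stub matching with
swap-repair of self-loops, duplicate edges and (for the inter-community
stubs) accidental within-community pairs, falling back to a randomized
Havel-Hakimi construction; internal stubs that prove non-graphical are
recycled into the external budget, so realised edge counts sit within
a fraction of a percent of the stub budget.  All randomness flows from
one explicit integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .graph import Graph, build_graph
from .model import Community, Cover, OverlapRecord

__all__ = [
    "LFRParams",
    "BenchmarkInstance",
    "GenerationError",
    "LFR_128",
    "generate_planted_partition",
    "generate_lfr",
]


class GenerationError(RuntimeError):
    """Raised when a feasible instance cannot be built within bounded retries."""


@dataclass(frozen=True)
class LFRParams:
    """Parameters of the LFR-style benchmark family.

    ``on`` overlapping nodes each belong to ``om`` communities.  The
    power-law exponents default to tau1=2 (degrees) and tau2=1
    (community sizes), the canonical choices for this benchmark family.
    """

    n: int
    avg_k: float
    max_k: int
    mu: float
    min_c: int
    max_c: int
    on: int = 0
    om: int = 2
    tau1: float = 2.0
    tau2: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (1 <= self.min_c <= self.max_c <= self.n):
            raise ValueError("need 1 <= min_c <= max_c <= n")
        if not (0 < self.avg_k <= self.max_k):
            raise ValueError("need 0 < avg_k <= max_k")
        if not (0 <= self.on <= self.n):
            raise ValueError("need 0 <= on <= n")
        if self.om < 2:
            raise ValueError("overlapping nodes need om >= 2 memberships")


#: The 128-node study configuration: mean degree 9.328, max degree 30,
#: mixing 0.1, community sizes between 10 and 30, ten overlapping
#: nodes with two memberships each.
LFR_128 = LFRParams(n=128, avg_k=9.328, max_k=30, mu=0.1,
                    min_c=10, max_c=30, on=10, om=2)


@dataclass(frozen=True)
class BenchmarkInstance:
    graph: Graph
    truth: Cover
    params: Dict
    seed: int


def _node_ids(n: int) -> List[str]:
    width = len(str(n - 1))
    return [f"{i:0{width}d}" for i in range(n)]


def generate_planted_partition(
    l: int, size: int, p_in: float, p_out: float, seed: int
) -> BenchmarkInstance:
    """Planted-partition graph: ``l`` groups of ``size`` nodes each."""
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ValueError("edge probabilities must lie in [0, 1]")
    if l * size < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    n = l * size
    ids = _node_ids(n)
    group = np.repeat(np.arange(l), size)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(group[iu] == group[ju], p_in, p_out)
    keep = rng.random(p.shape) < p
    edges = [(ids[i], ids[j]) for i, j in zip(iu[keep], ju[keep])]
    g = build_graph(edges, nodes=ids)
    communities = tuple(
        Community(id=c, members=frozenset(ids[c * size:(c + 1) * size]))
        for c in range(l)
    )
    primary = {ids[i]: int(group[i]) for i in range(n)}
    truth = Cover(communities=communities, primary=primary,
                  overlaps=(), isolated=frozenset())
    params = {"family": "planted_partition", "l": l, "size": size,
              "p_in": p_in, "p_out": p_out}
    return BenchmarkInstance(graph=g, truth=truth, params=params, seed=seed)


# ---------------------------------------------------------------------------
# power-law sampling helpers


def _rounded_powerlaw_pmf(xmin: float, xmax: float, tau: float) -> Tuple[np.ndarray, np.ndarray]:
    """PMF over integers of a continuous power law on [xmin, xmax+0.5)
    rounded to the nearest integer."""
    ks = np.arange(max(1, int(np.floor(xmin))), int(xmax) + 1)

    def cdf(x):
        x = np.clip(x, xmin, xmax + 0.5)
        if abs(tau - 1.0) < 1e-12:
            return np.log(x / xmin) / np.log((xmax + 0.5) / xmin)
        a, b = xmin ** (1 - tau), (xmax + 0.5) ** (1 - tau)
        return (x ** (1 - tau) - a) / (b - a)

    lo = cdf(ks - 0.5)
    hi = cdf(ks + 0.5)
    pmf = np.maximum(hi - lo, 0.0)
    total = pmf.sum()
    if total <= 0:
        raise GenerationError("degenerate power-law support")
    return ks, pmf / total


def _solve_xmin_for_mean(target: float, xmax: int, tau: float) -> float:
    """Lower cutoff of the rounded truncated power law whose mean is
    ``target`` (bisection; the mean is monotone in the cutoff)."""

    def mean(xmin: float) -> float:
        ks, pmf = _rounded_powerlaw_pmf(xmin, xmax, tau)
        return float((ks * pmf).sum())

    lo, hi = 1.0, float(xmax)
    if target <= mean(lo) or target >= mean(hi):
        raise GenerationError(
            f"mean degree {target} unreachable with max degree {xmax}")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_powerlaw_ints(rng, xmin: float, xmax: int, tau: float, n: int) -> np.ndarray:
    ks, pmf = _rounded_powerlaw_pmf(xmin, xmax, tau)
    return rng.choice(ks, size=n, p=pmf)


def _degree_sequence(rng, p: LFRParams) -> np.ndarray:
    """Power-law degrees whose *expected* value is exactly avg_k.

    The lower cutoff is solved so the truncated, rounded power law has
    mean avg_k, which also handles non-integer avg_k; the realized sum
    then fluctuates around n*avg_k as it should across seeds.  Only
    parity is fixed (one stub added to the smallest node below the
    degree cap), so no node is pushed artificially to max_k.
    """
    xmin = _solve_xmin_for_mean(p.avg_k, p.max_k, p.tau1)
    deg = _sample_powerlaw_ints(rng, xmin, p.max_k, p.tau1, p.n).astype(int)
    if int(deg.sum()) % 2:
        candidates = np.flatnonzero(deg < p.max_k)
        if len(candidates) == 0:
            raise GenerationError("cannot fix degree-sum parity at the cap")
        deg[candidates[int(np.argmin(deg[candidates]))]] += 1
    return deg


def _community_sizes(rng, p: LFRParams, slots: int) -> List[int]:
    """Power-law community sizes summing exactly to ``slots``.

    Sizes are drawn until the running sum reaches the membership
    budget; the overshoot is shaved off the largest communities (they
    stay >= min_c).  Returns sizes in draw order.
    """
    for _ in range(200):
        sizes: List[int] = []
        total = 0
        while total < slots:
            s = int(_sample_powerlaw_ints(rng, p.min_c, p.max_c, p.tau2, 1)[0])
            sizes.append(s)
            total += s
        excess = total - slots
        slack = sum(s - p.min_c for s in sizes)
        if slack < excess:
            continue
        while excess > 0:
            i = int(np.argmax(sizes))
            take = min(excess, sizes[i] - p.min_c)
            if take == 0:
                i = max(range(len(sizes)),
                        key=lambda j: sizes[j] - p.min_c)
                take = min(excess, sizes[i] - p.min_c)
            sizes[i] -= take
            excess -= take
        return sizes
    raise GenerationError("could not draw a feasible community-size sequence")


def _internal_degrees(rng, deg: np.ndarray, mu: float) -> np.ndarray:
    """Integer internal degrees (1-mu)*k under stochastic rounding, so
    the expected realized mixing is mu rather than the nearest-integer
    quantization of it (at avg_k ~ 9 deterministic rounding would give
    most nodes exactly one external stub and bias the mixing upward)."""
    exact = (1.0 - mu) * deg
    base = np.floor(exact).astype(int)
    frac = exact - base
    return base + (rng.random(len(deg)) < frac).astype(int)


def _assign_memberships(
    rng, p: LFRParams, deg: np.ndarray, d_int: np.ndarray, sizes: List[int]
) -> Tuple[List[List[int]], List[int]]:
    """Seat every node in 1 community (overlapping nodes in ``om``),
    respecting capacities and the constraint that a node's internal
    degree within a community is at most size-1.

    Returns (memberships per node, overlap node indices).
    """
    n = p.n
    sizes = list(sizes)
    # a node of internal degree d needs a community of size >= d+1
    dmax = int(d_int.max()) if n else 0
    if max(sizes) < dmax + 1:
        if dmax + 1 > p.max_c:
            raise GenerationError(
                f"internal degree {dmax} exceeds the largest admissible community")
        need = dmax + 1 - max(sizes)
        big = int(np.argmax(sizes))
        for _ in range(need):
            donors = [j for j in range(len(sizes))
                      if j != big and sizes[j] > p.min_c]
            if not donors:
                raise GenerationError("cannot enlarge a community to seat the hub node")
            j = max(donors, key=lambda j: sizes[j])
            sizes[j] -= 1
            sizes[big] += 1

    eligible = np.flatnonzero(d_int >= p.om)
    if len(eligible) < p.on:
        raise GenerationError(
            "not enough nodes with internal degree >= om to plant overlaps")
    overlap_nodes = sorted(rng.choice(eligible, size=p.on, replace=False).tolist())
    overlap_set = set(overlap_nodes)

    for attempt in range(50):
        capacity = list(sizes)
        memberships: List[Optional[List[int]]] = [None] * n
        # seat high-internal-degree nodes first; they are the constrained ones
        order = sorted(range(n), key=lambda v: -d_int[v])
        ok = True
        for v in order:
            want = p.om if v in overlap_set else 1
            # internal degree demanded from each membership community
            per = _split_internal(int(d_int[v]), want)
            feas = [c for c in range(len(sizes))
                    if capacity[c] >= 1 and sizes[c] - 1 >= max(per)]
            if len(feas) < want:
                ok = False
                break
            weights = np.array([capacity[c] for c in feas], dtype=float)
            chosen = rng.choice(feas, size=want, replace=False,
                                p=weights / weights.sum())
            memberships[v] = sorted(int(c) for c in chosen)
            for c in memberships[v]:
                capacity[c] -= 1
        if ok and all(c == 0 for c in capacity):
            return [list(ms) for ms in memberships], overlap_nodes
        # tight capacities can strand the last few nodes; redraw
    raise GenerationError("membership assignment failed after bounded retries")


def _split_internal(d: int, parts: int) -> List[int]:
    base, rem = divmod(d, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _eg_violation(demands: List[int]) -> bool:
    """Erdős–Gallai test: True when the demand multiset cannot be
    realized as a simple graph on its own nodes."""
    d = sorted(demands, reverse=True)
    if sum(d) % 2:  # parity fixed later; ignore here
        d = list(d)
    prefix = 0
    for k in range(1, len(d) + 1):
        prefix += d[k - 1]
        tail = sum(min(x, k) for x in d[k:])
        if prefix > k * (k - 1) + tail:
            return True
    return False


def _repair_graphicality(d_int, memberships: List[List[int]],
                         overlap_nodes: List[int], max_swaps: int = 200) -> None:
    """Swap members between communities until every community's
    internal degree demand is graphical (best effort, bounded).

    A community fails Erdős–Gallai when near-complete members (demand
    close to size-1) coexist with members too small to reciprocate;
    replacing the smallest-demand member with a larger-demand node
    from another community raises the bottom of the sequence.  Only
    single-membership nodes are swapped.  Mutates ``memberships``.
    """
    overlap = set(overlap_nodes)
    comm: Dict[int, List[int]] = {}
    for v, ms in enumerate(memberships):
        for c in ms:
            comm.setdefault(c, []).append(v)

    def demand(v: int, c: int) -> int:
        ms = memberships[v]
        return _split_internal(int(d_int[v]), len(ms))[ms.index(c)]

    budget = max_swaps
    for _round in range(10):
        dirty = [c for c in comm
                 if _eg_violation([demand(v, c) for v in comm[c]])]
        if not dirty or budget <= 0:
            break
        for c in dirty:
            while budget > 0 and _eg_violation([demand(v, c) for v in comm[c]]):
                size_c = len(comm[c])
                plain = [v for v in comm[c] if v not in overlap]
                if not plain:
                    break
                u = min(plain, key=lambda v: (d_int[v], v))
                best = None
                for b, members in comm.items():
                    if b == c or d_int[u] > len(members) - 1:
                        continue
                    for w in members:
                        if (w in overlap or len(memberships[w]) != 1
                                or d_int[w] <= d_int[u]
                                or d_int[w] > size_c - 1):
                            continue
                        if best is None or d_int[w] > d_int[best[1]]:
                            best = (b, w)
                if best is None:
                    break
                b, w = best
                comm[c].remove(u)
                comm[c].append(w)
                comm[b].remove(w)
                comm[b].append(u)
                memberships[u] = [b]
                memberships[w] = [c]
                budget -= 1


def _norm(u: int, v: int) -> Tuple[int, int]:
    return (u, v) if u <= v else (v, u)


def _havel_hakimi(rng, demand: Dict[int, int], valid) -> List[Tuple[int, int]]:
    """Realize a degree demand as simple edges, highest demand first
    (randomized tie order).  Succeeds fully whenever the demand is
    graphical under ``valid``; otherwise realizes a maximal part."""
    demand = {v: d for v, d in demand.items() if d > 0}
    edges: List[Tuple[int, int]] = []
    used: Set[Tuple[int, int]] = set()
    while True:
        live = [v for v, d in demand.items() if d > 0]
        if len(live) < 2:
            break
        rng.shuffle(live)
        live.sort(key=lambda v: -demand[v])
        u = live[0]
        partners = [w for w in live[1:]
                    if _norm(u, w) not in used and valid(u, w)][: demand[u]]
        if not partners:
            demand[u] = 0  # cannot be seated; leftover handled by caller
            continue
        for w in partners:
            edges.append((u, w))
            used.add(_norm(u, w))
            demand[w] -= 1
        demand[u] -= len(partners)
    return edges


def _match_stubs(rng, stubs: List[int], ok_pair, edge_set: Set[Tuple[int, int]],
                 restarts: int = 3) -> Tuple[List[Tuple[int, int]], List[int]]:
    """Pair up stubs into simple edges; returns (edges, leftover stubs).

    ``ok_pair(u, v)`` encodes validity beyond simplicity (e.g. the two
    endpoints must not share a community).  Invalid pairs (self-loops,
    duplicates, ok_pair failures) are repaired by swapping an endpoint
    with an accepted edge, scanning accepted edges in random order and
    trying both swap orientations; repair passes repeat while they
    make progress, and a failed matching is restarted from a fresh
    shuffle.  If pairs still cannot be placed, the whole stub multiset
    is rebuilt by a randomized Havel-Hakimi construction, which
    realizes the demand exactly whenever it is graphical.  Stubs that
    remain (a genuinely non-graphical demand) come back as leftovers
    for the caller to recycle.
    """

    def attempt():
        order = list(stubs)
        rng.shuffle(order)
        local: Set[Tuple[int, int]] = set()

        def valid(u, v):
            key = _norm(u, v)
            return (u != v and key not in local and key not in edge_set
                    and ok_pair(u, v))

        good: List[Tuple[int, int]] = []
        bad: List[Tuple[int, int]] = []
        for i in range(0, len(order) - 1, 2):
            u, v = order[i], order[i + 1]
            if valid(u, v):
                local.add(_norm(u, v))
                good.append((u, v))
            else:
                bad.append((u, v))
        while bad:
            progressed = False
            still: List[Tuple[int, int]] = []
            for u, v in bad:
                placed = False
                scan = list(range(len(good)))
                rng.shuffle(scan)
                for j in scan:
                    x, y = good[j]
                    for a, b, c, d in ((u, y, x, v), (u, x, y, v)):
                        if (valid(a, b) and valid(c, d)
                                and _norm(a, b) != _norm(c, d)):
                            local.discard(_norm(x, y))
                            local.add(_norm(a, b))
                            local.add(_norm(c, d))
                            good[j] = (c, d)
                            good.append((a, b))
                            placed = True
                            break
                    if placed:
                        break
                if placed:
                    progressed = True
                else:
                    still.append((u, v))
            bad = still
            if not progressed:
                break
        return good, bad

    target = len(stubs) // 2
    best_good, best_bad = attempt()
    for _ in range(restarts - 1):
        if not best_bad:
            break
        good, bad = attempt()
        if len(good) > len(best_good):
            best_good, best_bad = good, bad
    if best_bad:
        # rebuild the whole matching degree-first
        demand: Dict[int, int] = {}
        for v in stubs:
            demand[v] = demand.get(v, 0) + 1
        local: Set[Tuple[int, int]] = set()

        def valid(u, v):
            key = _norm(u, v)
            return (u != v and key not in local and key not in edge_set
                    and ok_pair(u, v))

        hh = []
        for u, v in _havel_hakimi(rng, dict(demand), valid):
            local.add(_norm(u, v))
            hh.append((u, v))
        if len(hh) > len(best_good):
            best_good = hh
    leftover_count: Dict[int, int] = {}
    for v in stubs:
        leftover_count[v] = leftover_count.get(v, 0) + 1
    for u, v in best_good:
        edge_set.add(_norm(u, v))
        leftover_count[u] -= 1
        leftover_count[v] -= 1
    leftovers = [v for v, d in leftover_count.items() for _ in range(d)]
    return best_good, leftovers


def generate_lfr(params: LFRParams, seed: int) -> BenchmarkInstance:
    """Generate one LFR-style benchmark instance with planted truth."""
    p = params
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        try:
            return _generate_lfr_once(p, rng, seed)
        except GenerationError:
            if attempt == 19:
                raise
    raise GenerationError("unreachable")


def _generate_lfr_once(p: LFRParams, rng, seed: int) -> BenchmarkInstance:
    deg = _degree_sequence(rng, p)
    d_int = _internal_degrees(rng, deg, p.mu)
    slots = p.n + p.on * (p.om - 1)
    sizes = _community_sizes(rng, p, slots)
    memberships, overlap_nodes = _assign_memberships(rng, p, deg, d_int, sizes)
    _repair_graphicality(d_int, memberships, overlap_nodes)

    k = len(sizes)
    # per-(node, community) internal stub budget
    int_stubs: List[Dict[int, int]] = []
    ext_stubs = np.zeros(p.n, dtype=int)
    for v in range(p.n):
        per = _split_internal(int(d_int[v]), len(memberships[v]))
        int_stubs.append(dict(zip(memberships[v], per)))
        ext_stubs[v] = deg[v] - d_int[v]

    # parity fix: each community's internal stub total must be even;
    # shift one stub of the heaviest member to its external budget
    comm_members: List[List[int]] = [[] for _ in range(k)]
    for v in range(p.n):
        for c in memberships[v]:
            comm_members[c].append(v)
    for c in range(k):
        total = sum(int_stubs[v][c] for v in comm_members[c])
        if total % 2:
            v = max(comm_members[c],
                    key=lambda u: (int_stubs[u][c], -u))
            int_stubs[v][c] -= 1
            if p.mu > 0:
                ext_stubs[v] += 1
            else:
                deg[v] -= 1  # at mu=0 no edge may leave a community
    if int(ext_stubs.sum()) % 2:
        v = int(np.argmax(ext_stubs))
        ext_stubs[v] -= 1

    node_comms = [set(ms) for ms in memberships]
    edge_set: Set[Tuple[int, int]] = set()
    edges: List[Tuple[int, int]] = []
    for c in range(k):
        stubs: List[int] = []
        for v in comm_members[c]:
            stubs.extend([v] * int_stubs[v][c])
        matched, leftover = _match_stubs(rng, stubs, lambda u, w: True, edge_set)
        edges.extend(matched)
        # a non-graphical internal demand: the unmatched stubs are
        # recycled into the external budget so the degree sequence
        # (and the edge count) is preserved; at mu=0 they are dropped
        # instead, since no edge may leave a community
        for v in leftover:
            if p.mu > 0:
                ext_stubs[v] += 1
            else:
                deg[v] -= 1
    ext_list: List[int] = []
    for v in range(p.n):
        ext_list.extend([v] * int(ext_stubs[v]))
    if len(ext_list) % 2:
        ext_list.append(int(np.argmax(ext_stubs)))  # pair the odd stub up
    matched, leftover = _match_stubs(
        rng, ext_list,
        lambda u, w: not (node_comms[u] & node_comms[w]),
        edge_set)
    edges.extend(matched)
    # reject instances whose matching still lost a noticeable share of
    # the budget; the caller retries with fresh randomness
    budget = int(deg.sum()) // 2
    if len(edges) < 0.995 * budget:
        raise GenerationError(
            f"stub matching realized {len(edges)} of {budget} edges")

    ids = _node_ids(p.n)
    g = build_graph([(ids[u], ids[v]) for u, v in edges], nodes=ids)

    communities = tuple(
        Community(id=c, members=frozenset(ids[v] for v in comm_members[c]))
        for c in range(k)
    )
    # primary membership of an overlapping node: the community holding
    # the larger internal stub share, ties to the smaller community id
    primary: Dict[str, int] = {}
    for v in range(p.n):
        primary[ids[v]] = max(memberships[v],
                              key=lambda c: (int_stubs[v][c], -c))
    overlaps = tuple(
        OverlapRecord(node=ids[v], community_ids=frozenset(memberships[v]), type=0)
        for v in overlap_nodes
    )
    isolated = frozenset(v for v in ids if not g.adj[v])
    for v in isolated:
        primary.pop(v, None)
    truth = Cover(communities=communities, primary=primary,
                  overlaps=overlaps, isolated=isolated)
    return BenchmarkInstance(
        graph=g, truth=truth,
        params=dataclasses.asdict(p) | {"family": "lfr"}, seed=seed)
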