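import itertools
import math
import time

import numpy as np
import pytest

import topocomm as tc
from topocomm.detect import (
    seed_candidates,
    extract_strong_seeds,
    grow_weak_communities,
    reassign_to_convergence,
)
from topocomm.model import Community, Cover

from conftest import clique_edges, random_graph


def serialize(cover):
    """Canonical, label-independent serialization of a cover."""
    comms = sorted(tuple(sorted(c.members)) for c in cover.communities)
    overlaps = sorted((r.node, r.type,
                       tuple(sorted(tuple(sorted(cover.members_of(i)))
                                    for i in r.community_ids)))
                      for r in cover.overlaps)
    return comms, overlaps, tuple(sorted(cover.isolated))


class TestSeedCandidates:
    def test_triangle(self):
        g = tc.build_graph(clique_edges(["a", "b", "c"]))
        cands = seed_candidates(g)
        assert len(cands) == 3
        for c in cands:
            assert c.members == {"a", "b", "c"}
            assert (c.internal, c.external) == (3, 0)

    def test_star(self):
        g = tc.build_graph([("c", f"l{i}") for i in range(4)])
        by_anchor = {c.anchor: c for c in seed_candidates(g)}
        assert by_anchor["c"].members == set(g.nodes)
        assert by_anchor["l0"].members == {"l0", "c"}

    def test_counts_match_edge_count_oracle(self):
        rng = np.random.default_rng(21)
        g = random_graph(rng, n=25, p=0.2)
        for c in seed_candidates(g):
            assert (c.internal, c.external) == tc.edge_counts(g, c.members)


class TestExtractStrongSeeds:
    def test_two_disjoint_triangles(self):
        g = tc.build_graph(clique_edges(["a", "b", "c"])
                           + clique_edges(["x", "y", "z"]))
        seeds = extract_strong_seeds(g, seed_candidates(g))
        assert sorted(map(sorted, seeds)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_six_cycle_yields_one_seed(self):
        # every closed neighborhood has internal 2 = external 2: no
        # candidate is strong on its own, yet the component still seeds
        g = tc.build_graph([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        for c in seed_candidates(g):
            assert c.internal == c.external == 2
        seeds = extract_strong_seeds(g, seed_candidates(g))
        assert len(seeds) == 1
        assert tc.is_strong_sense(g, seeds[0])

    def test_two_k5_joined_by_edge(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g = tc.build_graph(clique_edges(a) + clique_edges(b) + [("a0", "b0")])
        seeds = extract_strong_seeds(g, seed_candidates(g))
        assert len(seeds) == 2
        assert not (seeds[0] & seeds[1])
        assert {frozenset(s) for s in seeds} == {frozenset(a), frozenset(b)}

    def test_seeds_are_strong_sense(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n=40, p=0.18)
        for s in extract_strong_seeds(g, seed_candidates(g)):
            assert tc.is_strong_sense(g, s)


class TestGrow:
    def test_pendant_joins_its_clique(self):
        a = ["a1", "a2", "a3", "a4"]
        b = ["b1", "b2", "b3", "b4"]
        g = tc.build_graph(clique_edges(a) + clique_edges(b)
                           + [("a1", "b1"), ("a2", "pend")])
        cover = grow_weak_communities(g, [set(a), set(b)])
        assert cover.primary["pend"] == cover.primary["a2"]

    def test_chain_is_claimed_by_sweeps(self):
        # nodes far from the seed have no seeded neighbor at first and
        # are deferred until the frontier reaches them
        chain = [(f"c{i}", f"c{i+1}") for i in range(6)]
        g = tc.build_graph(clique_edges(["a", "b", "c0"]) + chain)
        cover = grow_weak_communities(g, [{"a", "b", "c0"}])
        assert set(cover.primary) == set(g.nodes)
        assert cover.n_communities == 1

    def test_cover_spans_all_components(self):
        rng = np.random.default_rng(6)
        g = random_graph(rng, n=40, p=0.12)
        seeds = extract_strong_seeds(g, seed_candidates(g))
        cover = grow_weak_communities(g, seeds)
        assert set(cover.primary) | set(cover.isolated) == set(g.nodes)


class TestReassign:
    def test_fixpoint_cover_unchanged(self):
        a = ["a1", "a2", "a3"]
        b = ["b1", "b2", "b3"]
        g = tc.build_graph(clique_edges(a) + clique_edges(b) + [("a1", "b1")])
        cover = grow_weak_communities(g, [set(a), set(b)])
        result, trace = reassign_to_convergence(g, cover)
        assert trace.converged and trace.moves_per_pass == [0]
        assert serialize(result) == serialize(cover)

    def test_misassigned_clique_node_returns(self):
        a = ["a1", "a2", "a3", "a4"]
        b = ["b1", "b2", "b3", "b4"]
        g = tc.build_graph(clique_edges(a) + clique_edges(b) + [("a1", "b1")])
        comms = (Community(id=0, members=frozenset(["a1", "a2", "a3"])),
                 Community(id=1, members=frozenset(b + ["a4"])))
        primary = {v: 0 for v in a[:3]} | {v: 1 for v in b + ["a4"]}
        bad = Cover(communities=comms, primary=primary)
        result, trace = reassign_to_convergence(g, bad)
        assert trace.converged
        assert {frozenset(c.members) for c in result.communities} == \
               {frozenset(a), frozenset(b)}

    def test_random_cover_on_disjoint_cliques_converges(self):
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        g = tc.build_graph(clique_edges(a) + clique_edges(b))
        rng = np.random.default_rng(17)
        labels = {v: int(rng.integers(0, 2)) for v in g.nodes}
        labels[a[0]], labels[b[0]] = 0, 1  # keep both communities non-empty
        members = {0: {v for v, c in labels.items() if c == 0},
                   1: {v for v, c in labels.items() if c == 1}}
        cover = Cover(
            communities=tuple(Community(id=i, members=frozenset(members[i]))
                              for i in (0, 1)),
            primary=labels)
        result, trace = reassign_to_convergence(g, cover)
        assert trace.converged
        # membership property holds everywhere at the fixpoint
        for v in g.nodes:
            counts = tc.membership_counts(g, v, result)
            assert counts[result.primary[v]] == max(counts.values())


class TestDetect:
    def test_karate_two_communities(self, karate):
        g, truth = karate
        cover = tc.detect_communities(g)
        assert cover.n_communities == 2
        assert tc.nmi(cover.as_partition(), truth) == 1.0

    def test_disjoint_cliques_and_isolated_nodes(self):
        edges, nodes = [], []
        for c in range(4):
            ids = [f"q{c}_{i}" for i in range(5)]
            edges += clique_edges(ids)
        nodes = [f"iso{i}" for i in range(3)]
        cover = tc.detect_communities(tc.build_graph(edges, nodes=nodes))
        assert cover.n_communities == 4
        assert sorted(cover.sizes()) == [5, 5, 5, 5]
        assert cover.isolated == {"iso0", "iso1", "iso2"}

    def test_shared_node_is_type2_overlap(self, two_cliques_shared_node):
        cover = tc.detect_communities(two_cliques_shared_node)
        assert cover.n_communities == 2
        assert len(cover.overlaps) == 1
        rec = cover.overlaps[0]
        assert rec.node == "v" and rec.type == 2
        assert len(rec.community_ids) == 2

    def test_empty_graph(self):
        cover = tc.detect_communities(tc.build_graph([], nodes=[]))
        assert cover.n_communities == 0 and not cover.isolated

    def test_edge_order_invariance(self):
        rng = np.random.default_rng(23)
        g = random_graph(rng, n=35, p=0.15)
        base = tc.detect_communities(g)
        edges = g.edges()
        for trial in range(3):
            perm = [edges[i] for i in rng.permutation(len(edges))]
            flipped = [(v, u) if trial % 2 else (u, v) for u, v in perm]
            other = tc.detect_communities(
                tc.build_graph(flipped, nodes=g.nodes))
            assert serialize(other) == serialize(base)

    def test_membership_property_at_convergence(self):
        inst = tc.generate_lfr(tc.LFR_128, seed=4)
        cover = tc.detect_communities(inst.graph)
        flagged = {r.node for r in cover.overlaps}
        for v in inst.graph.nodes:
            if v in cover.isolated or v in flagged:
                continue
            counts = tc.membership_counts(inst.graph, v, cover)
            assert counts[cover.primary[v]] == max(counts.values())

    def test_no_community_spans_components(self):
        rng = np.random.default_rng(31)
        g1 = random_graph(rng, n=20, p=0.3, prefix="x")
        g2 = random_graph(rng, n=15, p=0.3, prefix="y")
        g = tc.build_graph(g1.edges() + g2.edges())
        cover = tc.detect_communities(g)
        for c in cover.communities:
            prefixes = {v[0] for v in c.members}
            assert len(prefixes) == 1

    def test_trace_reports_convergence(self, karate):
        g, _ = karate
        cover, trace = tc.detect_communities(g, return_trace=True)
        assert trace.converged
        assert trace.moves_per_pass[-1] == 0


class TestScalingTrend:
    def test_runtime_grows_subquadratically(self):
        # planted-partition family with constant expected degree:
        # group size fixed, number of groups grows with n
        times = []
        sizes = (256, 512, 1024)
        for n in sizes:
            inst = tc.generate_planted_partition(n // 32, 32, 0.5,
                                                 2.56 / n, seed=1)
            t0 = time.perf_counter()
            tc.detect_communities(inst.graph)
            times.append(time.perf_counter() - t0)
        slope = np.polyfit(np.log(sizes), np.log(times), 1)[0]
        assert slope < 2.5
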