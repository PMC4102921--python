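"""The two kinds of overlapping nodes on small constructed graphs.

Type 1: a node whose maximum neighbor count is tied between two
communities *and* whose distance to both communities' hub members is
equal.  Type 2: a bridge node tightly attached to two communities that
would share almost no direct edges without it.
"""

import itertools

import topocomm as tc


def clique(names):
    return list(itertools.combinations(names, 2))


# --- type 2: two 4-cliques sharing the single node "v" ---------------
edges = clique(["a1", "a2", "a3", "v"]) + clique(["b1", "b2", "b3", "v"])
g = tc.build_graph(edges)
cover = tc.detect_communities(g)
print("two cliques sharing one node:")
print(f"  {cover.n_communities} communities, sizes {cover.sizes()}")
for rec in cover.overlaps:
    print(f"  overlap node {rec.node!r}: type {rec.type}, "
          f"bridges communities {sorted(rec.community_ids)}")

# --- type 1: a node equidistant and equally attached to two cliques --
edges = (clique(["a1", "a2", "a3", "a4"]) + clique(["b1", "b2", "b3", "b4"])
         + [("m", "a1"), ("m", "a2"), ("m", "b1"), ("m", "b2")])
g = tc.build_graph(edges)
cover = tc.detect_communities(g)
print("symmetric bridge node between two cliques:")
print(f"  {cover.n_communities} communities, sizes {cover.sizes()}")
for rec in cover.overlaps:
    print(f"  overlap node {rec.node!r}: type {rec.type}, "
          f"bridges communities {sorted(rec.community_ids)}")
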