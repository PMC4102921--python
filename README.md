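# topocomm

Parameter-free community detection from network topology, with
overlapping-node classification, evaluation metrics (NMI, modularity)
and synthetic benchmark generators with planted ground truth.

The package is aimed at anyone analysing the modular structure of
empirical networks — social, infrastructural or biological (it was
exercised in particular on transcriptional regulatory networks, where
modules correspond to functionally coherent groups of operons and a
"hub" is typically a master regulator).

## The method

Communities are defined purely by edge counts.  For a node set *S*
with *in(S)* internal edges and *out(S)* edges leaving it:

* **strong sense** — `in(S) > out(S)`;
* **weak sense** — `in(S) ≤ out(S)` but `in(S) > between(S, T)` for
  every other community *T*;
* **membership property** — every node belongs to the community that
  contains the maximum number of its neighbours, unless it is an
  overlapping node;
* **hub member** — a community member with the most neighbours inside
  its community.

Detection proceeds in four stages: (1) the adjacency list of every
node becomes a seed candidate; (2) disjoint strong-sense seeds are
extracted greedily (candidates are trimmed of members that already
violate the membership property and, when necessary, merged with
their best-attached neighbours until strong); (3) remaining nodes
join the seed holding most of their neighbours, ties resolved by the
shortest path to the nearest hub; (4) asynchronous sweeps re-apply the
membership property until a full pass makes no move.  Every ordering
is fixed by the canonical node order, so the algorithm is
deterministic and needs no parameters, initial conditions or random
tie-breaks.

On the converged cover two kinds of **overlapping nodes** are
reported: *type 1* (equal maximum neighbour counts toward ≥ 2
communities **and** equal shortest-path distance to those communities'
hubs) and *type 2* (a bridge attached by ≥ 2 edges to each of two
communities that would share fewer direct edges than either
attachment if the node were removed).

Partitions are scored with normalized mutual information,
`NMI = 2·I(X;Y) / (H(X) + H(Y))`, and with Newman modularity
`Q = Σ_i (e_ii − a_i²)` computed from the community mixing matrix *e*.

## Worked example

```python
import topocomm as tc

g, truth = tc.karate_club()          # bundled 34-node / 78-edge network
cover = tc.detect_communities(g)
print(cover.n_communities)                           # 2
print(sorted(cover.communities[0].hubs))             # ['34']
print(tc.nmi(cover.as_partition(), truth))           # 1.0
print(round(tc.modularity(g, cover.primary), 4))     # 0.3715
```

The two detected communities reproduce the club's two-faction split
exactly (NMI 1.0); the hubs are the instructor (node 1) and the
president (node 34).  On the 128-node LFR benchmark configuration
(mean degree 9.328, max degree 30, mixing 0.1, community sizes 10–30,
ten 2-membership overlap nodes) the bundled generator realizes ≈ 596
edges per instance, and detection recovers a modal count of 8
communities with mean NMI ≈ 0.94 against the planted truth
(`examples/02_lfr_benchmark.py` prints these numbers).

More narrative examples live in `examples/`:

| script | shows |
| --- | --- |
| `01_karate_club.py` | detection, hubs, strong/weak labels, NMI, Q |
| `02_lfr_benchmark.py` | benchmark generation and detector scoring |
| `03_overlap_types.py` | type-1 and type-2 overlapping nodes |
| `04_cli_workflow.py` | the `benchmark → detect → eval` shell workflow |

## Command line

```
topocomm detect    --input graph.tsv --format edgelist|gml|pajek --out prefix
topocomm eval      --pred pred.tsv [--truth truth.tsv | --graph graph.tsv] --metric nmi|q
topocomm benchmark lfr|planted --seed S --out prefix [generator options]
```

`detect` writes a membership table, an overlap table and a JSON
summary (community sizes, hubs, strong/weak labels, iteration trace);
metrics print with four decimals.

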