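# Methods

## Community model

The model is purely topological.  A graph is undirected and simple:
directed input is symmetrized, self-loops are dropped (a
self-regulatory arc in a regulatory network says nothing about
between-node modularity, and degree-based definitions are cleaner
without loops), and parallel edges collapse — the method is unweighted
throughout.  Node identifiers are canonicalized to strings and kept in
sorted order; this single ordering drives every sweep below, which is
what makes the whole pipeline deterministic.

For a node set *S*, `in(S)` counts edges with both endpoints in *S*
and `out(S)` edges with exactly one.  *S* is a **strong-sense**
community when `in(S) > out(S)`; it is **weak-sense** when it fails
that global test but still satisfies `in(S) > between(S, T)` for every
other community *T* of the cover.  The two predicates are mutually
exclusive by construction.  A **hub member** maximizes the number of
neighbours inside its community; ties keep all maximizers, and the
distance from a node to a community's hubs is the minimum over the hub
set — the only order-free choice when hubs tie.  The **membership
property** requires every non-overlapping node to sit in a community
attaining the maximum of its per-community neighbour counts.

## Detection pipeline

1. **Candidates.**  The closed neighbourhood of every non-isolated
   node, with cached `in`/`out` counts.

2. **Strong seeds.**  Candidates are processed in a fixed order:
   `(in − out)` descending, then `in` descending, then anchor id.
   Before the strong-sense test each candidate sheds members with
   strictly more neighbours outside the candidate than inside
   (iterated to a fixpoint; the anchor stays).  Without this, the
   neighbourhood of a high-degree anchor sweeps peripheral nodes of
   the *other* side of a community boundary into the seed, and the
   majority dynamics of stage 4 can lock them there: on the karate
   network the untrimmed pipeline converges to a wrong stable split.
   Members whose inside/outside counts tie are kept — ties are
   legitimate and resolved later by hub distance.

   A trimmed candidate that is still not strong is *expanded*: the
   unclaimed node with the best effect on `in − out` (equivalently,
   maximizing `3·attachment − degree`) is merged in repeatedly until
   the set turns strong.  This is essential on sparse communities,
   where a single adjacency list is almost never strong because most
   of its edges run to the rest of its *own* community and count as
   external.  Two guards keep seeds honest: a candidate that is
   merely several strong communities glued at its anchor (removing
   the anchor splits it into pieces that are each strong with the
   anchor added back) is rejected, its pieces seeding separately; and
   a residual that cannot become strong among unclaimed nodes alone,
   but becomes strong by borrowing one already-claimed node attached
   to it by ≥ 2 edges, is accepted on its own — the borrowed bridge
   stays with its first community and is later reported by the
   overlap classifier.  A component yielding no seed at all
   contributes its single best candidate as a fallback.

3. **Weak growth.**  Unassigned nodes join the community holding most
   of their neighbours (ties: nearest hub, then smallest community
   id).  Nodes with no assigned neighbour are deferred to later
   sweeps, so chains are absorbed link by link; sweeps repeat until
   the cover spans every component.

4. **Membership iteration.**  Asynchronous sweeps in canonical node
   order re-apply the membership property: a node moves to a
   maximum-count community unless its current community attains the
   maximum and is a nearest-hub community among the ties.  Emptied
   communities are deleted.  The loop stops at the first zero-move
   pass, with a safety cap of 100 passes (the cap has never been
   reached in testing; non-convergence would be flagged in the
   trace).  Asynchronous updating was chosen over synchronous because
   it cannot oscillate between two label waves and makes progress
   within a pass.

Overlap classification runs once, on the converged cover (overlaps
are properties of a stable partition, not of intermediate states).
Type 1 is tested before type 2 and a node carries at most one record.
The type-2 thresholds — "tightly attached" as ≥ 2 edges into each
community, "few residual edges" as strictly fewer direct
inter-community edges (with the node removed) than the node's weaker
attachment — are the package's parameter-free operationalization of a
qualitative notion; they hold for a node shared by two cliques and
fail when the two communities are directly well connected.  Every
community id, record and file output is ordered canonically
(component, then size descending, then smallest member), so repeated
runs are byte-identical and the result is invariant to the order in
which edges were supplied.

## Evaluation measures

NMI uses the arithmetic normalization `2·I(X;Y)/(H(X)+H(Y))` with
entropies in bits; among the normalizations in circulation this is the
standard one for community comparison, and it is cross-checked in the
tests against scikit-learn's implementation.  Two single-community
labelings are identical as partitions, so their NMI is defined as 1.
Modularity is computed from the mixing matrix: each edge contributes
`1/m` split across the symmetric cell pair, `Q = Σ_i (e_ii − a_i²)`;
an independent per-edge summation and networkx's implementation serve
as oracles in the tests.  Overlapping nodes enter both measures under
their primary community; isolated nodes are excluded from Q (they
carry no edges) and enter NMI as singleton communities.

## Synthetic benchmarks

**Planted partition**: `l` groups of `size` nodes, independent
Bernoulli edges with probability `p_in` inside and `p_out` between
groups.

**LFR-style generator.**  Degrees follow a truncated power law
(exponent `tau1 = 2` by default) whose lower cutoff is solved
numerically so the *expected* degree equals `avg_k` exactly — this
also handles non-integer targets such as 9.328, and the realized sum
is left to fluctuate around `n·avg_k` rather than being pinned
(pinning by pushing the largest nodes to the degree cap creates
several nodes that must be adjacent to an entire community, which
makes the internal wiring infeasible).  Community sizes follow a
power law (`tau2 = 1`) on `[min_c, max_c]`, drawn until the
membership budget `n + on·(om − 1)` is met, with the overshoot shaved
off the largest draws.  Each node allocates a fraction `1 − mu` of
its stubs inside its community — stochastically rounded, so the
expected mixing is `mu` rather than its integer quantization —
and `on` overlapping nodes split their internal stubs evenly across
`om` communities.  Nodes are seated by descending internal degree
into communities chosen with probability proportional to remaining
capacity, subject to `internal degree ≤ size − 1`; a bounded
Erdős–Gallai repair then swaps small-degree members out of
communities whose internal demand is top-heavy and non-graphical.

Wiring is configuration-model stub matching with swap-repair of
self-loops, duplicates and (for inter-community stubs) same-community
pairs; a failed matching is rebuilt by a randomized Havel–Hakimi
construction, and internal stubs that remain unrealizable (a
genuinely non-graphical residue) are recycled into the external
budget so the degree sequence and edge count are preserved (at
`mu = 0` they are dropped instead, preserving the all-edges-internal
guarantee).  Instances that still lose more than 0.5 % of the stub
budget are rejected and regenerated.  All randomness flows from one
`numpy` generator seeded by the caller; identical seed and parameters
give bit-identical instances.

At the 128-node study configuration (`avg_k = 9.328`, `max_k = 30`,
`mu = 0.1`, sizes 10–30, `on = 10`, `om = 2`) the generator realizes
a mean of ≈ 596 edges and a modal planted community count of 8; the
realized mixing averages ≈ 0.105 at both n = 128 and n = 512 (the small upward residue comes from recycled non-graphical internal
stubs).  The planted truth records a *primary* community for every
node; for an overlapping node this is the community holding its
larger internal-stub share.  Scoring against this single fixed
flattening (rather than the most favourable one) is deliberate: a
detector that places every overlap node in its other planted
community is genuinely less informative about the planted structure,
and a best-case flattening would hide exactly the errors the overlap
nodes cause.

### What the generator does and does not emulate

It reproduces the degree heterogeneity, bounded community sizes,
controlled mixing and planted overlaps of the standard benchmark
family.  It does not emulate degree assortativity, clustering beyond
what the community structure induces, hierarchical or weighted
structure, or the highly unbalanced module sizes of real regulatory
networks.  Passing benchmark tests therefore demonstrates correct
recovery under controlled planted structure, not performance claims
on any particular empirical network.

## Problem sizes in the test suite

The suite exercises detection on 50 generated 128-node instances for
the headline statistics, 50 planted-partition instances (4 × 32
nodes) for the recovery-rate property, 20 instances at n = 512 for
mixing calibration, and a three-point planted-partition family
(n = 256–1024, constant expected degree) for the coarse
runtime-scaling trend (log–log slope well below quadratic).  These
sizes give stable statistics for every tolerance asserted while
keeping the whole suite in tens of seconds.

## Known limitations

* Merged communities are never split after convergence; when two
  planted communities are bridged densely enough the detector
  reports their union (visible as detected counts one below the
  planted count on some benchmark seeds).
* Weighted, directed-semantic and hierarchical structure are out of
  scope; arcs are symmetrized before detection.
* Type-2 overlap records name exactly one community pair per node.
* The membership fixpoint is not unique in general; determinism comes
  from the fixed sweep order, not from uniqueness.
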