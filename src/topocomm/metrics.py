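"""Partition-comparison and partition-quality measures.

Normalized mutual information (NMI) between two labelings X, Y:

    NMI(X, Y) = 2 * I(X; Y) / (H(X) + H(Y)),
    I(X; Y)   = H(X) + H(Y) - H(X, Y),

with Shannon entropies in bits over the community-size distributions.
NMI is 1 for identical partitions and tends to 0 for independent ones.

Newman modularity of a partition is computed from the mixing matrix e,
where e_ij is the fraction of edges running between communities i and
j (an edge inside community i contributes wholly to e_ii; an edge
between i and j contributes half to e_ij and half to e_ji, so the
matrix is symmetric and sums to 1):

    Q = sum_i (e_ii - a_i^2),   a_i = sum_j e_ij.

Overlapping nodes enter both measures under their primary community;
isolated nodes are excluded from Q (they carry no edge) and enter NMI
as singleton communities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping, Tuple

import numpy as np

from .graph import Graph

__all__ = [
    "ContingencyTable",
    "MixingMatrix",
    "entropy",
    "contingency",
    "joint_entropy",
    "nmi",
    "mixing_matrix",
    "modularity",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint community-size counts of two labelings over one node set."""

    counts: np.ndarray  # shape (|X communities|, |Y communities|)
    row_labels: Tuple[Hashable, ...]
    col_labels: Tuple[Hashable, ...]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class MixingMatrix:
    """Fractions of edges within and between communities (sums to 1)."""

    e: np.ndarray
    labels: Tuple[Hashable, ...]

    @property
    def a(self) -> np.ndarray:
        return self.e.sum(axis=1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy(labels: Mapping[Hashable, Hashable]) -> float:
    """Shannon entropy (bits) of a labeling's community-size distribution."""
    if not labels:
        raise ValueError("empty labeling")
    counts = np.array(list(Counter(labels.values()).values()), dtype=float)
    return _entropy_from_counts(counts)


def contingency(X: Mapping, Y: Mapping) -> ContingencyTable:
    if set(X) != set(Y):
        raise ValueError("labelings are over different node sets")
    rows = sorted(set(X.values()), key=repr)
    cols = sorted(set(Y.values()), key=repr)
    ri = {l: i for i, l in enumerate(rows)}
    ci = {l: i for i, l in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for v in X:
        counts[ri[X[v]], ci[Y[v]]] += 1
    return ContingencyTable(counts=counts, row_labels=tuple(rows),
                            col_labels=tuple(cols))


def joint_entropy(X: Mapping, Y: Mapping) -> float:
    table = contingency(X, Y)
    return _entropy_from_counts(table.counts.astype(float).ravel())


def nmi(X: Mapping, Y: Mapping) -> float:
    """Normalized mutual information, 2I/(H(X)+H(Y)), in [0, 1].

    When both labelings are trivial (single community each) they are
    identical as partitions and NMI is defined as 1.
    """
    table = contingency(X, Y)
    hx = _entropy_from_counts(table.row_sums.astype(float))
    hy = _entropy_from_counts(table.col_sums.astype(float))
    if hx + hy == 0.0:
        return 1.0
    hxy = _entropy_from_counts(table.counts.astype(float).ravel())
    value = 2.0 * (hx + hy - hxy) / (hx + hy)
    return float(min(1.0, max(0.0, value)))


def mixing_matrix(g: Graph, partition: Mapping[str, Hashable]) -> MixingMatrix:
    """Edge-fraction matrix e of a partition; each edge contributes a
    total weight of 1/m, split across the symmetric pair of cells."""
    for v in g.nodes:
        if g.adj[v] and v not in partition:
            raise ValueError(f"node {v!r} has edges but no community label")
    if g.m == 0:
        raise ValueError("graph has no edges")
    labels = tuple(sorted(set(partition.values()), key=repr))
    idx = {l: i for i, l in enumerate(labels)}
    e = np.zeros((len(labels), len(labels)), dtype=float)
    half = 0.5 / g.m
    for u, v in g.edges():
        i, j = idx[partition[u]], idx[partition[v]]
        e[i, j] += half
        e[j, i] += half
    return MixingMatrix(e=e, labels=labels)


def modularity(g: Graph, partition: Mapping[str, Hashable]) -> float:
    """Newman modularity Q = sum_i (e_ii - a_i^2)."""
    mm = mixing_matrix(g, partition)
    return float(np.trace(mm.e) - (mm.a ** 2).sum())
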