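"""topocomm: parameter-free community detection from network topology.

The package detects communities by comparing internal and external
edge counts of node neighborhoods: strong-sense seeds are extracted
from adjacency lists, grown into weak-sense communities, and refined
by iterating the membership property to a fixpoint; overlapping nodes
are then classified into two topological types.  Evaluation (NMI,
modularity) and synthetic benchmark generators (planted partition,
LFR-style with planted overlaps) are included.
"""

from .graph import (
    Graph,
    ComponentDecomposition,
    GraphParseError,
    build_graph,
    connected_components,
    shortest_path_length,
    edge_counts,
    edges_between,
)
from .model import (
    Community,
    Cover,
    OverlapRecord,
    is_strong_sense,
    is_weak_sense,
    hub_members,
    membership_counts,
    classify_type1,
    classify_type2,
    classify_overlaps,
    community_labels,
)
from .detect import (
    SeedCandidate,
    DetectionTrace,
    seed_candidates,
    extract_strong_seeds,
    grow_weak_communities,
    reassign_to_convergence,
    detect_communities,
)
from .metrics import entropy, nmi, modularity, mixing_matrix, contingency
from .benchmarks import (
    LFRParams,
    LFR_128,
    BenchmarkInstance,
    GenerationError,
    generate_planted_partition,
    generate_lfr,
)
from .io import read_graph, write_cover, read_cover, read_membership, write_membership

__version__ = "0.1.0"

__all__ = [
    "Graph", "ComponentDecomposition", "GraphParseError",
    "build_graph", "connected_components", "shortest_path_length",
    "edge_counts", "edges_between",
    "Community", "Cover", "OverlapRecord",
    "is_strong_sense", "is_weak_sense", "hub_members", "membership_counts",
    "classify_type1", "classify_type2", "classify_overlaps", "community_labels",
    "SeedCandidate", "DetectionTrace", "seed_candidates",
    "extract_strong_seeds", "grow_weak_communities",
    "reassign_to_convergence", "detect_communities",
    "entropy", "nmi", "modularity", "mixing_matrix", "contingency",
    "LFRParams", "LFR_128", "BenchmarkInstance", "GenerationError",
    "generate_planted_partition", "generate_lfr",
    "read_graph", "write_cover", "read_cover",
    "read_membership", "write_membership",
    "karate_club",
]


def karate_club():
    """The canonical 34-node, 78-edge karate-club graph bundled with
    the package, plus the two-faction ground truth.

    Returns (graph, labels) where labels maps node id -> faction id.
    """
    from importlib import resources
    from .io import read_edgelist, read_membership

    data = resources.files(__name__) / "data"
    with resources.as_file(data / "karate.edgelist") as p:
        g = build_graph(read_edgelist(p))
    with resources.as_file(data / "karate_truth.tsv") as p:
        labels = read_membership(p)
    return g, {v: int(c) for v, c in labels.items()}
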