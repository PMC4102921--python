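"""Readers and writers for graphs, covers and membership tables.

Graphs come in as whitespace/tab edge lists, GML, or Pajek .net (the
latter two through networkx readers); all are funneled through
:func:`topocomm.graph.build_graph`, so directed input is symmetrized
and node labels are kept verbatim.  Covers go out as two TSV tables
(primary membership; overlap records) plus a JSON summary, with stable
ordering so outputs are diffable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .graph import Graph, GraphParseError, build_graph
from .model import Community, Cover, OverlapRecord, community_labels

__all__ = [
    "read_graph",
    "read_edgelist",
    "write_edgelist",
    "write_cover",
    "read_cover",
    "read_membership",
    "write_membership",
]

FORMATS = ("edgelist", "gml", "pajek")


def read_edgelist(path) -> List[Tuple[str, str]]:
    """Whitespace-separated edge list; '#' comment lines and blank
    lines are ignored; every data line must have exactly two tokens."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}: {line!r}")
            edges.append((tokens[0], tokens[1]))
    return edges


def read_graph(path, format: str = "edgelist", directed: bool = False) -> Graph:
    """Read a graph in one of the supported dialects as a canonical
    undirected simple graph."""
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        edges = read_edgelist(path)
        if not edges:
            raise GraphParseError(f"{path}: no edges found")
        return build_graph(edges, directed=directed)
    if format == "gml":
        nxg = nx.read_gml(path, label="label")
    else:  # pajek
        nxg = nx.read_pajek(path)
    nodes = [str(v) for v in nxg.nodes()]
    edges = [(str(u), str(v)) for u, v in nxg.edges()]
    return build_graph(edges, directed=directed, nodes=nodes)


def write_edgelist(g: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")


def write_gml(g: Graph, path) -> None:
    nxg = nx.Graph()
    nxg.add_nodes_from(g.nodes)
    nxg.add_edges_from(g.edges())
    nx.write_gml(nxg, path)


def write_membership(labels: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tcommunity\n")
        for v in sorted(labels):
            fh.write(f"{v}\t{labels[v]}\n")


def read_membership(path) -> Dict[str, str]:
    """node -> community-label TSV (labels kept as strings)."""
    labels: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and tokens[:2] == ["node", "community"]:
                continue
            if len(tokens) < 2:
                raise GraphParseError(
                    f"{path}:{lineno}: expected node and community, got {line!r}")
            labels[tokens[0]] = tokens[1]
    return labels


def write_cover(cover: Cover, prefix, graph: Optional[Graph] = None) -> List[Path]:
    """Write ``<prefix>.membership.tsv``, ``<prefix>.overlaps.tsv`` and
    ``<prefix>.summary.json``; returns the paths written.

    When the graph is supplied the summary also carries each
    community's strong/weak label and hub members.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    membership_path = prefix.with_name(prefix.name + ".membership.tsv")
    overlaps_path = prefix.with_name(prefix.name + ".overlaps.tsv")
    summary_path = prefix.with_name(prefix.name + ".summary.json")

    with open(membership_path, "w") as fh:
        fh.write("node\tcommunity\n")
        for v in sorted(cover.primary):
            fh.write(f"{v}\t{cover.primary[v]}\n")
        for v in sorted(cover.isolated):
            fh.write(f"{v}\tisolated\n")
    with open(overlaps_path, "w") as fh:
        fh.write("node\ttype\tcommunities\n")
        for rec in sorted(cover.overlaps, key=lambda r: r.node):
            cids = ",".join(str(c) for c in sorted(rec.community_ids))
            fh.write(f"{rec.node}\t{rec.type}\t{cids}\n")

    labels = community_labels(graph, cover) if graph is not None else {}
    summary = {
        "n_communities": cover.n_communities,
        "n_overlapping_nodes": len(cover.overlaps),
        "n_isolated_nodes": len(cover.isolated),
        "isolated_nodes": sorted(cover.isolated),
        "communities": [
            {
                "id": c.id,
                "size": len(c.members),
                "hubs": sorted(c.hubs),
                **({"sense": labels[c.id]} if labels else {}),
            }
            for c in cover.communities
        ],
    }
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [membership_path, overlaps_path, summary_path]


def read_cover(prefix) -> Cover:
    """Rebuild a Cover from the files written by :func:`write_cover`.

    Hub sets and strong/weak labels are not restored (they are derived
    data; recompute them from the graph when needed).
    """
    prefix = Path(prefix)
    membership_path = prefix.with_name(prefix.name + ".membership.tsv")
    overlaps_path = prefix.with_name(prefix.name + ".overlaps.tsv")
    primary: Dict[str, int] = {}
    isolated = set()
    members: Dict[int, set] = {}
    for v, label in read_membership(membership_path).items():
        if label == "isolated":
            isolated.add(v)
        else:
            cid = int(label)
            primary[v] = cid
            members.setdefault(cid, set()).add(v)
    overlaps = []
    with open(overlaps_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("node\t"):
                continue
            node, typ, cids = line.split("\t")
            overlaps.append(OverlapRecord(
                node=node, type=int(typ),
                community_ids=frozenset(int(c) for c in cids.split(","))))
    communities = tuple(
        Community(id=cid, members=frozenset(members[cid]))
        for cid in sorted(members)
    )
    return Cover(communities=communities, primary=primary,
                 overlaps=tuple(overlaps), isolated=frozenset(isolated))
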