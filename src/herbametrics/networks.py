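"""Collaboration and keyword co-occurrence networks.

Nodes are entities (countries, institutions, authors, or keywords) weighted
by their publication counts; an edge between two entities is weighted by the
number of records listing both.  Graphs are undirected with no self-loops.
Communities are found by Louvain modularity optimization; the modularity
score itself is recomputed here from the weighted Newman-Girvan definition

    Q = sum_c [ w_c / W - (s_c / (2 W))^2 ]

with ``w_c`` the intra-community edge weight, ``s_c`` the total weighted
degree of community ``c`` and ``W`` the total edge weight of the graph.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
from networkx.algorithms.community import louvain_communities

from .records import Corpus, record_entities

__all__ = [
    "EntityGraph",
    "Partition",
    "build_coauthorship_graph",
    "build_keyword_cooccurrence",
    "modularity",
    "detect_communities",
    "export_graph",
    "read_edgelist_csv",
]

COAUTHOR_LEVELS = ("country", "institution", "author")
EXPORT_FORMATS = ("gexf", "graphml", "csv")


class EdgelessGraphError(ValueError):
    """Modularity is undefined on a graph without edges."""


@dataclass
class EntityGraph:
    """Weighted undirected entity graph.

    Wraps a :class:`networkx.Graph` whose nodes carry a ``publication_count``
    attribute and whose edges carry an integer ``weight``.
    """

    graph: nx.Graph
    level: str

    def __post_init__(self) -> None:
        if any(self.graph.has_edge(n, n) for n in self.graph):
            raise ValueError("entity graphs must not contain self-loops")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def publication_count(self, node) -> int:
        return self.graph.nodes[node]["publication_count"]

    def edge_weight(self, a, b) -> int:
        return self.graph.edges[a, b]["weight"] if self.graph.has_edge(a, b) else 0

    def total_edge_weight(self) -> float:
        return self.graph.size(weight="weight")


@dataclass
class Partition:
    """Community assignment for every node plus its modularity score.

    ``modularity_q`` is ``None`` for edgeless graphs, where the score is
    undefined.
    """

    membership: dict = field(default_factory=dict)
    modularity_q: float | None = None

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set]:
        groups: dict[int, set] = {}
        for node, cid in self.membership.items():
            groups.setdefault(cid, set()).add(node)
        return [groups[c] for c in sorted(groups)]


def _count_and_link(
    entity_lists: list[list[str]], min_count: int, level: str
) -> EntityGraph:
    counts: Counter = Counter()
    for ents in entity_lists:
        for e in set(ents):
            counts[e] += 1
    keep = {e for e, n in counts.items() if n >= min_count}
    g = nx.Graph()
    for e in sorted(keep):
        g.add_node(e, publication_count=counts[e])
    for ents in entity_lists:
        present = sorted(set(ents) & keep)
        for a, b in combinations(present, 2):
            if g.has_edge(a, b):
                g.edges[a, b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return EntityGraph(graph=g, level=level)


def build_coauthorship_graph(
    corpus: Corpus, level: str, min_docs: int = 1
) -> EntityGraph:
    """Co-authorship graph at country/institution/author level.

    The node set is fixed *before* edge construction: only entities with at
    least *min_docs* publications are kept, and each record then adds +1 to
    the edge weight of every unordered pair of retained entities it lists.  A
    record listing a single retained entity contributes a node but no edge.
    """
    if level not in COAUTHOR_LEVELS:
        raise ValueError(f"level must be one of {COAUTHOR_LEVELS}, got {level!r}")
    lists = [record_entities(r, level) for r in corpus]
    return _count_and_link(lists, min_docs, level)


def build_keyword_cooccurrence(
    corpus: Corpus, which: str = "both", min_occurrence: int = 1
) -> EntityGraph:
    """Keyword co-occurrence graph.

    *which* selects author keywords, index keywords, or their union ("total
    keywords").  Node weight is the number of publications containing the
    keyword; edge weight the number containing both.  Keywords below
    *min_occurrence* publications are removed before edges are formed.
    """
    if which not in ("author", "indexed", "both"):
        raise ValueError(f"which must be author/indexed/both, got {which!r}")
    level = {"author": "keyword_author", "indexed": "keyword_index",
             "both": "keyword_both"}[which]
    lists = [record_entities(r, level) for r in corpus]
    return _count_and_link(lists, min_occurrence, "keyword")


def modularity(egraph: EntityGraph, partition: Partition | dict) -> float:
    """Weighted Newman-Girvan modularity of a node partition.

    Invariant under community relabeling; raises on edgeless graphs.
    """
    g = egraph.graph
    membership = partition.membership if isinstance(partition, Partition) else partition
    missing = set(g.nodes) - set(membership)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    W = g.size(weight="weight")
    if W <= 0:
        raise EdgelessGraphError("modularity undefined for an edgeless graph")
    intra: Counter = Counter()
    degree: Counter = Counter()
    for a, b, w in g.edges(data="weight", default=1):
        degree[membership[a]] += w
        degree[membership[b]] += w
        if membership[a] == membership[b]:
            intra[membership[a]] += w
    q = 0.0
    for c in set(membership.values()):
        q += intra[c] / W - (degree[c] / (2.0 * W)) ** 2
    return q


def detect_communities(egraph: EntityGraph, seed: int = 0) -> Partition:
    """Louvain community detection (local moving + aggregation, resolution 1).

    Deterministic for a fixed seed (the seed controls node visiting order).
    Communities are labeled 0..k-1 in order of their lexicographically
    smallest member.  On an edgeless graph every node becomes its own
    community and the (undefined) modularity is flagged as ``None``.
    """
    g = egraph.graph
    if g.number_of_edges() == 0:
        membership = {n: i for i, n in enumerate(sorted(g.nodes, key=str))}
        return Partition(membership=membership, modularity_q=None)
    comms = louvain_communities(g, weight="weight", resolution=1.0, seed=seed)
    comms = sorted((sorted(c, key=str) for c in comms), key=lambda c: str(c[0]))
    membership = {n: i for i, c in enumerate(comms) for n in c}
    q = modularity(egraph, membership)
    return Partition(membership=membership, modularity_q=q)


def export_graph(
    egraph: EntityGraph,
    path: str | Path,
    partition: Partition | None = None,
    fmt: str = "gexf",
) -> Path:
    """Write the graph as GEXF, GraphML, or an edge-list CSV.

    Node attributes carry ``publication_count`` and, when a partition is
    given, ``community``; edges carry ``weight``.
    """
    if egraph.n_nodes == 0:
        raise ValueError("refusing to export an empty graph")
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {EXPORT_FORMATS}")
    path = Path(path)
    g = egraph.graph.copy()
    if partition is not None and partition.membership:
        nx.set_node_attributes(g, partition.membership, "community")
    if fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for a, b, w in sorted(g.edges(data="weight", default=1)):
                writer.writerow([a, b, w])
    return path


def read_edgelist_csv(path: str | Path, level: str = "author") -> EntityGraph:
    """Read back an edge-list CSV written by :func:`export_graph`.

    Node publication counts are not stored in this format; they are set to 0.
    """
    g = nx.Graph()
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            g.add_edge(row["source"], row["target"], weight=int(row["weight"]))
    for n in g.nodes:
        g.nodes[n].setdefault("publication_count", 0)
    return EntityGraph(graph=g, level=level)
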