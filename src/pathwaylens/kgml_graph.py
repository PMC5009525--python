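"""KGML pathway maps as directed enzyme graphs, and induced-subgraph metrics.

A KEGG pathway map (KGML, the KEGG XML exchange dialect) is converted to a
directed graph whose nodes are enzyme-type entries (``ortholog``, ``gene`` or
``enzyme``) carrying KO/EC labels, and whose edges come from ``<relation>``
elements.  ``map`` entries are dropped; ``compound`` entries are collapsed so
that an enzyme -> compound -> enzyme relation chain becomes a direct
enzyme -> enzyme edge.  The graph is simple: parallel edges and self-loops are
removed at parse time, because the density and degree statistics below would
otherwise be multigraph-dependent.

Each node carries a ``mapped`` flag: true when at least one of its labels has
RNA-Seq evidence in the sample under study (the nodes KEGG would paint green).
The significance machinery operates on the subgraph induced by mapped nodes.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .pathway_data import SampleExpression, normalize_group_id

__all__ = [
    "PathwayGraph",
    "GraphMetrics",
    "parse_kgml",
    "mark_mapped",
    "induced_mapped_subgraph",
    "compute_metrics",
    "write_edge_list",
    "write_node_table",
]

_ENZYME_TYPES = frozenset({"ortholog", "gene", "enzyme"})


@dataclass
class PathwayGraph:
    """A directed enzyme graph for one pathway.

    ``graph`` is a simple :class:`networkx.DiGraph`; every node has two
    attributes: ``labels`` (frozenset of KO/EC identifiers) and ``mapped``
    (bool).  Node identifiers are opaque strings.
    """

    pathway_id: str
    graph: nx.DiGraph

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(self.pathway_id, self.graph.copy())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def labels(self, node: str) -> frozenset[str]:
        return self.graph.nodes[node]["labels"]

    def is_mapped(self, node: str) -> bool:
        return bool(self.graph.nodes[node]["mapped"])

    def mapped_nodes(self) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data=True) if d["mapped"]
        )

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges())

    def members(self) -> frozenset[str]:
        """Union of all node labels (the pathway's ortholog-group membership)."""
        out: set[str] = set()
        for _, d in self.graph.nodes(data=True):
            out |= d["labels"]
        return frozenset(out)

    def mapped_groups(self) -> frozenset[str]:
        """Union of labels over mapped nodes."""
        out: set[str] = set()
        for _, d in self.graph.nodes(data=True):
            if d["mapped"]:
                out |= d["labels"]
        return frozenset(out)

    def topology_equal(self, other: "PathwayGraph") -> bool:
        """Equality on node ids, labels and edges, ignoring mapped flags and order."""
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if self.edge_set() != other.edge_set():
            return False
        return all(
            self.labels(n) == other.labels(n) for n in self.graph.nodes
        )


@dataclass(frozen=True)
class GraphMetrics:
    """Summary statistics of an induced mapped subgraph.

    density
        edges / (nodes - 1); 0 by convention when the subgraph has <= 1 node.
    zero_degree_fraction
        (#nodes with out-degree 0 + #nodes with in-degree 0) / (2 * #nodes);
        0 by convention on the empty graph.  Each node contributes at most
        two of the 2N terms, so the value lies in [0, 1].
    Components are weakly connected components; the largest-by-nodes and
    largest-by-edges counts are independent maxima.
    """

    n_mapped_nodes: int
    n_edges: int
    density: float
    zero_degree_fraction: float
    n_components: int
    largest_cc_nodes: int
    largest_cc_edges: int

    def sort_key(self) -> tuple[float, float]:
        """Ascending sort puts better graphs first: density descending,
        zero-degree fraction ascending."""
        return (-self.density, self.zero_degree_fraction)


def _strip_prefix(token: str) -> str:
    for pre in ("ko:", "ec:", "gn:"):
        if token.startswith(pre):
            return token[len(pre):]
    return token


def parse_kgml(path) -> PathwayGraph:
    """Parse a KGML file into a :class:`PathwayGraph`.

    One node per ``<entry>`` of type ortholog/gene/enzyme; labels are the
    space-separated identifiers of the entry ``name`` attribute with
    ``ko:``/``ec:`` prefixes stripped.  One directed edge per ``<relation>``
    (entry1 -> entry2).  ``map`` entries never become nodes; ``compound``
    entries are collapsed (in-neighbours connected to out-neighbours) and
    removed.  All nodes start with ``mapped=False``.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    pathway_id = root.get("name", "") or ""
    if pathway_id.startswith("path:"):
        pathway_id = pathway_id[len("path:"):]

    g = nx.DiGraph()
    entry_type: dict[str, str] = {}
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "")
        if eid is None:
            continue
        entry_type[eid] = etype
        if etype in _ENZYME_TYPES:
            labels = frozenset(
                normalize_group_id(_strip_prefix(tok))
                for tok in (entry.get("name") or "").split()
                if _strip_prefix(tok)
            )
            g.add_node(eid, labels=labels, mapped=False)

    compound_in: dict[str, set[str]] = {}
    compound_out: dict[str, set[str]] = {}
    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 is None or e2 is None:
            continue
        t1 = entry_type.get(e1, "")
        t2 = entry_type.get(e2, "")
        if t1 in _ENZYME_TYPES and t2 in _ENZYME_TYPES:
            if e1 != e2:
                g.add_edge(e1, e2)
        elif t1 in _ENZYME_TYPES and t2 == "compound":
            compound_in.setdefault(e2, set()).add(e1)
        elif t1 == "compound" and t2 in _ENZYME_TYPES:
            compound_out.setdefault(e1, set()).add(e2)
        # relations touching map entries (or unknown ids) are dropped

    for cid in set(compound_in) | set(compound_out):
        for u in compound_in.get(cid, ()):
            for v in compound_out.get(cid, ()):
                if u != v:
                    g.add_edge(u, v)

    if g.number_of_nodes() == 0:
        warnings.warn(f"KGML file {path} contains no enzyme-type entries")
    return PathwayGraph(pathway_id=pathway_id, graph=g)


def mark_mapped(graph: PathwayGraph, sample: SampleExpression) -> PathwayGraph:
    """Return a copy with ``mapped=True`` exactly on nodes whose labels
    intersect the sample's expressed set.  Topology is unchanged."""
    out = graph.copy()
    for n, d in out.graph.nodes(data=True):
        d["mapped"] = bool(d["labels"] & sample.expressed)
    return out


def induced_mapped_subgraph(graph: PathwayGraph) -> PathwayGraph:
    """The subgraph on mapped nodes: mapped nodes only, and only edges with
    both endpoints mapped."""
    sub = graph.graph.subgraph(graph.mapped_nodes()).copy()
    return PathwayGraph(graph.pathway_id, sub)


def compute_metrics(graph: PathwayGraph) -> GraphMetrics:
    """Metrics of an induced mapped subgraph.

    density = |E| / (|V| - 1), defined as 0 for |V| <= 1.
    zero_degree_fraction = (#out-degree-0 + #in-degree-0) / (2|V|),
    defined as 0 for |V| = 0.
    """
    g = graph.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    density = e / (n - 1) if n > 1 else 0.0
    if n == 0:
        zdf = 0.0
        n_cc = largest_n = largest_e = 0
    else:
        out0 = sum(1 for _, d in g.out_degree() if d == 0)
        in0 = sum(1 for _, d in g.in_degree() if d == 0)
        zdf = (out0 + in0) / (2 * n)
        comps = list(nx.weakly_connected_components(g))
        n_cc = len(comps)
        largest_n = max(len(c) for c in comps)
        largest_e = max(g.subgraph(c).number_of_edges() for c in comps)
    return GraphMetrics(
        n_mapped_nodes=n,
        n_edges=e,
        density=density,
        zero_degree_fraction=zdf,
        n_components=n_cc,
        largest_cc_nodes=largest_n,
        largest_cc_edges=largest_e,
    )


def write_edge_list(graph: PathwayGraph, path) -> None:
    """Debug dump: one ``node_id <TAB> node_id`` line per edge, sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(graph.graph.edges()):
            fh.write(f"{u}\t{v}\n")


def write_node_table(graph: PathwayGraph, path) -> None:
    """Debug dump: node_id, space-joined labels, mapped flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#node_id\tlabels\tmapped\n")
        for n in sorted(graph.graph.nodes):
            d = graph.graph.nodes[n]
            fh.write(f"{n}\t{' '.join(sorted(d['labels']))}\t{int(d['mapped'])}\n")
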