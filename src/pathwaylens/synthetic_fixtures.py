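"""Seeded generators for pathway graphs, overlapping pathway families and
KGML fixture files.

These generators make the full pipeline testable without KEGG access.  They
emulate the structural features the methods depend on — directed enzyme
graphs of realistic size (the smallest real pathway graphs have about 15
nodes and 40 edges), pathway families that share ortholog groups, and a
binary expressed/unexpressed labelling — but they are not a biologically
realistic pathway simulator: no reaction semantics, no read-level noise.

Everything is driven by an explicit ``random.Random`` or seed, so identical
seeds reproduce identical fixtures bit for bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from xml.sax.saxutils import quoteattr

import networkx as nx

from .kgml_graph import PathwayGraph
from .pathway_data import PathwayCollection, PathwayDefinition, SampleExpression

__all__ = [
    "FixtureSpec",
    "random_pathway_graph",
    "random_pathway_family",
    "write_kgml_fixture",
]

# background_expression: fraction of non-planted groups expressed anyway —
# non-degenerate but separable test cases.
@dataclass
class FixtureSpec:
    """Parameters for fixture generation.

    Graph sizes default to the smallest realistic pathway (15 nodes, 40
    edges).  ``overlap_fraction`` is the share of each pathway's members
    drawn from a common shared pool rather than minted fresh;
    ``mapped_fraction`` is the share of graph nodes flagged as expressed.
    """

    seed: int = 0
    n_pathways: int = 10
    groups_per_pathway: tuple[int, int] = (3, 8)
    overlap_fraction: float = 0.3
    n_nodes: int = 15
    n_edges: int = 40
    mapped_fraction: float = 0.5
    planted_active: frozenset[str] = field(default_factory=frozenset)
    background_expression: float = 0.1

    def __post_init__(self) -> None:
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError(
                f"{self.n_edges} edges infeasible on {self.n_nodes} nodes "
                "(simple directed graph)"
            )
        lo, hi = self.groups_per_pathway
        if lo < 1 or hi < lo:
            raise ValueError("groups_per_pathway range is empty")
        for name in ("overlap_fraction", "mapped_fraction", "background_expression"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def rng(self) -> random.Random:
        return random.Random(self.seed)


def _ko(i: int) -> str:
    return f"K{i:05d}"


def random_pathway_graph(
    spec: FixtureSpec,
    rng: random.Random | None = None,
    pathway_id: str = "ko99001",
    label_offset: int = 0,
) -> PathwayGraph:
    """A simple directed graph with exactly spec.n_nodes nodes and
    spec.n_edges edges, unit KO labels, and mapped flags drawn per
    ``mapped_fraction`` (count rounded, assignment random)."""
    if rng is None:
        rng = spec.rng()
    n, e = spec.n_nodes, spec.n_edges
    node_ids = [f"n{i}" for i in range(n)]
    g = nx.DiGraph()
    for i, nid in enumerate(node_ids):
        g.add_node(nid, labels=frozenset({_ko(label_offset + i + 1)}), mapped=False)
    pairs = [
        (node_ids[i], node_ids[j])
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    g.add_edges_from(rng.sample(pairs, e))
    n_mapped = round(spec.mapped_fraction * n)
    for nid in rng.sample(node_ids, n_mapped):
        g.nodes[nid]["mapped"] = True
    return PathwayGraph(pathway_id=pathway_id, graph=g)


def random_pathway_family(
    spec: FixtureSpec, rng: random.Random | None = None
) -> tuple[PathwayCollection, SampleExpression]:
    """An overlapping pathway family plus one expressed-set sample.

    Each pathway draws ``overlap_fraction`` of its members from a shared
    pool (so pathways genuinely compete for groups) and mints the rest
    fresh.  The expressed set covers every member of the planted-active
    pathways plus a ``background_expression`` fraction of the remaining
    groups.
    """
    if rng is None:
        rng = spec.rng()
    lo, hi = spec.groups_per_pathway
    pool_size = max(hi, 2)
    shared_pool = [_ko(i + 1) for i in range(pool_size)]
    next_id = pool_size + 1

    pathways: dict[str, PathwayDefinition] = {}
    for p in range(spec.n_pathways):
        pid = f"ko9{p:04d}"
        size = rng.randint(lo, hi)
        n_shared = round(spec.overlap_fraction * size)
        n_shared = min(n_shared, len(shared_pool))
        members = set(rng.sample(shared_pool, n_shared))
        while len(members) < size:
            members.add(_ko(next_id))
            next_id += 1
        pathways[pid] = PathwayDefinition(pid, frozenset(members))
    collection = PathwayCollection(pathways)

    expressed: set[str] = set()
    for pid in spec.planted_active:
        if pid in collection:
            expressed |= collection[pid].members
    rest = sorted(collection.all_groups - expressed)
    n_bg = round(spec.background_expression * len(rest))
    expressed |= set(rng.sample(rest, n_bg))
    sample = SampleExpression(
        sample_id=f"synthetic-seed{spec.seed}", expressed=frozenset(expressed)
    )
    return collection, sample


def write_kgml_fixture(graph: PathwayGraph, path) -> None:
    """Emit a minimal well-formed KGML file that parses back to ``graph``.

    Only ``entry`` and ``relation`` elements are written (no graphics);
    entries are typed ``ortholog`` and labels get the ``ko:`` prefix KGML
    uses.  The mapped flag is sample-dependent and is not part of KGML, so
    the round trip restores topology and labels with all flags false.
    """
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name={quoteattr("path:" + graph.pathway_id)} '
        f'org="ko" number={quoteattr(graph.pathway_id.lstrip("ko"))}>',
    ]
    for nid in sorted(graph.graph.nodes):
        labels = " ".join(
            ("ko:" + l) if not l[0].isdigit() else ("ec:" + l)
            for l in sorted(graph.labels(nid))
        )
        lines.append(
            f"  <entry id={quoteattr(nid)} name={quoteattr(labels)} "
            'type="ortholog"/>'
        )
    for u, v in sorted(graph.graph.edges()):
        lines.append(
            f"  <relation entry1={quoteattr(u)} entry2={quoteattr(v)} "
            'type="ECrel"/>'
        )
    lines.append("</pathway>")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
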