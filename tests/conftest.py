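"""Shared builders for the test suite.

Graphs are built directly as networkx DiGraphs with the ``labels`` /
``mapped`` node attributes the package expects; families are built from
plain (pathway, members) mappings.  Everything here is deterministic.
"""

from __future__ import annotations

import random

import networkx as nx
import pytest

from pathwaylens.kgml_graph import PathwayGraph
from pathwaylens.pathway_data import PathwayCollection, PathwayDefinition


def make_graph(
    n_nodes: int,
    edges: list[tuple[int, int]],
    mapped: set[int] | None = None,
    pathway_id: str = "ko90001",
) -> PathwayGraph:
    """Graph on nodes n0..n{n-1}; each node labelled with its own KO id."""
    mapped = mapped or set()
    g = nx.DiGraph()
    for i in range(n_nodes):
        g.add_node(f"n{i}", labels=frozenset({f"K{i + 1:05d}"}), mapped=i in mapped)
    g.add_edges_from((f"n{u}", f"n{v}") for u, v in edges)
    return PathwayGraph(pathway_id=pathway_id, graph=g)


def make_collection(members: dict[str, set[str]]) -> PathwayCollection:
    return PathwayCollection(
        {pid: PathwayDefinition(pid, frozenset(ms)) for pid, ms in members.items()}
    )


def random_simple_digraph_edges(
    n_nodes: int, n_edges: int, rng: random.Random
) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    return rng.sample(pairs, n_edges)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20250930)
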