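"""Permutation null models and empirical significance for pathway graphs.

Two degree-aware null models randomize an annotated pathway graph:

* **Vertex label swapping** keeps the topology fixed and exchanges the
  mapped/unmapped labelling between pairs of nodes whose flags differ.  The
  number of mapped nodes is conserved, so the null asks: given this topology
  and this many expressed enzymes, how coherent could their placement be by
  chance?
* **Edge swapping** keeps the labelling fixed and rewires pairs of edges
  (a->b, c->d) into (a->d, c->b), rejecting swaps that would create a
  self-loop or a duplicate edge.  Every node's in- and out-degree is
  invariant, so the null preserves the degree sequence while scrambling
  which enzymes are adjacent.

An ensemble of m pairwise-distinct randomized graphs is summarized by the
induced-mapped-subgraph metrics of each member.  The observed graph is ranked
against the ensemble by (density descending, zero-degree fraction ascending);
the empirical p-value is rank/m.  Ties place the observed graph after
equal-keyed random graphs — conservative: ties inflate p, never deflate it.

Swap counts are *attempted* swaps: an attempt that draws an ineligible pair
has no effect but is still counted, which guarantees termination on rigid
graphs.  At the default n of one million attempts the distinction from
accepted-swap counting is negligible for mixing.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .kgml_graph import (
    GraphMetrics,
    PathwayGraph,
    compute_metrics,
    induced_mapped_subgraph,
)

__all__ = [
    "NullModel",
    "SignificanceClass",
    "NullEnsemble",
    "SignificanceResult",
    "EnsembleError",
    "vertex_label_swap",
    "edge_swap",
    "generate_null_ensemble",
    "rank_and_pvalue",
    "significance_class",
    "DEFAULT_M",
    "DEFAULT_N_SWAPS",
]

DEFAULT_M = 200
DEFAULT_N_SWAPS = 1_000_000


class NullModel(str, Enum):
    VERTEX_LABEL_SWAP = "vertex"
    EDGE_SWAP = "edge"


class SignificanceClass(str, Enum):
    MOST_SIGNIFICANT = "most_significant"
    VERY_SIGNIFICANT = "very_significant"
    SIGNIFICANT = "significant"
    NOT_SIGNIFICANT = "not_significant"


class EnsembleError(RuntimeError):
    """The graph is too small or rigid to admit the requested ensemble."""


@dataclass
class NullEnsemble:
    model: NullModel
    m: int
    n_swaps: int
    seed: int | None
    metrics_list: list[GraphMetrics] = field(default_factory=list)


@dataclass(frozen=True)
class SignificanceResult:
    pathway_id: str
    observed: GraphMetrics
    rank: int
    p_value: float
    significance_class: SignificanceClass


def vertex_label_swap(
    graph: PathwayGraph, n_swaps: int, rng: random.Random
) -> PathwayGraph:
    """Shuffle the mapped/unmapped labelling by pairwise swaps, topology fixed.

    Each attempt draws two distinct nodes uniformly; if their mapped flags
    differ, the flags (and KO/EC labels, which travel with the annotation)
    are exchanged, otherwise the attempt is rejected without effect.
    """
    out = graph.copy()
    nodes = sorted(out.graph.nodes)
    if len(nodes) < 2:
        return out
    attrs = out.graph.nodes
    flags = [bool(attrs[n]["mapped"]) for n in nodes]
    labels = [attrs[n]["labels"] for n in nodes]
    if len(set(flags)) < 2:
        warnings.warn(
            f"pathway {graph.pathway_id}: all nodes share one mapped flag; "
            "label swapping has no effect"
        )
        return out
    k = len(nodes)
    randrange = rng.randrange
    for _ in range(n_swaps):
        i = randrange(k)
        j = randrange(k - 1)
        if j >= i:
            j += 1
        if flags[i] != flags[j]:
            flags[i], flags[j] = flags[j], flags[i]
            labels[i], labels[j] = labels[j], labels[i]
    for n, f, l in zip(nodes, flags, labels):
        attrs[n]["mapped"] = f
        attrs[n]["labels"] = l
    return out


def edge_swap(
    graph: PathwayGraph, n_swaps: int, rng: random.Random
) -> PathwayGraph:
    """Rewire edge pairs (a->b, c->d) -> (a->d, c->b), degrees invariant.

    Attempts that would create a self-loop or duplicate an existing edge are
    rejected.  Node labels and mapped flags are untouched.
    """
    out = graph.copy()
    edges = sorted(out.graph.edges())
    if len(edges) < 2:
        warnings.warn(
            f"pathway {graph.pathway_id}: fewer than 2 edges; edge swapping "
            "has no effect"
        )
        return out
    edge_set = set(edges)
    ne = len(edges)
    for _ in range(n_swaps):
        i = rng.randrange(ne)
        j = rng.randrange(ne - 1)
        if j >= i:
            j += 1
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    g = out.graph
    g.remove_edges_from(list(g.edges()))
    g.add_edges_from(edges)
    return out


def _signature(model: NullModel, graph: PathwayGraph) -> frozenset:
    if model is NullModel.VERTEX_LABEL_SWAP:
        return graph.mapped_nodes()
    return graph.edge_set()


def generate_null_ensemble(
    graph: PathwayGraph,
    model: NullModel,
    m: int = DEFAULT_M,
    n_swaps: int = DEFAULT_N_SWAPS,
    rng: random.Random | None = None,
    seed: int | None = None,
    max_retries: int = 100,
) -> NullEnsemble:
    """Generate m pairwise-distinct randomized graphs and record the metrics
    of each member's induced mapped subgraph.

    Distinctness is per model: the mapped-node assignment for label swapping,
    the edge set for edge swapping.  Each member is randomized independently
    from the observed graph (not chained).  If a distinct state cannot be
    found within ``max_retries`` attempts for some slot, an
    :class:`EnsembleError` is raised advising a smaller m — silently
    duplicating null members would bias the rank.
    """
    if rng is None:
        rng = random.Random(seed)
    swap = (
        vertex_label_swap if model is NullModel.VERTEX_LABEL_SWAP else edge_swap
    )
    seen: set[frozenset] = set()
    metrics: list[GraphMetrics] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(m):
            for _attempt in range(max_retries):
                randomized = swap(graph, n_swaps, rng)
                sig = _signature(model, randomized)
                if sig not in seen:
                    seen.add(sig)
                    metrics.append(
                        compute_metrics(induced_mapped_subgraph(randomized))
                    )
                    break
            else:
                raise EnsembleError(
                    f"pathway {graph.pathway_id}: could not generate "
                    f"{m} distinct {model.value}-model graphs "
                    f"(got {len(metrics)}); use a smaller m"
                )
    return NullEnsemble(
        model=model, m=m, n_swaps=n_swaps, seed=seed, metrics_list=metrics
    )


def rank_and_pvalue(
    observed: GraphMetrics,
    ensemble: NullEnsemble,
    pathway_id: str = "",
) -> SignificanceResult:
    """Rank the observed metrics within the ensemble and convert to p = rank/m.

    The combined list is ordered by density (largest first) then by the
    zero-degree fraction (smallest first).  The observed record is placed
    after ensemble entries with an identical key, so rank counts every null
    member that is at least as good.  p may reach rank (m+1)/m when the
    observed graph is worst; it is clipped to 1.
    """
    if not ensemble.metrics_list:
        raise ValueError("empty ensemble")
    key = observed.sort_key()
    rank = 1 + sum(1 for r in ensemble.metrics_list if r.sort_key() <= key)
    p = min(rank / ensemble.m, 1.0)
    return SignificanceResult(
        pathway_id=pathway_id,
        observed=observed,
        rank=rank,
        p_value=p,
        significance_class=significance_class(p),
    )


def significance_class(p: float) -> SignificanceClass:
    """Map an empirical p-value to its significance class.

    <=0.5% most significant; <1% very significant; <5% significant.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value {p} outside (0, 1]")
    if p <= 0.005:
        return SignificanceClass.MOST_SIGNIFICANT
    if p < 0.01:
        return SignificanceClass.VERY_SIGNIFICANT
    if p < 0.05:
        return SignificanceClass.SIGNIFICANT
    return SignificanceClass.NOT_SIGNIFICANT
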