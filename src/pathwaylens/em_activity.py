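"""The uniform binary pathway-activity model.

Pathways compete for shared ortholog groups.  Under the uniformity
assumption, a group g contributes to pathway w the participation

    g_w = 1 / (1 + sum over other active pathways w' containing g of delta(w'))

i.e. a group shared by s pathways that are all currently active splits one
unit of evidence equally among them.  The activity level of a pathway is the
sum of participations over its members, f_w = sum_{g in w} g_w, and its
binary status is delta(w) = 1 iff f_w >= T_w for a (possibly per-pathway)
threshold T_w.

The fixed-point iteration starts all-active and alternates level and status
updates.  Because the status vector lives in a finite space, the trajectory
must eventually revisit a state; the first revisit closes a terminal cycle of
period k (k = 1 is a fixed point).  Reported activity levels are the
arithmetic mean of f over one full terminal cycle — the only reading that is
well-defined for oscillating trajectories.  Shared groups fluctuating between
pathways are exactly what produces k > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .pathway_data import PathwayCollection

__all__ = [
    "ActivityState",
    "Thresholds",
    "ActivityResult",
    "ConvergenceError",
    "participation",
    "activity_levels",
    "update_status",
    "run_em",
]


@dataclass(frozen=True)
class ActivityState:
    """Binary activity status per pathway at one iteration."""

    status: Mapping[str, int]
    iteration: int = 0

    def key(self) -> tuple[int, ...]:
        return tuple(self.status[p] for p in sorted(self.status))


@dataclass(frozen=True)
class Thresholds:
    """Activity thresholds T_w > 0: a global default plus per-pathway overrides.

    The default of 1.0 demands one full ortholog-group-equivalent of
    participation before a pathway counts as active.  Rankings of activity
    levels are empirically insensitive to the exact value (checked as a
    property, since no canonical threshold exists).
    """

    default: float = 1.0
    per_pathway: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.default <= 0 or any(v <= 0 for v in self.per_pathway.values()):
            raise ValueError("thresholds must be positive")

    def for_pathway(self, pathway_id: str) -> float:
        return self.per_pathway.get(pathway_id, self.default)


@dataclass
class ActivityResult:
    """Outcome of the fixed-point iteration.

    levels: cycle-mean f_w per pathway; final_states: the states of one
    terminal cycle; period: its length (1 = converged to a fixed point).
    """

    levels: dict[str, float]
    final_states: list[ActivityState]
    n_iterations: int
    period: int

    def final_status(self, pathway_id: str) -> int:
        return self.final_states[-1].status[pathway_id]


class ConvergenceError(RuntimeError):
    """max_iter reached without a state revisit; carries the partial trace."""

    def __init__(self, message: str, trace: list[ActivityState]):
        super().__init__(message)
        self.trace = trace


def participation(
    g: str, w: str, collection: PathwayCollection, state: ActivityState
) -> float:
    """Participation g_w of group g in pathway w given the current statuses.

    The pathway's own status never gates its own level: the sum runs over
    *other* pathways containing g, and the constant 1 remains even when
    delta(w) = 0.
    """
    if g not in collection[w].members:
        raise ValueError(f"group {g!r} is not a member of pathway {w!r}")
    active_others = sum(
        state.status[w2]
        for w2 in collection.group_index[g]
        if w2 != w and w2 in state.status
    )
    return 1.0 / (1.0 + active_others)


def activity_levels(
    collection: PathwayCollection, state: ActivityState
) -> dict[str, float]:
    """f_w = sum over members of their participation, for every pathway."""
    return {
        pw.pathway_id: sum(
            participation(g, pw.pathway_id, collection, state)
            for g in pw.members
        )
        for pw in collection
    }


def update_status(
    levels: Mapping[str, float], thresholds: Thresholds, iteration: int = 0
) -> ActivityState:
    """delta(w) = 1 iff f_w >= T_w (equality counts as active)."""
    return ActivityState(
        status={
            pid: (0 if f < thresholds.for_pathway(pid) else 1)
            for pid, f in levels.items()
        },
        iteration=iteration,
    )


def run_em(
    collection: PathwayCollection,
    thresholds: Thresholds | None = None,
    max_iter: int = 1000,
) -> ActivityResult:
    """Iterate level/status updates from the all-active start until the
    status sequence revisits a state, then report cycle-mean levels.

    The state space is finite so a revisit is guaranteed within 2^|W| steps;
    ``max_iter`` is a safety valve and raising :class:`ConvergenceError`
    preserves the partial trace for inspection.
    """
    if len(collection) == 0:
        raise ValueError("empty pathway collection")
    if thresholds is None:
        thresholds = Thresholds()

    state = ActivityState(
        status={pw.pathway_id: 1 for pw in collection}, iteration=0
    )
    trace = [state]
    first_seen: dict[tuple[int, ...], int] = {state.key(): 0}

    for n in range(1, max_iter + 1):
        levels = activity_levels(collection, state)
        state = update_status(levels, thresholds, iteration=n)
        key = state.key()
        if key in first_seen:
            start = first_seen[key]
            cycle = trace[start:]
            period = n - start
            mean_levels: dict[str, float] = {
                pw.pathway_id: 0.0 for pw in collection
            }
            for cyc_state in cycle:
                for pid, f in activity_levels(collection, cyc_state).items():
                    mean_levels[pid] += f / period
            return ActivityResult(
                levels=mean_levels,
                final_states=cycle,
                n_iterations=n,
                period=period,
            )
        first_seen[key] = n
        trace.append(state)

    raise ConvergenceError(
        f"no state revisit within {max_iter} iterations", trace
    )
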