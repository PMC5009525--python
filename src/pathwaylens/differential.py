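"""Two-sample differential analysis of pathway activity and significance.

Activity branch: pathways are compared by the ratio of their activity levels
between two samples; a ratio at or above 1.5 calls the pathway up, at or
below 0.66 down.  A zero denominator yields an explicit ``undefined`` call
with the raw levels preserved (never dropped, never pseudocounted).

Significance branch: each sample contributes a permutation p-value for the
pathway.  The two are combined by

    probDiff = (1 - p_small) * p_large

where p_small/p_large are the smaller and larger of the two p-values.  The
statistic is symmetric in its arguments and large exactly when the pathway is
strongly significant in one sample but not the other; values above 0.5 call
the pathway differentially significant.  No multiple-testing adjustment is
applied to either branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ActivityCall",
    "DifferentialActivityRecord",
    "DifferentialSignificanceRecord",
    "activity_ratio",
    "call_differential_activity",
    "prob_diff",
    "call_differential_significance",
    "UP_THRESHOLD",
    "DOWN_THRESHOLD",
    "PROBDIFF_CUTOFF",
]

UP_THRESHOLD = 1.5
DOWN_THRESHOLD = 0.66
PROBDIFF_CUTOFF = 0.5


class ActivityCall(str, Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class DifferentialActivityRecord:
    pathway_id: str
    level_sample1: float
    level_sample2: float
    ratio: float | None
    call: ActivityCall


@dataclass(frozen=True)
class DifferentialSignificanceRecord:
    pathway_id: str
    p1: float
    p2: float
    prob_diff: float
    differential: bool


def activity_ratio(level1: float, level2: float) -> float | None:
    """level1 / level2, or None when the denominator is zero."""
    if level1 < 0 or level2 < 0:
        raise ValueError("activity levels must be non-negative")
    if level2 == 0:
        return None
    return level1 / level2


def call_differential_activity(
    pathway_id: str,
    level1: float,
    level2: float,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
) -> DifferentialActivityRecord:
    """Classify one pathway's activity change between two samples.

    ratio >= up_threshold -> up; ratio <= down_threshold -> down; otherwise
    unchanged.  A zero level-2 denominator propagates as undefined.
    """
    if not (0 < down_threshold < 1 < up_threshold):
        raise ValueError("thresholds must satisfy 0 < down < 1 < up")
    ratio = activity_ratio(level1, level2)
    if ratio is None:
        call = ActivityCall.UNDEFINED
    elif ratio >= up_threshold:
        call = ActivityCall.UP
    elif ratio <= down_threshold:
        call = ActivityCall.DOWN
    else:
        call = ActivityCall.UNCHANGED
    return DifferentialActivityRecord(
        pathway_id=pathway_id,
        level_sample1=level1,
        level_sample2=level2,
        ratio=ratio,
        call=call,
    )


def prob_diff(p1: float, p2: float) -> float:
    """probDiff = (1 - p1) * p2 if p2 >= p1, else (1 - p2) * p1.

    Both branches agree at p1 = p2, so the statistic is symmetric; its value
    lies in [0, 1) and never exceeds 0.25 when the two p-values coincide.
    """
    for p in (p1, p2):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    if p2 >= p1:
        return (1.0 - p1) * p2
    return (1.0 - p2) * p1


def call_differential_significance(
    pathway_id: str,
    p1: float,
    p2: float,
    cutoff: float = PROBDIFF_CUTOFF,
) -> DifferentialSignificanceRecord:
    """Differential iff probDiff strictly exceeds the cutoff (default 50%)."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    pd = prob_diff(p1, p2)
    return DifferentialSignificanceRecord(
        pathway_id=pathway_id,
        p1=p1,
        p2=p2,
        prob_diff=pd,
        differential=pd > cutoff,
    )
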