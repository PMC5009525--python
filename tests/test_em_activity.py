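"""Uniform binary activity model: participation, levels, and the iteration."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from pathwaylens.em_activity import (
    ActivityState,
    Thresholds,
    activity_levels,
    participation,
    run_em,
    update_status,
)

from .conftest import make_collection


def naive_em(members: dict[str, set[str]], threshold: float, max_iter: int = 200):
    """Independent brute-force simulation of the state machine.

    Written as plain nested loops over the membership dict, with no shared
    code with the implementation under test.
    """
    pids = sorted(members)

    def lv(state):
        out = {}
        for p in pids:
            total = 0.0
            for g in members[p]:
                denom = 1
                for q in pids:
                    if q != p and g in members[q] and state[q] == 1:
                        denom += 1
                total += 1.0 / denom
            out[p] = total
        return out

    state = {p: 1 for p in pids}
    trace = [dict(state)]
    for n in range(1, max_iter + 1):
        state = {p: (1 if f >= threshold else 0) for p, f in lv(state).items()}
        for j, earlier in enumerate(trace):
            if earlier == state:
                cycle = trace[j:]
                period = n - j
                mean = {p: 0.0 for p in pids}
                for s in cycle:
                    for p, f in lv(s).items():
                        mean[p] += f / period
                return mean, period, n
        trace.append(dict(state))
    raise AssertionError("naive simulation did not cycle")


def test_participation_examples():
    coll = make_collection(
        {"w": {"g"}, "a": {"g", "x"}, "b": {"g"}, "c": {"g"}}
    )
    all_active = ActivityState({p: 1 for p in ("w", "a", "b", "c")})
    # g in w plus 3 others, statuses {1,0,1} -> 1/3
    mixed = ActivityState({"w": 1, "a": 1, "b": 0, "c": 1})
    assert participation("g", "w", coll, mixed) == pytest.approx(1 / 3)
    assert participation("g", "w", coll, all_active) == pytest.approx(1 / 4)
    only = make_collection({"w": {"g"}})
    assert participation("g", "w", only, ActivityState({"w": 0})) == 1.0


def test_participation_rejects_non_member():
    coll = make_collection({"w": {"g"}})
    with pytest.raises(ValueError, match="not a member"):
        participation("h", "w", coll, ActivityState({"w": 1}))


def test_levels_disjoint_pathways_equal_sizes():
    coll = make_collection({"a": {"g1", "g2"}, "b": {"g3", "g4", "g5"}})
    for status in ({"a": 1, "b": 1}, {"a": 0, "b": 0}, {"a": 1, "b": 0}):
        lv = activity_levels(coll, ActivityState(status))
        assert lv == {"a": 2.0, "b": 3.0}


def test_levels_fully_shared_pathways_split_evenly():
    groups = {"g1", "g2", "g3", "g4"}
    coll = make_collection({"a": groups, "b": groups})
    lv = activity_levels(coll, ActivityState({"a": 1, "b": 1}))
    assert lv == {"a": 2.0, "b": 2.0}


def test_update_status_boundary_is_active_at_threshold():
    st_ = update_status({"a": 1.0, "b": 0.999, "c": 0.0}, Thresholds(default=1.0))
    assert st_.status == {"a": 1, "b": 0, "c": 0}


def test_thresholds_must_be_positive():
    with pytest.raises(ValueError):
        Thresholds(default=0.0)
    with pytest.raises(ValueError):
        Thresholds(default=1.0, per_pathway={"a": -1.0})


def test_all_active_participation_sums_to_one_per_group():
    # conservation: a group shared by s all-active pathways splits one unit
    coll = make_collection(
        {"a": {"g", "x"}, "b": {"g", "y"}, "c": {"g"}, "d": {"z"}}
    )
    state = ActivityState({p: 1 for p in "abcd"})
    for g, owners in coll.group_index.items():
        total = sum(participation(g, w, coll, state) for w in owners)
        assert total == pytest.approx(1.0)


def test_run_em_disjoint_family_fixed_point():
    coll = make_collection({"a": {"g1", "g2"}, "b": {"g3"}})
    res = run_em(coll, Thresholds(default=1.0))
    assert res.period == 1
    assert res.n_iterations == 1
    assert res.levels == {"a": 2.0, "b": 1.0}
    assert res.final_status("a") == 1


def test_run_em_two_pathway_oscillation():
    # a and b share both groups; T=1.5: all-active gives f=1 (<T) -> both off,
    # both-off gives f=2 (>=T) -> both on: a period-2 cycle from the start.
    groups = {"g1", "g2"}
    coll = make_collection({"a": groups, "b": groups})
    res = run_em(coll, Thresholds(default=1.5))
    assert res.period == 2
    assert res.levels == {"a": pytest.approx(1.5), "b": pytest.approx(1.5)}
    keys = [s.key() for s in res.final_states]
    assert sorted(keys) == [(0, 0), (1, 1)]


small_families = st.dictionaries(
    st.sampled_from(["w1", "w2", "w3", "w4"]),
    st.frozensets(st.sampled_from(["g1", "g2", "g3", "g4", "g5", "g6"]), min_size=1),
    min_size=1,
    max_size=4,
)


@given(fam=small_families, threshold=st.sampled_from([0.5, 1.0, 1.5, 2.0, 3.0]))
@settings(max_examples=80, deadline=None)
def test_run_em_matches_bruteforce_state_machine(fam, threshold):
    coll = make_collection({p: set(ms) for p, ms in fam.items()})
    res = run_em(coll, Thresholds(default=threshold))
    mean, period, n = naive_em({p: set(ms) for p, ms in fam.items()}, threshold)
    assert res.period == period
    assert res.n_iterations == n
    assert res.levels == pytest.approx(mean)


def test_run_em_rejects_empty_collection():
    import pathwaylens.pathway_data as pd

    with pytest.raises(ValueError, match="empty"):
        run_em(pd.PathwayCollection({}), Thresholds())


def test_run_em_cycles_on_larger_random_families():
    from pathwaylens.synthetic_fixtures import FixtureSpec, random_pathway_family

    spec = FixtureSpec(seed=3, n_pathways=50, groups_per_pathway=(3, 10),
                       overlap_fraction=0.5)
    coll, _ = random_pathway_family(spec)
    res = run_em(coll, Thresholds(default=1.0), max_iter=1000)
    assert res.period >= 1
    assert res.n_iterations <= 1000
    assert all(0.0 <= f <= len(coll[p].members) for p, f in res.levels.items())


def test_ranking_stable_under_threshold_doubling():
    from scipy.stats import spearmanr

    from pathwaylens.synthetic_fixtures import FixtureSpec, random_pathway_family

    spec = FixtureSpec(seed=11, n_pathways=40, groups_per_pathway=(3, 10),
                       overlap_fraction=0.4)
    coll, _ = random_pathway_family(spec)
    lv_a = run_em(coll, Thresholds(default=1.0)).levels
    lv_b = run_em(coll, Thresholds(default=2.0)).levels
    pids = sorted(lv_a)
    rho, _ = spearmanr([lv_a[p] for p in pids], [lv_b[p] for p in pids])
    assert rho > 0.8
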