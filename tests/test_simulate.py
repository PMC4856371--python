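"""Hudson's algorithm: state mechanics, event draws, merging, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coalseq import simulate
from coalseq.simulate import (
    COMMON_ANCESTOR,
    RECOMBINATION,
    SimulationParams,
    ancestor_links,
    common_ancestor_event,
    defragment_segments,
    draw_next_event,
    initialise_state,
    merge_ancestors,
    recombination_event,
)


def make_state(n, m, ancestors, rho=0.0, seed=1, t=0.0):
    """A simulation state with a hand-picked population.

    The overlap counter is rebuilt from the given segments so the state
    is internally consistent.
    """
    state = initialise_state(SimulationParams(n=n, m=m, rho=rho, seed=seed))
    for slot in list(state._occupied):
        state.remove_ancestor(slot)
    slots = [state.add_ancestor(segs) for segs in ancestors]
    bounds = sorted({c for segs in ancestors for l, r, _ in segs for c in (l, r)})
    pos, cnt = [0], []
    for x in bounds:
        if x != pos[-1]:
            pos.append(x)
    if pos[-1] != m:
        pos.append(m)
    for x1 in pos[:-1]:
        cnt.append(
            sum(
                1
                for segs in ancestors
                for l, r, _ in segs
                if l <= x1 < r
            )
        )
    state.overlap.pos = pos
    state.overlap.cnt = cnt
    state.t = t
    return state, slots


def brute_force_coverage(state, x):
    return sum(
        1 for segs in state.ancestors() for l, r, _ in segs if l <= x < r
    )


class TestParamsAndInit:
    def test_initial_state(self):
        state = initialise_state(SimulationParams(n=4, m=10))
        assert state.num_ancestors == 4
        assert state.L == 4 * 9
        assert state.w == 5 and state.t == 0.0
        assert sorted(state.ancestors()) == [[(0, 10, u)] for u in range(1, 5)]
        assert all(state.overlap.count_at(x) == 4 for x in range(10))

    def test_single_site_has_no_links(self):
        state = initialise_state(SimulationParams(n=2, m=1))
        assert state.L == 0

    def test_large_population_initialisation(self):
        state = initialise_state(SimulationParams(n=1000, m=50_000_000))
        assert state.num_ancestors == 1000
        assert state.w == 1001

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=1, m=10), dict(n=2, m=0), dict(n=2, m=10, rho=-1.0),
         dict(n=2, m=1, rho=1.0)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)


class TestAncestorLinks:
    def test_single_segment(self):
        assert ancestor_links([(0, 10, 1)]) == 9

    def test_gap_counts_as_breakable(self):
        assert ancestor_links([(0, 2, 1), (7, 10, 2)]) == 9

    def test_unit_segment_unbreakable(self):
        assert ancestor_links([(3, 4, 1)]) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ancestor_links([])


class TestDefragment:
    @pytest.mark.parametrize(
        "segments, expected",
        [
            ([(0, 3, 1), (3, 7, 1)], [(0, 7, 1)]),
            ([(0, 3, 1), (3, 7, 2)], [(0, 3, 1), (3, 7, 2)]),
            ([(0, 2, 1), (2, 4, 1), (4, 9, 1)], [(0, 9, 1)]),
            ([(0, 2, 1), (3, 4, 1)], [(0, 2, 1), (3, 4, 1)]),
        ],
    )
    def test_merging_rules(self, segments, expected):
        assert defragment_segments(segments) == expected
        assert ancestor_links(defragment_segments(segments)) == ancestor_links(segments)


class TestEventDraws:
    def test_no_recombination_without_rho(self):
        state = initialise_state(SimulationParams(n=5, m=100, rho=0.0, seed=2))
        kinds = {draw_next_event(state)[1] for _ in range(200)}
        assert kinds == {COMMON_ANCESTOR}

    def test_no_recombination_without_links(self):
        # five ancestors, all single-site segments: L = 0
        state, _ = make_state(
            5, 5, [[(i, i + 1, i + 1)] for i in range(5)], rho=10.0
        )
        assert state.L == 0
        kinds = {draw_next_event(state)[1] for _ in range(200)}
        assert kinds == {COMMON_ANCESTOR}

    def test_pair_coalescence_waiting_time_mean(self):
        # n=2: single event at rate |P|(|P|-1) = 2, mean wait 1/2
        state = initialise_state(SimulationParams(n=2, m=1, seed=3))
        waits = np.array([draw_next_event(state)[0] for _ in range(10_000)])
        assert waits.mean() == pytest.approx(0.5, abs=3 * waits.std() / 100)


class TestRecombination:
    def test_straddling_segment_split(self):
        # only ancestor 1 has links, so the break must split (0, 10, 1)
        state, _ = make_state(2, 10, [[(0, 10, 1)], [(0, 1, 2)]], rho=1.0, seed=4)
        assert state.L == 9
        recombination_event(state)
        assert state.num_ancestors == 3
        split = sorted(
            segs[0] for segs in state.ancestors() if segs[0][2] == 1
        )
        assert len(split) == 2
        (l1, r1, _), (l2, r2, _) = split
        assert (l1, r2) == (0, 10) and r1 == l2 and 0 < r1 < 10
        assert state.counts.recombination_within_ancestral == 1

    def test_break_in_gap_moves_whole_segments(self):
        # break positions 2..5 of the first ancestor fall in its gap
        found_gap_break = False
        for trial in range(50):
            s, _ = make_state(
                2, 10, [[(0, 2, 1), (5, 8, 2)], [(0, 10, 3)]], rho=1.0, seed=trial
            )
            recombination_event(s)
            pieces = [segs for segs in s.ancestors() if segs != [(0, 10, 3)]]
            if [(0, 2, 1)] in pieces and [(5, 8, 2)] in pieces:
                found_gap_break = True
                assert s.counts.recombination_within_ancestral == 0
                break
        assert found_gap_break

    def test_link_choice_uniform_over_links(self):
        # ancestors with 9 and 3 links: every one of the 12 links is
        # equally likely, so ancestors are hit in 9:3 proportion
        state, _ = make_state(2, 20, [[(0, 10, 1)], [(12, 16, 2)]], rho=1.0)
        rng = np.random.default_rng(321)
        trials = 60_000
        hits = {}
        for _ in range(trials):
            g = int(rng.integers(1, state.L + 1))
            slot, residual = state._fenwick.find(g)
            hits[(slot, residual)] = hits.get((slot, residual), 0) + 1
        assert len(hits) == 12  # every link reachable
        observed = np.array(list(hits.values()))
        expected = np.full(12, trials / 12)
        chi2 = (((observed - expected) ** 2) / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=11)

    def test_preserves_overlap_counts(self):
        state, _ = make_state(3, 20, [[(0, 20, u)] for u in (1, 2, 3)], rho=1.0, seed=9)
        before = [brute_force_coverage(state, x) for x in range(20)]
        recombination_event(state)
        after = [brute_force_coverage(state, x) for x in range(20)]
        assert before == after
        assert [state.overlap.count_at(x) for x in range(20)] == after


class TestMerge:
    def test_disjoint_union_emits_no_record(self):
        state, slots = make_state(
            3, 10, [[(0, 3, 1)], [(5, 8, 2)], [(0, 10, 3)]], seed=6
        )
        merge_ancestors(state, slots[0], slots[1])
        assert state.records == []
        assert [(0, 3, 1), (5, 8, 2)] in state.ancestors()
        assert state.num_ancestors == 2

    def test_final_pair_coalescence(self):
        state, slots = make_state(2, 1, [[(0, 1, 1)], [(0, 1, 2)]], t=0.7, seed=7)
        merge_ancestors(state, slots[0], slots[1])
        assert state.num_ancestors == 0
        (rec,) = state.records
        assert rec.astuple() == (0, 1, 3, (1, 2), 0.7)

    def test_overhangs_and_partial_completion(self):
        # a=[(0,6,u)], b=[(4,10,v)], third ancestor spans [0,10):
        # only [4,6) coalesces, and it stays ancestral (count 3 there).
        state, slots = make_state(
            3, 10, [[(0, 6, 1)], [(4, 10, 2)], [(0, 10, 3)]], t=0.4, seed=8
        )
        merge_ancestors(state, slots[0], slots[1])
        (rec,) = state.records
        assert rec.astuple() == (4, 6, 4, (1, 2), 0.4)
        assert [(0, 4, 1), (4, 6, 4), (6, 10, 2)] in state.ancestors()
        assert state.w == 5

    def test_shared_node_for_disjoint_coalescing_intervals(self):
        # a and b overlap on two disjoint intervals: one event, one w
        state, slots = make_state(
            3,
            10,
            [
                [(0, 2, 1), (6, 9, 1)],
                [(0, 9, 2)],
                [(0, 10, 3)],
            ],
            t=0.3,
            seed=10,
        )
        merge_ancestors(state, slots[0], slots[1])
        assert len(state.records) == 2
        assert {r.node for r in state.records} == {4}
        assert {r.time for r in state.records} == {0.3}
        assert state.w == 5

    def test_fully_coalesced_interval_dropped(self):
        state, slots = make_state(2, 10, [[(0, 10, 1)], [(3, 7, 2)]], t=0.2, seed=11)
        merge_ancestors(state, slots[0], slots[1])
        (rec,) = state.records
        assert rec.astuple() == (3, 7, 3, (1, 2), 0.2)
        # [3,7) completed; flanks remain under node 1
        assert [(0, 3, 1), (7, 10, 1)] in state.ancestors()
        assert state.overlap.count_at(4) == 0


class TestBookkeepingInvariants:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_incremental_l_and_overlap_match_brute_force(self, seed):
        params = SimulationParams(n=6, m=30, rho=3.0, seed=seed)
        state = initialise_state(params)
        while state.num_ancestors > 0:
            dt, kind = draw_next_event(state)
            state.t += dt
            if kind == RECOMBINATION:
                recombination_event(state)
            else:
                common_ancestor_event(state)
            assert state.L == state.compute_L()
            for x in range(0, params.m, 7):
                assert state.overlap.count_at(x) == brute_force_coverage(state, x)
        assert all(c == 0 for c in state.overlap.cnt)

    def test_node_labels_increase_with_time(self):
        ts = simulate(n=10, m=50, rho=5.0, seed=12)
        order = np.argsort(ts.time, kind="stable")
        nodes_in_time_order = ts.node[order]
        assert np.all(np.diff(nodes_in_time_order) >= 0)


class TestSimulateOutput:
    def test_determinism(self):
        a = simulate(n=9, m=80, rho=4.0, seed=99)
        b = simulate(n=9, m=80, rho=4.0, seed=99)
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate(n=9, m=80, rho=4.0, seed=99)
        b = simulate(n=9, m=80, rho=4.0, seed=100)
        assert a != b

    def test_pair_kingman_record_and_time(self):
        times = []
        for seed in range(2000):
            ts = simulate(n=2, m=1, rho=0.0, seed=seed)
            assert ts.M == 1
            rec = ts.records()[0]
            assert rec.left == 0 and rec.right == 1 and rec.node == 3
            assert rec.children == (1, 2) and rec.time > 0
            times.append(rec.time)
        times = np.array(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert times.mean() == pytest.approx(0.5, abs=3 * se)

    def test_kingman_reduction_records_and_tmrca(self):
        tmrca = []
        for seed in range(1500):
            ts = simulate(n=10, m=1, rho=0.0, seed=seed)
            assert ts.M == 9
            tmrca.append(ts.time.max())
        tmrca = np.array(tmrca)
        se = tmrca.std(ddof=1) / np.sqrt(len(tmrca))
        assert tmrca.mean() == pytest.approx(0.9, abs=3 * se)

    def test_event_counts_reported(self):
        ts, counts = simulate(n=10, m=100, rho=5.0, seed=13, return_counts=True)
        assert counts.coalescence_events >= ts.M
        assert counts.recombination_events >= counts.recombination_within_ancestral
        assert counts.common_ancestor_events > 0
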