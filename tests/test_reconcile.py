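"""The fixed-timing DP: exactness properties, constraints, special cases."""

import dataclasses
import math

import numpy as np
import pytest

from cophylo import (
    CostScheme,
    RegionSpec,
    Tanglegram,
    TimedGrid,
    TimeZoneSpec,
    Tree,
    evaluate_mapping,
    greedy_no_switch,
    simulate_host,
    solve,
    switch_distance,
)
from cophylo.positions import HANDLE
from cophylo.timing import all_timings, random_timing

from conftest import make_congruent, tiny_histories

BALANCED = Tree({"r": ("x", "y"), "x": ("a", "b"), "y": ("c", "d")}, root="r")


class TestSwitchDistance:
    def test_sibling_edges_distance_one(self):
        assert switch_distance(BALANCED, ("x", "a"), ("x", "b")) == 1
        assert switch_distance(BALANCED, ("r", "x"), ("r", "y")) == 1

    def test_opposite_sides_distance_three(self):
        assert switch_distance(BALANCED, ("x", "a"), ("y", "c")) == 3

    def test_symmetric(self):
        for e, f in [(("x", "a"), ("y", "c")), (("r", "x"), ("x", "b"))]:
            assert switch_distance(BALANCED, e, f) == switch_distance(BALANCED, f, e)

    def test_identical_edges_rejected(self):
        with pytest.raises(ValueError):
            switch_distance(BALANCED, ("x", "a"), ("x", "a"))


class TestCongruentTanglegram:
    def test_all_cospeciations_at_zero_cost(self):
        """A parasite tree identical to its host reconciles with one
        cospeciation per host divergence and nothing else."""
        for seed in range(10):
            host, timing = simulate_host(6, np.random.default_rng(seed))
            tg = make_congruent(host)
            sol = solve(tg, timing)
            assert sol.feasible
            assert sol.total_cost == 0.0
            assert sol.counts.cospeciations == host.m
            assert sol.counts.duplications == 0
            assert sol.counts.host_switches == 0
            assert sol.counts.losses == 0

    def test_zero_cost_under_every_timing(self):
        host, _ = simulate_host(5, np.random.default_rng(42))
        tg = make_congruent(host)
        for t in all_timings(host):
            assert solve(tg, t).total_cost == 0.0


class TestForcedSwitch:
    """host (h1,h2); parasite ((p1,p2),p3) with p1:h1, p2:h2, p3:h2.
    The cheapest embedding cospeciates at the root and switches once."""

    def setup_method(self):
        host = Tree({"r": ("h1", "h2")}, root="r")
        para = Tree({"P1": ("P2", "p3"), "P2": ("p1", "p2")}, root="P1")
        self.tg = Tanglegram(host, para, {"p1": "h1", "p2": "h2", "p3": "h2"})
        self.timing = {"r": 1}

    def test_cost_and_events(self):
        sol = solve(self.tg, self.timing)
        assert sol.total_cost == 1.0
        assert sol.counts.cospeciations == 1
        assert sol.counts.host_switches == 1
        assert sol.counts.losses == 0

    def test_switch_record_is_contemporaneous(self):
        sol = solve(self.tg, self.timing)
        (rec,) = sol.switches
        grid = TimedGrid(self.tg.host, self.timing)
        e = grid.edge_index[rec.takeoff_edge]
        f = grid.edge_index[rec.landing_edge]
        assert e in grid.alive[rec.slice_index]
        assert f in grid.alive[rec.slice_index]
        assert rec.takeoff_edge != rec.landing_edge
        assert rec.switching_child in self.tg.parasite.children[rec.parasite_vertex]

    def test_switch_includes_duplication_surcharge(self):
        self.tg.costs = CostScheme(switch_includes_duplication=True)
        assert solve(self.tg, self.timing).total_cost == 2.0

    def test_infinite_switch_cost_forbids_switches(self):
        self.tg.costs = CostScheme(switch_cost=math.inf)
        sol = solve(self.tg, self.timing)
        assert sol.feasible and sol.counts.host_switches == 0
        # root duplicates above the host root, one lineage cospeciates,
        # the other loses one side: 2 duplications is the alternative —
        # either way the optimum without switches costs more than 1
        assert sol.total_cost > 1.0


class TestAgainstRecordedHistories:
    def test_true_history_recosts_exactly(self):
        """The mapping evaluator charged with the recorded annotations
        reproduces the simulator's own event counts and cost."""
        for hist, _ in tiny_histories(8_100, 40):
            tg = hist.tanglegram
            ev = evaluate_mapping(tg, hist.placements, hist.timing, hist.annotations)
            assert ev.feasible, ev.message
            assert ev.total_cost == pytest.approx(hist.total_cost)
            assert ev.counts.as_dict() == hist.counts.as_dict()

    def test_solver_never_beaten_by_truth(self):
        for hist, _ in tiny_histories(8_200, 40):
            sol = solve(hist.tanglegram, hist.timing)
            assert sol.feasible
            assert sol.total_cost <= hist.total_cost + 1e-9

    def test_solution_recosts_to_its_own_total(self):
        """Backtracked placements, re-costed independently by the mapping
        evaluator, give exactly the DP's optimum."""
        for hist, _ in tiny_histories(8_300, 40):
            sol = solve(hist.tanglegram, hist.timing)
            ev = evaluate_mapping(hist.tanglegram, sol.placements, hist.timing)
            assert ev.feasible, ev.message
            assert ev.total_cost == pytest.approx(sol.total_cost)

    def test_deterministic(self):
        for hist, _ in tiny_histories(8_400, 5):
            a = solve(hist.tanglegram, hist.timing)
            b = solve(hist.tanglegram, hist.timing)
            assert a.to_json() == b.to_json()


class TestConstraints:
    def test_zone_infeasible_tip_reported(self):
        host, timing = simulate_host(4, np.random.default_rng(3))
        tg = make_congruent(host)
        tip = host.tips[0]
        tg.zones = TimeZoneSpec({tip: (1, 2)}, {tip: (5, 9)})
        sol = solve(tg, timing)
        assert not sol.feasible
        assert tip in sol.message

    def test_consistent_zones_leave_optimum_unchanged(self):
        host, timing = simulate_host(4, np.random.default_rng(3))
        tg = make_congruent(host)
        # the true ranks themselves as zones: satisfied by the congruent embedding
        tg.zones = TimeZoneSpec(
            {v: (r, r) for v, r in timing.items()},
            {v: (r, r) for v, r in timing.items()},
        )
        assert solve(tg, timing).total_cost == 0.0

    def test_distance_bound_respected_and_monotone(self):
        for hist, _ in tiny_histories(8_500, 20):
            tg = hist.tanglegram
            base = solve(tg, hist.timing)
            tg.switch_distance_bound = 1
            bounded = solve(tg, hist.timing)
            tg.switch_distance_bound = None
            if not bounded.feasible:
                continue
            assert bounded.total_cost >= base.total_cost - 1e-9
            for rec in bounded.switches:
                assert switch_distance(tg.host, rec.takeoff_edge, rec.landing_edge) == 1

    def test_uniform_region_matrix_equals_scalar_cost(self):
        for hist, _ in tiny_histories(8_600, 10):
            tg = hist.tanglegram
            base = solve(tg, hist.timing)
            tg.regions = RegionSpec(
                {v: "only" for v in tg.host.vertices},
                {("only", "only"): tg.costs.switch_cost},
            )
            assert solve(tg, hist.timing).total_cost == pytest.approx(base.total_cost)
            tg.regions = None

    def test_prohibitive_region_cost_matches_no_switch_optimum(self):
        for hist, _ in tiny_histories(8_700, 10):
            tg = hist.tanglegram
            tg.regions = RegionSpec(
                {v: "only" for v in tg.host.vertices}, {("only", "only"): math.inf}
            )
            banned = solve(tg, hist.timing)
            tg.regions = None
            no_switch = dataclasses.replace(tg.costs, switch_cost=math.inf)
            ref = solve(
                Tanglegram(tg.host, tg.parasite, tg.tip_mapping, costs=no_switch),
                hist.timing,
            )
            assert banned.total_cost == pytest.approx(ref.total_cost)


class TestEvaluateMapping:
    def test_missing_placement_reported(self):
        host, timing = simulate_host(3, np.random.default_rng(1))
        tg = make_congruent(host)
        sol = solve(tg, timing)
        placements = dict(sol.placements)
        gone = tg.parasite.internal[0]
        del placements[gone]
        ev = evaluate_mapping(tg, placements, timing)
        assert not ev.feasible and gone in ev.message

    def test_misplaced_tip_reported(self):
        host, timing = simulate_host(3, np.random.default_rng(1))
        tg = make_congruent(host)
        sol = solve(tg, timing)
        placements = dict(sol.placements)
        t0, t1 = tg.parasite.tips[0], tg.parasite.tips[1]
        placements[t0] = placements[t1]
        ev = evaluate_mapping(tg, placements, timing)
        assert not ev.feasible and t0 in ev.message


class TestGreedyNoSwitch:
    def test_matches_dp_with_switches_forbidden(self):
        """The MRCA construction is exactly optimal when switching is
        impossible, for the default cost scheme."""
        for hist, _ in tiny_histories(8_800, 30):
            tg = hist.tanglegram
            greedy = greedy_no_switch(tg, hist.timing)
            no_switch = dataclasses.replace(tg.costs, switch_cost=math.inf)
            ref = solve(
                Tanglegram(tg.host, tg.parasite, tg.tip_mapping, costs=no_switch),
                hist.timing,
            )
            assert greedy.feasible and ref.feasible
            assert greedy.total_cost == pytest.approx(ref.total_cost)
            assert greedy.counts.host_switches == 0

    def test_timing_invariant(self):
        for hist, _ in tiny_histories(8_900, 5):
            tg = hist.tanglegram
            costs = {
                greedy_no_switch(tg, t).total_cost for t in all_timings(tg.host)
            }
            assert len(costs) == 1

    def test_congruent_is_all_cospeciations(self):
        host, timing = simulate_host(6, np.random.default_rng(9))
        sol = greedy_no_switch(make_congruent(host), timing)
        assert sol.total_cost == 0.0
        assert sol.counts.cospeciations == host.m


def test_random_timings_never_beat_an_exact_recost():
    """For arbitrary (not true) timings the DP remains internally
    consistent: its solutions re-cost to their reported totals."""
    for hist, rng in tiny_histories(9_000, 15):
        tg = hist.tanglegram
        t = random_timing(tg.host, rng)
        sol = solve(tg, t)
        if not sol.feasible:
            continue
        ev = evaluate_mapping(tg, sol.placements, t)
        assert ev.feasible and ev.total_cost == pytest.approx(sol.total_cost)
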