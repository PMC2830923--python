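"""Ground-truth engines for testing the reconciliation solver.

These are deliberately independent of the dynamic program: the
exhaustive enumerator shares only the grid/reachability rules and the
mapping evaluator with the rest of the package, never the DP recurrence,
so agreement between the two is a meaningful check.  Everything here is
guarded to tiny instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .model import Tanglegram, Tree
from .positions import (
    HANDLE,
    Edge,
    EdgePosition,
    HostPosition,
    TimedGrid,
    VertexPosition,
)
from .reconcile import Solution, evaluate_mapping, solve
from .timing import Timing, all_timings, is_valid_timing

__all__ = [
    "EnumerationResult",
    "enumerate_reconciliations",
    "GlobalOptimum",
    "global_optimum",
    "CompatibilityResult",
    "check_switch_compatibility",
]

MAX_ENUM_TIPS = 7
MAX_ENUM_INTERNAL = 8


@dataclass
class EnumerationResult:
    feasible: bool
    min_cost: float = float("inf")
    optimal_placements: list[dict[str, HostPosition]] = field(default_factory=list)
    n_feasible: int = 0


def enumerate_reconciliations(tg: Tanglegram, timing: Timing) -> EnumerationResult:
    """Exhaustive minimum over *all* embeddings consistent with the event
    semantics, for a fixed timing.

    Candidate positions are enumerated per parasite vertex in preorder,
    pruned only by necessary conditions (a child's event cannot precede
    its parent's, and a cospeciation's children stay inside the host
    subtree); each complete assignment is costed by the shared mapping
    evaluator.  Exponential — guarded to tiny instances.
    """
    if tg.host.n_tips > MAX_ENUM_TIPS or tg.parasite.n_tips > MAX_ENUM_TIPS:
        raise ValueError(
            f"instance too large for exhaustive enumeration "
            f"(> {MAX_ENUM_TIPS} tips per tree)"
        )
    grid = TimedGrid(tg.host, timing, tg.zones)
    parasite = tg.parasite

    def candidates(p: str) -> list[HostPosition]:
        if parasite.is_tip(p):
            return [VertexPosition(tg.tip_mapping[p])]
        out: list[HostPosition] = [
            VertexPosition(v) for v in tg.host.internal if grid.zone_ok_vertex(p, v)
        ]
        for e, (lo, hi) in enumerate(grid.span):
            if not grid.zone_ok_edge(p, e):
                continue
            out.extend(EdgePosition(grid.edges[e], s) for s in range(lo, hi))
        return out

    cand = {p: candidates(p) for p in parasite.vertices}
    order = list(parasite.vertices)  # preorder: parents before children

    def compatible(parent_pos: HostPosition, pos: HostPosition) -> bool:
        # necessary conditions only; final feasibility is the evaluator's call
        if isinstance(parent_pos, VertexPosition):
            v = parent_pos.vertex
            if isinstance(pos, VertexPosition):
                return pos.vertex != v and tg.host.is_ancestor(v, pos.vertex)
            a = pos.edge[0]
            return a != HANDLE and tg.host.is_ancestor(v, a)
        s = parent_pos.slice_index
        return grid.position_time(pos) > s

    result = EnumerationResult(feasible=False)
    assignment: dict[str, HostPosition] = {}

    def rec(i: int) -> None:
        if i == len(order):
            sol = evaluate_mapping(tg, assignment, timing)
            if not sol.feasible:
                return
            result.n_feasible += 1
            if sol.total_cost < result.min_cost - 1e-12:
                result.min_cost = sol.total_cost
                result.optimal_placements = [dict(assignment)]
                result.feasible = True
            elif abs(sol.total_cost - result.min_cost) <= 1e-12:
                result.optimal_placements.append(dict(assignment))
            return
        p = order[i]
        par = parasite.parent[p]
        for pos in cand[p]:
            if par is not None and not compatible(assignment[par], pos):
                continue
            assignment[p] = pos
            rec(i + 1)
            del assignment[p]

    rec(0)
    return result


@dataclass
class GlobalOptimum:
    feasible: bool
    min_cost: float = float("inf")
    optimal_timings: list[Timing] = field(default_factory=list)
    n_timings: int = 0


def global_optimum(tg: Tanglegram) -> GlobalOptimum:
    """Minimum of the fixed-timing optimum over every timing of the host
    tree, by explicit enumeration of linear extensions.  Guarded: only
    viable at test scale."""
    if tg.host.m > MAX_ENUM_INTERNAL:
        raise ValueError(
            f"host tree has {tg.host.m} internal vertices; global enumeration "
            f"is guarded to {MAX_ENUM_INTERNAL}"
        )
    out = GlobalOptimum(feasible=False)
    for t in all_timings(tg.host):
        out.n_timings += 1
        sol = solve(tg, t)
        if not sol.feasible:
            continue
        if sol.total_cost < out.min_cost - 1e-12:
            out.min_cost = sol.total_cost
            out.optimal_timings = [t]
            out.feasible = True
        elif abs(sol.total_cost - out.min_cost) <= 1e-12:
            out.optimal_timings.append(t)
    return out


# ---------------------------------------------------------------------------
# strong / weak switch incompatibility
# ---------------------------------------------------------------------------


@dataclass
class CompatibilityResult:
    classification: str  # "compatible" | "weakly_incompatible" | "strongly_incompatible"
    relocations: Optional[dict[str, Edge]] = None  # switch id -> relocated landing


def _constraint_digraph(
    host: Tree, pairs: Iterable[tuple[Edge, Edge]]
) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(host.internal)
    for v in host.internal:
        p = host.parent[v]
        if p is not None:
            g.add_edge(p, v)
    for (a, b), (c, d) in pairs:
        # takeoff (a,b) and landing (c,d) must overlap in time:
        # rank(a) < rank(d) and rank(c) < rank(b); constraints against
        # tips (rank m+1) always hold and are dropped.
        if a != HANDLE and not host.is_tip(d):
            g.add_edge(a, d)
        if c != HANDLE and not host.is_tip(b):
            g.add_edge(c, b)
    return g


def check_switch_compatibility(
    host: Tree,
    switches: Sequence[tuple[Edge, Edge, str]],
    max_combinations: int = 100_000,
) -> CompatibilityResult:
    """Classify a set of host switches by their implied time constraints.

    Each switch is ``(takeoff_edge, landing_edge, switch_id)``.  The set
    is *compatible* if some timing places every takeoff and landing edge
    in overlapping time windows; *weakly incompatible* if not, but moving
    one or more landing sites to an ancestor edge (earlier, at the price
    of extra losses) admits a timing (the witness relocation is
    returned); *strongly incompatible* if no relocation helps.
    """
    for takeoff, landing, _sid in switches:
        if takeoff == landing:
            raise ValueError("a switch cannot land on its own takeoff edge")

    def ancestor_edges(e: Edge) -> list[Edge]:
        out = []
        u = e[0]
        while u != HANDLE and host.parent[u] is not None:
            out.append((host.parent[u], u))
            u = host.parent[u]
        return out

    originals = [(t, l) for (t, l, _s) in switches]
    if nx.is_directed_acyclic_graph(_constraint_digraph(host, originals)):
        return CompatibilityResult("compatible")

    candidate_lists = []
    for takeoff, landing, _sid in switches:
        cands = [landing] + [f for f in ancestor_edges(landing) if f != takeoff]
        candidate_lists.append(cands)

    n_combos = 1
    for c in candidate_lists:
        n_combos *= len(c)
    if n_combos > max_combinations:
        raise ValueError(f"too many relocation combinations ({n_combos})")

    for combo in itertools.product(*candidate_lists):
        pairs = [(sw[0], landing) for sw, landing in zip(switches, combo)]
        if nx.is_directed_acyclic_graph(_constraint_digraph(host, pairs)):
            relocations = {
                sw[2]: landing
                for sw, landing in zip(switches, combo)
                if landing != sw[1]
            }
            return CompatibilityResult("weakly_incompatible", relocations)
    return CompatibilityResult("strongly_incompatible")
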