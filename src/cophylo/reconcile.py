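"""Event-cost reconciliation of a parasite tree onto a timed host tree.

Given a fixed timing of the host tree's internal vertices, the optimal
reconciliation under the four-event model (cospeciation, duplication,
host switch, loss) is found by dynamic programming over the host
position grid.  Event semantics:

* cospeciation — an internal parasite vertex sits on an internal host
  vertex; its two children descend into the two host child edges;
* duplication — an internal parasite vertex sits on an (edge, slice)
  cell; both children continue on that edge;
* host switch — as duplication, but one child lands on a *different*
  edge alive in the same slice (switches are contemporaneous with the
  divergence);
* loss — every host vertex strictly passed through on the path from a
  parasite vertex's position down to one of its children's positions.

Host switches are charged the scalar switch cost, or the region-pair
matrix entry when regions are specified, and are forbidden beyond the
switch-distance bound.  Time-zone ranges restrict which host positions a
parasite vertex may occupy.

Because takeoff and landing edges must overlap in time, a fixed timing
can never produce the timing-incompatible switch sets that plague
unconstrained event inference; optimality for the given timing is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .model import CostScheme, Tanglegram, TanglegramError, Tree
from .positions import (
    HANDLE,
    Edge,
    EdgePosition,
    HostPosition,
    TimedGrid,
    VertexPosition,
)
from .timing import Timing, default_timing, is_valid_timing

__all__ = [
    "EventCounts",
    "SwitchRecord",
    "Solution",
    "solve",
    "greedy_no_switch",
    "evaluate_mapping",
    "switch_distance",
]

INF = math.inf


@dataclass
class EventCounts:
    cospeciations: int = 0
    duplications: int = 0
    host_switches: int = 0
    losses: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "cospeciations": self.cospeciations,
            "duplications": self.duplications,
            "host_switches": self.host_switches,
            "losses": self.losses,
        }


@dataclass(frozen=True)
class SwitchRecord:
    parasite_vertex: str
    takeoff_edge: Edge
    landing_edge: Edge
    slice_index: int
    switching_child: str


@dataclass
class Solution:
    """One reconciliation: placements, event labels, counts and cost.

    ``feasible`` is False when no embedding satisfies the constraints;
    ``message`` then names the obstruction.
    """

    feasible: bool
    total_cost: float = INF
    placements: dict[str, HostPosition] = field(default_factory=dict)
    events: dict[str, str] = field(default_factory=dict)
    switches: list[SwitchRecord] = field(default_factory=list)
    counts: EventCounts = field(default_factory=EventCounts)
    timing: Optional[Timing] = None
    message: str = ""

    def to_dict(self) -> dict:
        def pos_dict(pos: HostPosition) -> dict:
            if isinstance(pos, VertexPosition):
                return {"kind": "vertex", "vertex": pos.vertex}
            return {
                "kind": "edge",
                "edge": list(pos.edge),
                "slice": pos.slice_index,
            }

        if not self.feasible:
            return {"feasible": False, "message": self.message}
        return {
            "feasible": True,
            "total_cost": self.total_cost,
            "counts": self.counts.as_dict(),
            "placements": {p: pos_dict(x) for p, x in sorted(self.placements.items())},
            "events": dict(sorted(self.events.items())),
            "switches": [
                {
                    "parasite_vertex": s.parasite_vertex,
                    "takeoff_edge": list(s.takeoff_edge),
                    "landing_edge": list(s.landing_edge),
                    "slice": s.slice_index,
                    "switching_child": s.switching_child,
                }
                for s in self.switches
            ],
            "timing": dict(sorted(self.timing.items())) if self.timing else None,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def to_text(self) -> str:
        if not self.feasible:
            return f"NO SOLUTION: {self.message}"
        c = self.counts
        lines = [
            f"total cost: {self.total_cost:g}",
            f"events: {c.cospeciations} cospeciations, {c.duplications} "
            f"duplications, {c.host_switches} host switches, {c.losses} losses",
            "placements:",
        ]
        for p in sorted(self.placements):
            ev = self.events.get(p, "tip")
            lines.append(f"  {p:<12} {str(self.placements[p]):<20} {ev}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# switch distance and per-pair switch costs
# ---------------------------------------------------------------------------


def switch_distance(host: Tree, takeoff_edge: Edge, landing_edge: Edge) -> int:
    """Number of host vertices passed going from the takeoff edge to the
    landing edge along the unique undirected path between them.

    Sibling edges (sharing their parent vertex) are at distance 1.
    Identical edges do not constitute a switch and raise ``ValueError``.
    """
    if takeoff_edge == landing_edge:
        raise ValueError("takeoff and landing edges are identical: not a switch")

    def endpoints(e: Edge) -> tuple[str, ...]:
        u, v = e
        return (v,) if u == HANDLE else (u, v)

    best = None
    for x in endpoints(takeoff_edge):
        for y in endpoints(landing_edge):
            a = host.mrca(x, y)
            n_vertices = host.depth(x) + host.depth(y) - 2 * host.depth(a) + 1
            if best is None or n_vertices < best:
                best = n_vertices
    assert best is not None
    return best


def _switch_cost_matrix(tg: Tanglegram, grid: TimedGrid) -> list[list[float]]:
    """cost[e][f] of a switch taking off from edge e and landing on f
    (inf when forbidden by the distance bound or by an infinite entry)."""
    n = len(grid.edges)
    costs = tg.costs
    extra = costs.duplication_cost if costs.switch_includes_duplication else 0.0
    out = [[INF] * n for _ in range(n)]
    for e in range(n):
        for f in range(n):
            if e == f:
                continue
            if tg.switch_distance_bound is not None:
                d = switch_distance(tg.host, grid.edges[e], grid.edges[f])
                if d > tg.switch_distance_bound:
                    continue
            if tg.regions is not None:
                r1 = tg.regions.vertex_region[grid.edge_child(e)]
                r2 = tg.regions.vertex_region[grid.edge_child(f)]
                base = tg.regions.cost(r1, r2)
            else:
                base = costs.switch_cost
            out[e][f] = base + extra
    return out


# ---------------------------------------------------------------------------
# the fixed-timing dynamic program
# ---------------------------------------------------------------------------


def solve(tg: Tanglegram, timing: Timing) -> Solution:
    """Minimum-cost reconciliation for a fixed host timing.

    Returns an optimal embedding (via backtracking) together with event
    counts and the total cost.  Ties between co-optimal embeddings are
    broken by a fixed option order (cospeciation, duplication, switch by
    landing-edge index, tip arrival, continuation, loss by child-edge
    order), so the result is reproducible.
    """
    if not is_valid_timing(tg.host, timing):
        raise TanglegramError("invalid timing for this host tree")
    grid = TimedGrid(tg.host, timing, tg.zones)
    host, parasite = tg.host, tg.parasite
    costs = tg.costs
    swc = _switch_cost_matrix(tg, grid)
    n_slices = grid.n_slices
    n_edges = len(grid.edges)

    A: dict[str, list[list[float]]] = {}
    CH: dict[str, list[list[Optional[tuple]]]] = {}

    for p in parasite.postorder():
        is_tip = parasite.is_tip(p)
        if is_tip:
            target = tg.tip_mapping[p]
            tip_zone_ok = grid.zone_ok_vertex(p, target)
        else:
            c1, c2 = parasite.children[p]
            A1, A2 = A[c1], A[c2]
            edge_ok = [grid.zone_ok_edge(p, e) for e in range(n_edges)]
        Ap = [[INF] * n_slices for _ in range(n_edges)]
        Cp: list[list[Optional[tuple]]] = [[None] * n_slices for _ in range(n_edges)]
        for s in range(grid.m, -1, -1):
            alive = grid.alive[s]
            for e in alive:
                options: list[tuple[float, tuple]] = []
                hi = grid.span[e][1]
                at_end = s + 1 == hi
                v = grid.edge_child(e)
                if at_end and not host.is_tip(v):
                    f1, f2 = grid.child_edges[v]
                    if not is_tip and grid.zone_ok_vertex(p, v):
                        base = costs.cospeciation_cost
                        options.append((base + A1[f1][s + 1] + A2[f2][s + 1], ("cosp", 0)))
                        options.append((base + A1[f2][s + 1] + A2[f1][s + 1], ("cosp", 1)))
                if not is_tip and edge_ok[e]:
                    options.append(
                        (costs.duplication_cost + A1[e][s] + A2[e][s], ("dup",))
                    )
                    for f in alive:
                        sc = swc[e][f]
                        if sc == INF:
                            continue
                        options.append((sc + A1[e][s] + A2[f][s], ("switch", f, 0)))
                        options.append((sc + A2[e][s] + A1[f][s], ("switch", f, 1)))
                if at_end:
                    if host.is_tip(v):
                        if is_tip and v == target and tip_zone_ok:
                            options.append((0.0, ("tip",)))
                    else:
                        options.append(
                            (costs.loss_cost + Ap[f1][s + 1], ("loss", f1))
                        )
                        options.append(
                            (costs.loss_cost + Ap[f2][s + 1], ("loss", f2))
                        )
                else:
                    options.append((Ap[e][s + 1], ("continue",)))
                best, bch = INF, None
                for cost, ch in options:
                    if cost < best:
                        best, bch = cost, ch
                Ap[e][s] = best
                Cp[e][s] = bch
        A[p] = Ap
        CH[p] = Cp

    root = parasite.root
    total = A[root][0][0]  # handle edge has index 0 and spans slice 0 only
    if total == INF:
        return Solution(
            feasible=False,
            timing=dict(timing),
            message=_infeasibility_hint(tg, grid),
        )

    # -- backtracking --------------------------------------------------------
    placements: dict[str, HostPosition] = {}
    events: dict[str, str] = {}
    switches: list[SwitchRecord] = []
    counts = EventCounts()
    stack = [(root, 0, 0)]
    while stack:
        p, e, s = stack.pop()
        while True:
            ch = CH[p][e][s]
            assert ch is not None, "backtracking entered an infeasible state"
            if ch[0] == "continue":
                s += 1
            elif ch[0] == "loss":
                counts.losses += 1
                e, s = ch[1], s + 1
            else:
                break
        kind = ch[0]
        if kind == "tip":
            placements[p] = VertexPosition(tg.tip_mapping[p])
            continue
        c1, c2 = parasite.children[p]
        if kind == "cosp":
            v = grid.edge_child(e)
            placements[p] = VertexPosition(v)
            events[p] = "cospeciation"
            counts.cospeciations += 1
            f1, f2 = grid.child_edges[v]
            if ch[1] == 0:
                stack += [(c1, f1, s + 1), (c2, f2, s + 1)]
            else:
                stack += [(c1, f2, s + 1), (c2, f1, s + 1)]
        elif kind == "dup":
            placements[p] = EdgePosition(grid.edges[e], s)
            events[p] = "duplication"
            counts.duplications += 1
            stack += [(c1, e, s), (c2, e, s)]
        else:  # switch
            f, which = ch[1], ch[2]
            placements[p] = EdgePosition(grid.edges[e], s)
            events[p] = "host_switch"
            counts.host_switches += 1
            stayer = (c1, c2)[which]
            mover = (c2, c1)[which]
            switches.append(
                SwitchRecord(p, grid.edges[e], grid.edges[f], s, mover)
            )
            stack += [(stayer, e, s), (mover, f, s)]

    return Solution(
        feasible=True,
        total_cost=total,
        placements=placements,
        events=events,
        switches=switches,
        counts=counts,
        timing=dict(timing),
    )


def _infeasibility_hint(tg: Tanglegram, grid: TimedGrid) -> str:
    """Name a parasite vertex with no zone-feasible position, if any."""
    for p in tg.parasite.vertices:
        if tg.parasite.is_tip(p):
            if not grid.zone_ok_vertex(p, tg.tip_mapping[p]):
                return (
                    f"parasite tip {p!r} is zone-incompatible with its host "
                    f"tip {tg.tip_mapping[p]!r}"
                )
            continue
        any_ok = any(
            grid.zone_ok_vertex(p, v) for v in tg.host.internal
        ) or any(grid.zone_ok_edge(p, e) for e in range(len(grid.edges)))
        if not any_ok:
            return f"parasite vertex {p!r} has no zone-compatible host position"
    return "no feasible embedding under the given timing and constraints"


# ---------------------------------------------------------------------------
# evaluation of user-supplied mappings
# ---------------------------------------------------------------------------

Annotation = Union[str, tuple[str, str, Edge]]


def evaluate_mapping(
    tg: Tanglegram,
    placements: dict[str, HostPosition],
    timing: Timing,
    annotations: Optional[dict[str, Annotation]] = None,
) -> Solution:
    """Cost a proposed embedding, or report why it is infeasible.

    ``placements`` must cover every parasite vertex.  Without
    annotations, each edge placement is given the cheapest feasible
    interpretation (duplication, or a host switch over the best landing
    edge).  ``annotations`` may pin the event of a vertex: either the
    string ``"duplication"`` / ``"cospeciation"`` or a tuple
    ``("host_switch", switching_child, landing_edge)``.  This is how a
    recorded history is re-costed exactly as it happened.
    """
    if not is_valid_timing(tg.host, timing):
        raise TanglegramError("invalid timing for this host tree")
    grid = TimedGrid(tg.host, timing, tg.zones)
    parasite = tg.parasite
    costs = tg.costs
    annotations = annotations or {}

    def infeasible(msg: str) -> Solution:
        return Solution(feasible=False, timing=dict(timing), message=msg)

    for p in parasite.vertices:
        if p not in placements:
            return infeasible(f"parasite vertex {p!r} has no placement")
        err = grid.position_exists(placements[p])
        if err is not None:
            return infeasible(f"placement of {p!r}: {err}")

    swc = _switch_cost_matrix(tg, grid)
    total = 0.0
    events: dict[str, str] = {}
    switches: list[SwitchRecord] = []
    counts = EventCounts()

    # tips must sit on their mapped host tips
    for p in parasite.tips:
        pos = placements[p]
        want = tg.tip_mapping[p]
        if not (isinstance(pos, VertexPosition) and pos.vertex == want):
            return infeasible(
                f"parasite tip {p!r} is placed off its associated host tip {want!r}"
            )
        if not grid.zone_ok_vertex(p, want):
            return infeasible(f"parasite tip {p!r} violates its time-zone range")

    # the root lineage descends from above the host root
    r = grid.descend_losses(0, 0, placements[parasite.root])
    if r is None:  # pragma: no cover - every position is below the handle
        return infeasible("parasite root placement unreachable from the host root")
    counts.losses += r
    total += r * costs.loss_cost

    for p in parasite.internal:
        pos = placements[p]
        c1, c2 = parasite.children[p]
        q1, q2 = placements[c1], placements[c2]
        ann = annotations.get(p)
        if isinstance(pos, VertexPosition):
            v = pos.vertex
            if tg.host.is_tip(v):
                return infeasible(
                    f"internal parasite vertex {p!r} is placed on host tip {v!r}"
                )
            if ann is not None and ann != "cospeciation":
                return infeasible(
                    f"{p!r} is annotated {ann!r} but placed on a host vertex"
                )
            if not grid.zone_ok_vertex(p, v):
                return infeasible(f"{p!r} violates its time-zone range at {v!r}")
            f1, f2 = grid.child_edges[v]
            s = grid.rank[v]
            best = None
            for ea, eb in ((f1, f2), (f2, f1)):
                ra = grid.descend_losses(ea, s, q1)
                rb = grid.descend_losses(eb, s, q2)
                if ra is not None and rb is not None:
                    tot = ra + rb
                    if best is None or tot < best:
                        best = tot
            if best is None:
                return infeasible(
                    f"children of {p!r} are not reachable from the two child "
                    f"edges of host vertex {v!r}"
                )
            events[p] = "cospeciation"
            counts.cospeciations += 1
            counts.losses += best
            total += costs.cospeciation_cost + best * costs.loss_cost
            continue

        # edge placement: duplication or host switch
        e = grid.edge_index[pos.edge]
        s = pos.slice_index
        if not grid.zone_ok_edge(p, e):
            return infeasible(f"{p!r} violates its time-zone range on edge {pos.edge!r}")
        r1 = grid.descend_losses(e, s, q1)
        r2 = grid.descend_losses(e, s, q2)
        options: list[tuple[float, tuple]] = []
        if ann is None or ann == "duplication":
            if r1 is not None and r2 is not None:
                options.append(
                    (costs.duplication_cost + (r1 + r2) * costs.loss_cost, ("dup", r1 + r2))
                )
        if ann is None or (isinstance(ann, tuple) and ann[0] == "host_switch"):
            pinned_child = ann[1] if isinstance(ann, tuple) else None
            pinned_edge = (
                grid.edge_index[ann[2]] if isinstance(ann, tuple) else None
            )
            for mover, stay_r, q_m in ((c1, r2, q1), (c2, r1, q2)):
                if pinned_child is not None and mover != pinned_child:
                    continue
                if stay_r is None:
                    continue
                for f in grid.alive[s]:
                    if f == e or swc[e][f] == INF:
                        continue
                    if pinned_edge is not None and f != pinned_edge:
                        continue
                    rl = grid.descend_losses(f, s, q_m)
                    if rl is None:
                        continue
                    options.append(
                        (
                            swc[e][f] + (stay_r + rl) * costs.loss_cost,
                            ("switch", f, mover, stay_r + rl),
                        )
                    )
        if not options:
            return infeasible(
                f"no feasible event interpretation for {p!r} at {pos}"
            )
        cost, ch = min(options, key=lambda x: x[0])
        total += cost
        if ch[0] == "dup":
            events[p] = "duplication"
            counts.duplications += 1
            counts.losses += ch[1]
        else:
            events[p] = "host_switch"
            counts.host_switches += 1
            counts.losses += ch[3]
            switches.append(
                SwitchRecord(p, pos.edge, grid.edges[ch[1]], s, ch[2])
            )

    return Solution(
        feasible=True,
        total_cost=total,
        placements=dict(placements),
        events=events,
        switches=switches,
        counts=counts,
        timing=dict(timing),
    )


# ---------------------------------------------------------------------------
# the no-switch greedy special case
# ---------------------------------------------------------------------------


def greedy_no_switch(tg: Tanglegram, timing: Optional[Timing] = None) -> Solution:
    """Optimal no-switch reconciliation via the classic MRCA mapping.

    Each internal parasite vertex maps to the most recent common ancestor
    of its tips' hosts: a cospeciation when both children map strictly
    below it, otherwise a duplication on the edge above it.  This is the
    cost-optimal no-switch embedding whenever cospeciation is the
    cheapest event and losses cost at least zero (true of the default
    scheme).  Time zones, regions and the switch-distance bound are
    ignored: with switches forbidden they only constrain placements, and
    this routine reports the unconstrained no-switch optimum.

    The result is expressed under ``timing`` (a canonical breadth-first
    timing when omitted); its cost is the same for every timing, since
    switches are the only timing-sensitive event.
    """
    import dataclasses as _dc

    plain = Tanglegram(
        host=tg.host,
        parasite=tg.parasite,
        tip_mapping=tg.tip_mapping,
        costs=_dc.replace(tg.costs, switch_cost=INF, switch_includes_duplication=False),
        zones=None,
        regions=None,
        switch_distance_bound=None,
    )
    if timing is None:
        timing = default_timing(tg.host)
    grid = TimedGrid(plain.host, timing, None)
    host, parasite = tg.host, tg.parasite

    hmap: dict[str, str] = {}
    for p in parasite.postorder():
        if parasite.is_tip(p):
            hmap[p] = tg.tip_mapping[p]
        else:
            c1, c2 = parasite.children[p]
            hmap[p] = host.mrca(hmap[c1], hmap[c2])

    placements: dict[str, HostPosition] = {}
    annotations: dict[str, Annotation] = {}
    for p in parasite.vertices:
        v = hmap[p]
        if parasite.is_tip(p):
            placements[p] = VertexPosition(v)
            continue
        c1, c2 = parasite.children[p]
        if v != hmap[c1] and v != hmap[c2]:
            placements[p] = VertexPosition(v)
            annotations[p] = "cospeciation"
        else:
            # duplication on the edge entering v, in that edge's last slice
            parent = host.parent[v]
            edge = (HANDLE, v) if parent is None else (parent, v)
            e = grid.edge_index[edge]
            placements[p] = EdgePosition(edge, grid.span[e][1] - 1)
            annotations[p] = "duplication"

    sol = evaluate_mapping(plain, placements, timing, annotations)
    assert sol.feasible, f"greedy embedding must be feasible: {sol.message}"
    return sol
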