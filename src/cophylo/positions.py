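"""The host-position grid induced by a fixed timing.

For a timing with ranks 1..m (tips at m+1), time is divided into slices
0..m, slice ``s`` lying between ranks ``s`` and ``s+1``.  A host edge
(u, v) is alive exactly in slices [rank(u), rank(v)).  A virtual *handle*
edge above the root (alive in slice 0 only) lets parasite events predate
the host root.

A parasite vertex is placed either on a host vertex (cospeciation, or a
tip's terminal association) or on an (edge, slice) cell (duplication or
host switch).  The reachability rules here — how a lineage may descend
from one position to another, and how many host vertices it passes
(losses) on the way — are the single source of constraint logic shared
by the mapping evaluator and the brute-force oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .model import TimeZoneSpec, Tree
from .timing import Timing

__all__ = ["HANDLE", "Edge", "VertexPosition", "EdgePosition", "HostPosition", "TimedGrid"]

HANDLE = "$handle"  # virtual parent label of the handle edge above the root

Edge = tuple[str, str]


@dataclass(frozen=True)
class VertexPosition:
    vertex: str

    def __str__(self) -> str:
        return f"@{self.vertex}"


@dataclass(frozen=True)
class EdgePosition:
    edge: Edge
    slice_index: int

    def __str__(self) -> str:
        u, v = self.edge
        return f"({u},{v})#{self.slice_index}"


HostPosition = Union[VertexPosition, EdgePosition]


class TimedGrid:
    """Placement grid for one host tree under one fixed timing."""

    def __init__(self, host: Tree, timing: Timing, zones: Optional[TimeZoneSpec] = None):
        self.host = host
        self.zones = zones
        self.m = host.m
        self.rank: dict[str, int] = dict(timing)
        for tip in host.tips:
            self.rank[tip] = self.m + 1
        self.rank[HANDLE] = 0
        self.edges: list[Edge] = [(HANDLE, host.root)] + host.edges()
        self.edge_index: dict[Edge, int] = {e: i for i, e in enumerate(self.edges)}
        # half-open slice span of each edge
        self.span: list[tuple[int, int]] = [
            (self.rank[u], self.rank[v]) for (u, v) in self.edges
        ]
        self.n_slices = self.m + 1  # slices 0..m
        self.alive: list[list[int]] = [[] for _ in range(self.n_slices)]
        for i, (lo, hi) in enumerate(self.span):
            for s in range(lo, hi):
                self.alive[s].append(i)
        # child edges of each internal vertex, as edge indices
        self.child_edges: dict[str, list[int]] = {
            v: [self.edge_index[(v, c)] for c in host.children[v]]
            for v in host.internal
        }

    # -- structure helpers -------------------------------------------------

    def edge_child(self, e: int) -> str:
        return self.edges[e][1]

    def edge_alive_at(self, e: int, s: int) -> bool:
        lo, hi = self.span[e]
        return lo <= s < hi

    def _edge_depth(self, e: int) -> int:
        # depth of the edge's child vertex; handle edge child is the root
        return self.host.depth(self.edges[e][1])

    def edge_below(self, f: int, e: int) -> bool:
        """True iff edge ``f`` lies strictly below edge ``e`` (f's parent
        endpoint is a descendant-or-equal of e's child endpoint)."""
        if f == e:
            return False
        fu, _ = self.edges[f]
        ev = self.edges[e][1]
        if fu == HANDLE:
            return False
        return self.host.is_ancestor(ev, fu)

    # -- zone constraints --------------------------------------------------

    def zone_ok_vertex(self, p: str, v: str) -> bool:
        """May parasite vertex ``p`` be placed on host vertex ``v``?"""
        z = self.zones
        if z is None:
            return True
        plo, phi = z.parasite_range(p)
        hlo, hhi = z.host_range(v)
        return plo <= hhi and hlo <= phi

    def zone_ok_edge(self, p: str, e: int) -> bool:
        """May parasite vertex ``p`` be placed on (any slice of) edge ``e``?

        The edge's zone span runs from its parent's lower bound to its
        child's upper bound; the handle edge is unbounded below.
        """
        z = self.zones
        if z is None:
            return True
        u, v = self.edges[e]
        lo = -math.inf if u == HANDLE else z.host_range(u)[0]
        hi = z.host_range(v)[1]
        plo, phi = z.parasite_range(p)
        return plo <= hi and lo <= phi

    # -- reachability ------------------------------------------------------

    def position_exists(self, pos: HostPosition) -> Optional[str]:
        """None if the position exists on this grid; else a diagnostic."""
        if isinstance(pos, VertexPosition):
            if pos.vertex not in self.rank or pos.vertex == HANDLE:
                return f"unknown host vertex {pos.vertex!r}"
            return None
        if pos.edge not in self.edge_index:
            return f"unknown host edge {pos.edge!r}"
        e = self.edge_index[pos.edge]
        if not self.edge_alive_at(e, pos.slice_index):
            lo, hi = self.span[e]
            return (
                f"edge {pos.edge!r} is not alive in slice {pos.slice_index} "
                f"(alive in [{lo}, {hi}))"
            )
        return None

    def descend_losses(self, e: int, s: int, pos: HostPosition) -> Optional[int]:
        """Losses incurred by a lineage on edge ``e`` during slice ``s``
        descending (forward in time, no switches) to ``pos``; None if
        unreachable.

        Each host vertex strictly passed through costs one loss; the
        target vertex of a vertex position is not counted (the event
        there is not a loss).
        """
        ev = self.edges[e][1]
        if isinstance(pos, VertexPosition):
            v = pos.vertex
            if v == ev:
                return 0
            if not self.host.is_ancestor(ev, v):
                return None
            # passes ev, then every vertex strictly between ev and v
            return self.host.depth(v) - self.host.depth(ev)
        f = self.edge_index[pos.edge]
        if f == e:
            return 0 if pos.slice_index >= s else None
        if not self.edge_below(f, e):
            return None
        fu = self.edges[f][0]
        # passes ev .. fu inclusive
        return self.host.depth(fu) - self.host.depth(ev) + 1

    def position_time(self, pos: HostPosition) -> float:
        """Ordering key: events in slice s happen between ranks s and s+1."""
        if isinstance(pos, VertexPosition):
            return float(self.rank[pos.vertex])
        return pos.slice_index + 0.5
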