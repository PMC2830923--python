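"""Domain types for cophylogeny reconciliation problem instances.

A problem instance (a *tanglegram*) is a rooted bifurcating host tree, a
rooted bifurcating parasite tree, a mapping from parasite tips to host
tips, costs for the four reconciliation events (cospeciation, duplication,
host switch, loss), and optional constraints: time-zone ranges on vertices
of either tree, a partition of host vertices into regions with a
region-pair switch-cost matrix, and an upper bound on host-switch
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Tree",
    "CostScheme",
    "TimeZoneSpec",
    "RegionSpec",
    "Tanglegram",
    "TanglegramError",
    "validate",
]

INF = math.inf


class TanglegramError(ValueError):
    """Raised for structurally invalid problem instances."""


class Tree:
    """A rooted tree with labelled vertices.

    Vertices are identified by their (unique, non-empty) string labels;
    internal vertices carry labels too, because time zones and regions
    attach to them.  The reconciliation model requires strictly
    bifurcating trees; :class:`Tree` itself tolerates polytomies so that
    :func:`validate` can report them, but the parsers reject them.
    """

    def __init__(self, children: Mapping[str, Sequence[str]], root: str):
        self.children: dict[str, tuple[str, ...]] = {
            v: tuple(cs) for v, cs in children.items() if cs
        }
        self.root = root
        self.parent: dict[str, Optional[str]] = {root: None}
        for v, cs in self.children.items():
            for c in cs:
                if c in self.parent:
                    raise TanglegramError(f"vertex {c!r} has two parents")
                self.parent[c] = v
        for v in self.children:
            if v not in self.parent:
                raise TanglegramError(f"vertex {v!r} is disconnected from the root")
        self.vertices: tuple[str, ...] = tuple(self._preorder())
        if set(self.vertices) != set(self.parent):
            raise TanglegramError("tree is not connected")
        self.tips: tuple[str, ...] = tuple(
            v for v in self.vertices if v not in self.children
        )
        self.internal: tuple[str, ...] = tuple(
            v for v in self.vertices if v in self.children
        )
        self._depth: dict[str, int] = {root: 0}
        for v in self.vertices[1:]:
            self._depth[v] = self._depth[self.parent[v]] + 1  # type: ignore[index]

    # -- basic structure -------------------------------------------------

    def _preorder(self) -> Iterable[str]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children.get(v, ())))

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def m(self) -> int:
        """Number of internal vertices."""
        return len(self.internal)

    def is_tip(self, v: str) -> bool:
        return v not in self.children

    def depth(self, v: str) -> int:
        return self._depth[v]

    def postorder(self) -> list[str]:
        return list(reversed(self.vertices))

    def is_ancestor(self, a: str, v: str) -> bool:
        """True iff ``a`` is an ancestor of ``v`` (or equal to it)."""
        while v is not None:
            if v == a:
                return True
            v = self.parent[v]  # type: ignore[assignment]
        return False

    def mrca(self, a: str, b: str) -> str:
        seen = set()
        x: Optional[str] = a
        while x is not None:
            seen.add(x)
            x = self.parent[x]
        y: Optional[str] = b
        while y is not None:
            if y in seen:
                return y
            y = self.parent[y]
        raise TanglegramError("vertices share no ancestor")

    def edges(self) -> list[tuple[str, str]]:
        """All (parent, child) edges in preorder of the child."""
        return [(self.parent[v], v) for v in self.vertices if v != self.root]  # type: ignore[misc]

    def subtree_vertices(self, v: str) -> set[str]:
        out = set()
        stack = [v]
        while stack:
            x = stack.pop()
            out.add(x)
            stack.extend(self.children.get(x, ()))
        return out

    # -- equality / hashing ----------------------------------------------

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Tree)
            and self.root == other.root
            and {v: frozenset(cs) for v, cs in self.children.items()}
            == {v: frozenset(cs) for v, cs in other.children.items()}
        )

    def __repr__(self) -> str:
        return f"Tree(root={self.root!r}, n_tips={self.n_tips})"


@dataclass(frozen=True)
class CostScheme:
    """Costs of the four reconciliation events.

    The defaults (0, 1, 1, 2) are the standard scheme: free
    cospeciations, unit duplications and switches, and losses at twice
    the unit cost.  ``switch_cost`` may be ``inf`` to forbid switches
    entirely.  When ``switch_includes_duplication`` is set, each host
    switch is additionally charged the duplication cost (an alternative
    accounting used by some tools).
    """

    cospeciation_cost: float = 0.0
    duplication_cost: float = 1.0
    switch_cost: float = 1.0
    loss_cost: float = 2.0
    switch_includes_duplication: bool = False

    def __post_init__(self) -> None:
        for name in ("cospeciation_cost", "duplication_cost", "switch_cost", "loss_cost"):
            if getattr(self, name) < 0:
                raise TanglegramError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TimeZoneSpec:
    """Inclusive integer time-zone ranges for vertices of both trees.

    A vertex absent from a map is unconstrained.  A parasite vertex may
    be placed on a host vertex only if their zone ranges intersect, and
    on a host edge only if its range intersects the edge's zone span
    (from the parent's lower bound to the child's upper bound).
    """

    host_zones: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    parasite_zones: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def host_range(self, v: str) -> tuple[float, float]:
        return self.host_zones.get(v, (-INF, INF))

    def parasite_range(self, v: str) -> tuple[float, float]:
        return self.parasite_zones.get(v, (-INF, INF))


@dataclass(frozen=True)
class RegionSpec:
    """Host-vertex regions with a per-region-pair switch-cost matrix.

    When present, the matrix entry for (region of takeoff edge, region of
    landing edge) replaces the scalar switch cost entirely.  An edge's
    region is the region of its child vertex.
    """

    vertex_region: Mapping[str, str] = field(default_factory=dict)
    pair_costs: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def cost(self, from_region: str, to_region: str) -> float:
        return self.pair_costs[(from_region, to_region)]


@dataclass
class Tanglegram:
    """A full cophylogeny reconciliation problem instance."""

    host: Tree
    parasite: Tree
    tip_mapping: dict[str, str]
    costs: CostScheme = field(default_factory=CostScheme)
    zones: Optional[TimeZoneSpec] = None
    regions: Optional[RegionSpec] = None
    switch_distance_bound: Optional[int] = None

    def require_valid(self) -> "Tanglegram":
        problems = validate(self)
        if problems:
            raise TanglegramError("; ".join(problems))
        return self


def _check_binary(tree: Tree, which: str, out: list[str]) -> None:
    for v in tree.internal:
        k = len(tree.children[v])
        if k != 2:
            out.append(f"{which} vertex {v!r} has {k} children (must be 2)")


def validate(tg: Tanglegram) -> list[str]:
    """Return a list of diagnostics; empty iff the instance is well formed.

    Each diagnostic names the violated invariant and its location.
    """
    out: list[str] = []
    _check_binary(tg.host, "host", out)
    _check_binary(tg.parasite, "parasite", out)
    for which, tree in (("host", tg.host), ("parasite", tg.parasite)):
        for v in tree.vertices:
            if not v:
                out.append(f"{which} tree contains an empty vertex label")

    host_tips = set(tg.host.tips)
    para_tips = set(tg.parasite.tips)
    for p in sorted(para_tips):
        if p not in tg.tip_mapping:
            out.append(f"parasite tip {p!r} has no host association")
    for p, h in sorted(tg.tip_mapping.items()):
        if p not in para_tips:
            out.append(f"association names unknown parasite tip {p!r}")
        if h not in host_tips:
            out.append(f"association of {p!r} names unknown host tip {h!r}")

    if tg.zones is not None:
        for which, tree, zmap in (
            ("host", tg.host, tg.zones.host_zones),
            ("parasite", tg.parasite, tg.zones.parasite_zones),
        ):
            for v, (lo, hi) in sorted(zmap.items()):
                if v not in tree.parent:
                    out.append(f"zone names unknown {which} vertex {v!r}")
                    continue
                if lo > hi:
                    out.append(f"{which} vertex {v!r} has zone range {lo}>{hi}")
        # A host vertex's range may not end before its parent's begins:
        # zones must not contradict ancestry.
        for v, (lo, hi) in sorted(tg.zones.host_zones.items()):
            parent = tg.host.parent.get(v)
            if parent is None or parent not in tg.zones.host_zones:
                continue
            plo, _ = tg.zones.host_zones[parent]
            if hi < plo:
                out.append(
                    f"host vertex {v!r} zone ends ({hi}) before parent "
                    f"{parent!r} zone begins ({plo})"
                )

    if tg.regions is not None:
        regions = set(tg.regions.vertex_region.values())
        for v in tg.host.vertices:
            if v not in tg.regions.vertex_region:
                out.append(f"host vertex {v!r} has no region")
        for v in sorted(tg.regions.vertex_region):
            if v not in tg.host.parent:
                out.append(f"region assignment names unknown host vertex {v!r}")
        for r1 in sorted(regions):
            for r2 in sorted(regions):
                if (r1, r2) not in tg.regions.pair_costs:
                    out.append(f"region cost matrix misses pair ({r1}, {r2})")
                elif tg.regions.pair_costs[(r1, r2)] < 0:
                    out.append(f"region cost for ({r1}, {r2}) is negative")

    if tg.switch_distance_bound is not None and tg.switch_distance_bound < 1:
        out.append("switch distance bound must be a positive integer")
    return out
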