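"""Synthetic coevolutionary histories and canned worked-example fixtures.

The forward simulator grows a Yule host tree (whose birth order is the
true timing), then propagates parasite lineages down the timed host
tree: at each host divergence a resident lineage either cospeciates or
follows a single child edge (a loss); within each time slice a lineage
may duplicate in place or switch to a uniformly chosen contemporaneous
edge.  Every surviving lineage reaching a host tip becomes a parasite
tip associated with that host.  The realized events form a ground-truth
embedding whose cost upper-bounds the optimum, which is how solver
optimality is exercised at scale.

Because all surviving lineages are kept, generated corpora naturally
contain both host tips with several parasites and host tips with none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import CostScheme, Tanglegram, Tree
from .positions import EdgePosition, HostPosition, TimedGrid, VertexPosition
from .reconcile import Annotation, EventCounts
from .timing import Timing

__all__ = [
    "SimulatedHistory",
    "simulate_host",
    "simulate_coevolution",
    "simulate_tanglegram",
    "fixture",
    "CrossoverExample",
    "TimingExample",
]


@dataclass
class SimulatedHistory:
    """A tanglegram together with the true history that generated it."""

    tanglegram: Tanglegram
    timing: Timing
    placements: dict[str, HostPosition]
    annotations: dict[str, Annotation]
    counts: EventCounts
    total_cost: float


def simulate_host(n_tips: int, rng: np.random.Generator) -> tuple[Tree, Timing]:
    """Yule (pure-birth) host topology; the birth order is the timing.

    Internal vertices are labelled H1..Hm in birth (= rank) order and
    tips h1..hn in preorder.
    """
    if n_tips < 2:
        raise ValueError("a host tree needs at least 2 tips")
    next_id = 0

    def nid() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    root = nid()
    active = [root]
    kids: dict[int, list[int]] = {}
    birth_order: list[int] = []
    while len(active) < n_tips:
        i = int(rng.integers(len(active)))
        v = active.pop(i)
        c1, c2 = nid(), nid()
        kids[v] = [c1, c2]
        birth_order.append(v)
        active += [c1, c2]

    label = {v: f"H{r}" for r, v in enumerate(birth_order, start=1)}
    tip_no = 0
    stack = [root]
    while stack:
        v = stack.pop()
        if v in kids:
            stack.extend(reversed(kids[v]))
        else:
            tip_no += 1
            label[v] = f"h{tip_no}"
    children = {label[v]: tuple(label[c] for c in cs) for v, cs in kids.items()}
    tree = Tree(children, root=label[root])
    timing = {f"H{r}": r for r in range(1, len(birth_order) + 1)}
    return tree, timing


def simulate_coevolution(
    host: Tree,
    timing: Timing,
    rng: np.random.Generator,
    p_cosp: float = 0.85,
    p_dup: float = 0.05,
    p_switch: float = 0.05,
    p_loss: float = 0.15,
    costs: Optional[CostScheme] = None,
    max_retries: int = 50,
) -> SimulatedHistory:
    """Propagate parasite lineages down the timed host tree.

    ``p_cosp`` and ``p_loss`` are relative weights for the outcome at
    each host divergence a lineage reaches (cospeciate vs. follow one
    child edge); ``p_dup`` and ``p_switch`` are per-slice probabilities
    of a lineage duplicating in place or switching to a contemporaneous
    edge (at most one such event per lineage per slice; the offspring
    act from the next slice on).  Histories with fewer than two parasite
    tips are redrawn, up to ``max_retries``.
    """
    for p in (p_cosp, p_dup, p_switch, p_loss):
        if not 0.0 <= p <= 1.0:
            raise ValueError("event probabilities must lie in [0, 1]")
    if p_dup + p_switch > 1.0:
        raise ValueError("p_dup + p_switch must not exceed 1")
    if p_cosp + p_loss <= 0.0:
        raise ValueError("p_cosp + p_loss must be positive")
    w_cosp = p_cosp / (p_cosp + p_loss)
    costs = costs or CostScheme()
    grid = TimedGrid(host, timing)
    rank_to_vertex = {r: v for v, r in timing.items()}

    for _attempt in range(max_retries):
        next_pid = 0

        def pid() -> int:
            nonlocal next_pid
            next_pid += 1
            return next_pid - 1

        placements: dict[int, HostPosition] = {}
        events: dict[int, str] = {}
        landings: dict[int, tuple[int, tuple]] = {}  # switcher -> (mover pid, edge)
        kids: dict[int, tuple[int, int]] = {}
        losses = 0
        root_pid = pid()
        lineages: list[tuple[int, int]] = [(root_pid, 0)]  # (pid, edge index)

        for s in range(grid.n_slices):
            nxt: list[tuple[int, int]] = []
            for lp, e in lineages:
                u = rng.random()
                if u < p_dup:
                    c1, c2 = pid(), pid()
                    kids[lp] = (c1, c2)
                    placements[lp] = EdgePosition(grid.edges[e], s)
                    events[lp] = "duplication"
                    nxt += [(c1, e), (c2, e)]
                elif u < p_dup + p_switch:
                    others = [f for f in grid.alive[s] if f != e]
                    if others:
                        f = others[int(rng.integers(len(others)))]
                        c1, c2 = pid(), pid()
                        kids[lp] = (c1, c2)
                        placements[lp] = EdgePosition(grid.edges[e], s)
                        events[lp] = "host_switch"
                        landings[lp] = (c2, grid.edges[f])
                        nxt += [(c1, e), (c2, f)]
                    else:
                        nxt.append((lp, e))
                else:
                    nxt.append((lp, e))
            if s == grid.m:
                lineages = nxt
                break
            v = rank_to_vertex[s + 1]
            f1, f2 = grid.child_edges[v]
            lineages = []
            for lp, e in nxt:
                if grid.edge_child(e) == v and grid.span[e][1] == s + 1:
                    if rng.random() < w_cosp:
                        c1, c2 = pid(), pid()
                        kids[lp] = (c1, c2)
                        placements[lp] = VertexPosition(v)
                        events[lp] = "cospeciation"
                        lineages += [(c1, f1), (c2, f2)]
                    else:
                        losses += 1
                        f = (f1, f2)[int(rng.integers(2))]
                        lineages.append((lp, f))
                else:
                    lineages.append((lp, e))

        if len(lineages) < 2:
            continue

        # label the parasite tree: internals P1.. and tips p1.. in preorder
        tip_host = {lp: grid.edge_child(e) for lp, e in lineages}
        label: dict[int, str] = {}
        n_int = n_tip = 0
        stack = [root_pid]
        while stack:
            x = stack.pop()
            if x in kids:
                n_int += 1
                label[x] = f"P{n_int}"
                stack.extend(reversed(kids[x]))
            else:
                n_tip += 1
                label[x] = f"p{n_tip}"
        children = {label[x]: tuple(label[c] for c in cs) for x, cs in kids.items()}
        parasite = Tree(children, root=label[root_pid])
        mapping = {label[lp]: h for lp, h in tip_host.items()}

        tg = Tanglegram(host=host, parasite=parasite, tip_mapping=mapping, costs=costs)
        out_placements = {label[x]: pos for x, pos in placements.items()}
        out_placements.update(
            {label[lp]: VertexPosition(h) for lp, h in tip_host.items()}
        )
        annotations: dict[str, Annotation] = {}
        counts = EventCounts(losses=losses)
        for x, ev in events.items():
            if ev == "cospeciation":
                counts.cospeciations += 1
                annotations[label[x]] = "cospeciation"
            elif ev == "duplication":
                counts.duplications += 1
                annotations[label[x]] = "duplication"
            else:
                counts.host_switches += 1
                mover, edge = landings[x]
                annotations[label[x]] = ("host_switch", label[mover], edge)
        total = (
            counts.cospeciations * costs.cospeciation_cost
            + counts.duplications * costs.duplication_cost
            + counts.host_switches
            * (
                costs.switch_cost
                + (costs.duplication_cost if costs.switch_includes_duplication else 0)
            )
            + counts.losses * costs.loss_cost
        )
        return SimulatedHistory(
            tanglegram=tg,
            timing=dict(timing),
            placements=out_placements,
            annotations=annotations,
            counts=counts,
            total_cost=total,
        )
    raise RuntimeError(
        f"simulation produced fewer than 2 parasite tips in {max_retries} attempts"
    )


def simulate_tanglegram(
    n_host_tips: int, rng: np.random.Generator, **kwargs
) -> SimulatedHistory:
    """Convenience: a Yule host plus a coevolution history on it."""
    host, timing = simulate_host(n_host_tips, rng)
    return simulate_coevolution(host, timing, rng, **kwargs)


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossoverExample:
    """The crossover worked example: a 9-internal-vertex host tree, two
    parent timings, and the chosen subtree (rooted at f, child of c).

    The non-subtree vertices under tau1 list as a:1, b:2, c:3, d:5, g:7,
    e:8 and the subtree vertices under tau2 as f:3, h:6, i:8.
    """

    host: Tree
    tau1: Timing
    tau2: Timing
    subtree_root: str


@dataclass(frozen=True)
class TimingExample:
    """A 5-internal-vertex host tree with three reference timings; the
    second and third are neighbors (they differ by swapping b and c at
    consecutive ranks)."""

    host: Tree
    timings: tuple[Timing, ...]


def fixture(name: str):
    """Named worked-example instances: ``crossover_example`` or
    ``timing_example``."""
    if name == "crossover_example":
        host = Tree(
            {
                "a": ("b", "c"),
                "b": ("d", "t1"),
                "c": ("f", "t2"),
                "d": ("g", "e"),
                "f": ("h", "t3"),
                "h": ("i", "t4"),
                "g": ("t5", "t6"),
                "e": ("t7", "t8"),
                "i": ("t9", "t10"),
            },
            root="a",
        )
        tau1 = {"a": 1, "b": 2, "c": 3, "f": 4, "d": 5, "h": 6, "g": 7, "e": 8, "i": 9}
        tau2 = {"a": 1, "c": 2, "f": 3, "b": 4, "d": 5, "h": 6, "g": 7, "i": 8, "e": 9}
        return CrossoverExample(host=host, tau1=tau1, tau2=tau2, subtree_root="f")
    if name == "timing_example":
        host = Tree(
            {
                "a": ("b", "c"),
                "b": ("d", "u1"),
                "c": ("e", "u2"),
                "d": ("u3", "u4"),
                "e": ("u5", "u6"),
            },
            root="a",
        )
        timings = (
            {"a": 1, "b": 2, "d": 3, "c": 4, "e": 5},
            {"a": 1, "c": 2, "b": 3, "d": 4, "e": 5},
            {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5},
        )
        return TimingExample(host=host, timings=timings)
    raise KeyError(f"unknown fixture {name!r}")
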