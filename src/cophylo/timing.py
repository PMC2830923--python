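"""Timings of a host tree: linear extensions of its ancestry order.

A *timing* assigns each internal host vertex a distinct relative time
(rank 1..m) such that every parent precedes its children; all tips
implicitly share rank m+1 ("current time").  The reconciliation DP is
exact for a fixed timing, and the genetic search explores the space of
timings, whose moves are built from the operations here.

Two timings are *neighbors* when they differ only by swapping two
vertices at consecutive ranks, neither of which is the other's parent.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .model import Tree

__all__ = [
    "Timing",
    "is_valid_timing",
    "neighbors",
    "random_timing",
    "swap_mutation",
    "default_timing",
    "all_timings",
]

Timing = dict[str, int]


def is_valid_timing(host: Tree, t: Timing) -> bool:
    """True iff ``t`` is a bijection from internal vertices onto 1..m with
    every internal parent ranked before its internal children."""
    internal = host.internal
    for v in t:
        if v not in host.parent:
            raise KeyError(f"timing names unknown vertex {v!r}")
    if set(t) != set(internal):
        return False
    ranks = sorted(t.values())
    if ranks != list(range(1, len(internal) + 1)):
        return False
    for v in internal:
        p = host.parent[v]
        if p is not None and t[p] >= t[v]:
            return False
    return True


def _swappable_pairs(host: Tree, t: Timing) -> list[tuple[str, str]]:
    by_rank = sorted(t, key=t.__getitem__)
    pairs = []
    for x, y in zip(by_rank, by_rank[1:]):
        if host.parent[y] != x and host.parent[x] != y:
            pairs.append((x, y))
    return pairs


def neighbors(host: Tree, t: Timing) -> list[Timing]:
    """All timings reachable by one adjacent, non-parent/child rank swap."""
    out = []
    for x, y in _swappable_pairs(host, t):
        t2 = dict(t)
        t2[x], t2[y] = t2[y], t2[x]
        out.append(t2)
    return out


def random_timing(host: Tree, rng: np.random.Generator) -> Timing:
    """Draw a random timing by repeatedly choosing uniformly among the
    vertices whose ancestors are all already placed.

    This is not uniform over linear extensions; it is a cheap source of
    diverse valid timings, which is all the genetic search needs.
    """
    t: Timing = {}
    placed: set[str] = set()
    available = [host.root] if not host.is_tip(host.root) else []
    rank = 1
    while available:
        i = int(rng.integers(len(available)))
        v = available.pop(i)
        t[v] = rank
        rank += 1
        placed.add(v)
        for c in host.children[v]:
            if not host.is_tip(c):
                available.append(c)
        available.sort()  # deterministic candidate order for a given rng
    return t


def swap_mutation(host: Tree, t: Timing, rng: np.random.Generator) -> Timing:
    """Return a uniformly chosen neighbor of ``t``; ``t`` itself if none."""
    pairs = _swappable_pairs(host, t)
    if not pairs:
        return dict(t)
    x, y = pairs[int(rng.integers(len(pairs)))]
    t2 = dict(t)
    t2[x], t2[y] = t2[y], t2[x]
    return t2


def default_timing(host: Tree) -> Timing:
    """A canonical timing: breadth-first order, ties by label."""
    t: Timing = {}
    rank = 1
    frontier = [host.root] if not host.is_tip(host.root) else []
    while frontier:
        frontier.sort(key=lambda v: (host.depth(v), v))
        v = frontier.pop(0)
        t[v] = rank
        rank += 1
        frontier.extend(c for c in host.children[v] if not host.is_tip(c))
    return t


def all_timings(host: Tree, limit: int = 500_000) -> Iterator[Timing]:
    """Enumerate every timing (linear extension) of the host tree.

    Exponential in general; guarded by ``limit`` on the number yielded.
    """
    count = 0

    def rec(t: Timing, available: list[str]) -> Iterator[Timing]:
        nonlocal count
        if not available:
            count += 1
            if count > limit:
                raise RuntimeError(f"more than {limit} timings; tree too large")
            yield dict(t)
            return
        for i, v in enumerate(list(available)):
            rest = available[:i] + available[i + 1 :]
            nxt = rest + [c for c in host.children[v] if not host.is_tip(c)]
            t[v] = len(t) + 1
            yield from rec(t, nxt)
            del t[v]

    start = [host.root] if not host.is_tip(host.root) else []
    yield from rec({}, start)
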