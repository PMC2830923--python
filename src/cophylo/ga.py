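"""Genetic search over host-tree timings.

Each individual is a timing; its fitness is the exact DP reconciliation
cost for that timing.  Parents are drawn with probability weighted
exponentially in fitness, recombined with a subtree-merge crossover, and
a fraction of offspring receive one adjacent-swap mutation.  The
population is fully replaced each generation; a best-so-far archive
outside the population retains the best cost and every distinct timing
observed to achieve it.

The crossover picks a random host subtree T, lists the non-T internal
vertices in the order of the first parent and the T vertices in the
order of the second, and fills ranks 1..m by repeatedly taking, among
the eligible heads of the two lists (a vertex is eligible once its
parent is placed), the one whose original time is closest to the rank
being filled, breaking exact ties at random.  The complement of a
subtree is closed under parents, so the non-T head is always eligible
and the fill never deadlocks.
"""

from __future__ import annotations

import json
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .model import Tanglegram, TanglegramError, Tree
from .reconcile import Solution, solve
from .timing import Timing, is_valid_timing, random_timing, swap_mutation

__all__ = ["GAConfig", "GAResult", "crossover", "select_pair", "run_ga"]

TieBreak = Union[None, str, Callable[[str, str, int], str]]


@dataclass
class GAConfig:
    """Search parameters.

    The defaults G=45 generations of S=23 timings follow the guidance
    G ≈ 2S with S·G ≈ 1000 DP invocations, which suits small-to-medium
    trees.  ``selection_beta`` is the exponent weighting selection toward
    low cost: a member costing one unit more is e^beta times less likely
    to be drawn (beta = ln 2 halves the odds per unit).  ``thread_count``
    may parallelize scoring but never changes results.
    """

    population_size: int = 23
    generations: int = 45
    mutation_rate: float = 0.05
    selection_beta: float = math.log(2.0)
    seed: Optional[int] = None
    thread_count: int = 1

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be at least 1")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass
class GAResult:
    feasible: bool
    best_cost: float = math.inf
    best_timings: list[Timing] = field(default_factory=list)
    best_solutions: list[Solution] = field(default_factory=list)
    trace: list[dict[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "best_cost": self.best_cost if self.feasible else None,
            "n_distinct_optimal_timings": len(self.best_timings),
            "best_timings": [dict(sorted(t.items())) for t in self.best_timings],
            "best_solutions": [s.to_dict() for s in self.best_solutions],
            "trace": self.trace,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def crossover(
    host: Tree,
    tau1: Timing,
    tau2: Timing,
    rng: np.random.Generator,
    subtree_root: Optional[str] = None,
    tie_break: TieBreak = None,
) -> Timing:
    """Subtree-merge crossover of two timings.

    ``subtree_root`` pins the randomly chosen subtree (an internal host
    vertex; T is that vertex plus all its internal descendants).
    ``tie_break`` resolves equidistant candidates: None draws uniformly
    from ``rng``; ``"subtree"``/``"non_subtree"`` always prefer one list
    (used to replay worked examples); a callable receives
    (non_subtree_vertex, subtree_vertex, rank) and returns "A" or "B".
    """
    internal = set(host.internal)
    if set(tau1) != internal or set(tau2) != internal:
        raise TanglegramError("timings do not cover this host tree's internal vertices")
    if subtree_root is None:
        subtree_root = host.internal[int(rng.integers(len(host.internal)))]
    elif subtree_root not in internal:
        raise TanglegramError(f"subtree root {subtree_root!r} is not an internal vertex")

    in_t = {v for v in host.subtree_vertices(subtree_root) if v in internal}
    a_list = sorted((v for v in internal if v not in in_t), key=tau1.__getitem__)
    b_list = sorted(in_t, key=tau2.__getitem__)

    new: Timing = {}
    ia = ib = 0
    m = len(internal)
    for rank in range(1, m + 1):
        a_head = a_list[ia] if ia < len(a_list) else None
        b_head = b_list[ib] if ib < len(b_list) else None
        if a_head is not None:
            pa = host.parent[a_head]
            assert pa is None or pa in new, "non-subtree head must be eligible"
        if b_head is not None:
            pb = host.parent[b_head]
            if not (pb is None or pb in new):
                b_head = None
        if a_head is not None and b_head is not None:
            da = abs(tau1[a_head] - rank)
            db = abs(tau2[b_head] - rank)
            if da < db:
                pick = "A"
            elif db < da:
                pick = "B"
            elif tie_break is None:
                pick = "A" if rng.random() < 0.5 else "B"
            elif tie_break == "subtree":
                pick = "B"
            elif tie_break == "non_subtree":
                pick = "A"
            else:
                pick = tie_break(a_head, b_head, rank)
        elif a_head is not None:
            pick = "A"
        elif b_head is not None:
            pick = "B"
        else:  # pragma: no cover - the fill cannot deadlock
            raise AssertionError("crossover fill has no eligible candidate")
        if pick == "A":
            new[a_head] = rank
            ia += 1
        else:
            new[b_head] = rank
            ib += 1
    assert is_valid_timing(host, new)
    return new


def select_pair(
    population: Sequence[tuple[Timing, float]],
    selection_beta: float,
    rng: np.random.Generator,
) -> tuple[Timing, Timing]:
    """Draw two members independently (repetition allowed) with
    probability proportional to exp(-beta * (cost - best cost))."""
    if not population:
        raise ValueError("population is empty")
    costs = np.array([c for _, c in population], dtype=float)
    finite = costs[np.isfinite(costs)]
    if finite.size == 0:
        weights = np.ones(len(costs))
    else:
        delta = costs - finite.min()
        weights = np.where(np.isfinite(delta), np.exp(-selection_beta * delta), 0.0)
        if weights.sum() <= 0:
            weights = np.ones(len(costs))
    probs = weights / weights.sum()
    i, j = rng.choice(len(population), size=2, replace=True, p=probs)
    return population[int(i)][0], population[int(j)][0]


def _timing_key(t: Timing) -> tuple:
    return tuple(sorted(t.items()))


def run_ga(tg: Tanglegram, cfg: GAConfig) -> GAResult:
    """Run the genetic search and report the best solutions found.

    Deterministic for a fixed seed, independent of ``thread_count``
    (scoring the population is pure and order-preserving).
    """
    host = tg.host
    rng = np.random.default_rng(cfg.seed)
    s_size = cfg.population_size

    def score_all(timings: list[Timing]) -> list[Solution]:
        if cfg.thread_count > 1:
            with ThreadPoolExecutor(max_workers=cfg.thread_count) as pool:
                return list(pool.map(lambda t: solve(tg, t), timings))
        return [solve(tg, t) for t in timings]

    archive_cost = math.inf
    archive: dict[tuple, tuple[Timing, Solution]] = {}
    trace: list[dict[str, float]] = []

    def absorb(timings: list[Timing], sols: list[Solution]) -> None:
        nonlocal archive_cost
        for t, sol in zip(timings, sols):
            if not sol.feasible:
                continue
            if sol.total_cost < archive_cost - 1e-12:
                archive_cost = sol.total_cost
                archive.clear()
            if abs(sol.total_cost - archive_cost) <= 1e-12:
                archive.setdefault(_timing_key(t), (t, sol))

    population = [random_timing(host, rng) for _ in range(s_size)]
    solutions = score_all(population)
    absorb(population, solutions)

    def record_trace(gen: int, sols: list[Solution]) -> None:
        costs = [s.total_cost if s.feasible else math.inf for s in sols]
        finite = [c for c in costs if math.isfinite(c)]
        trace.append(
            {
                "generation": gen,
                "best": min(costs) if costs else math.inf,
                "mean": sum(finite) / len(finite) if finite else math.inf,
                "archive_best": archive_cost,
            }
        )

    record_trace(0, solutions)

    for gen in range(1, cfg.generations + 1):
        scored = [
            (t, s.total_cost if s.feasible else math.inf)
            for t, s in zip(population, solutions)
        ]
        offspring = []
        for _ in range(s_size):
            if s_size == 1:
                t1 = t2 = population[0]
            else:
                t1, t2 = select_pair(scored, cfg.selection_beta, rng)
            offspring.append(crossover(host, t1, t2, rng))
        n_mut = int(round(cfg.mutation_rate * s_size))
        if n_mut > 0:
            idx = rng.choice(s_size, size=min(n_mut, s_size), replace=False)
            for i in sorted(int(k) for k in idx):
                offspring[i] = swap_mutation(host, offspring[i], rng)
        population = offspring
        solutions = score_all(population)
        absorb(population, solutions)
        record_trace(gen, solutions)

    if not archive:
        return GAResult(feasible=False, trace=trace)
    items = sorted(archive.items())
    return GAResult(
        feasible=True,
        best_cost=archive_cost,
        best_timings=[t for _, (t, _s) in items],
        best_solutions=[s for _, (_t, s) in items],
        trace=trace,
    )
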