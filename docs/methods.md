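# Methods

This note defines the model implemented by `cophylo`, the algorithms,
their parameters and defaults, the numerical conventions, and the known
limitations.

## Problem instances

A problem instance (*tanglegram*) is:

* a rooted, strictly bifurcating **host tree** `H` with labelled
  internal vertices and tips;
* a rooted, strictly bifurcating **parasite tree** `P`;
* a total **tip mapping** φ from parasite tips to host tips (many
  parasite tips may share a host tip; host tips may be unmapped);
* a **cost scheme** `(cospeciation, duplication, switch, loss)`,
  default `(0, 1, 1, 2)`; any cost may be `inf` to forbid the event;
* optional **time zones**: inclusive integer rank ranges on vertices of
  either tree;
* optional **regions**: a total map from host vertices to region labels
  plus a complete region-pair cost matrix that *replaces* the scalar
  switch cost (an edge's region is its child vertex's region);
* an optional **switch distance bound**: the maximum number of host
  vertices on the undirected path between takeoff and landing edge
  (sibling edges are at distance 1).

`validate()` returns a list of human-readable diagnostics (polytomies,
missing associations, inconsistent zones, incomplete region matrices,
…); parsers reject structurally invalid files with named locations.

## Timings and the timed grid

A **timing** τ assigns the `m` internal host vertices distinct ranks
`1..m` with every parent before its children (a linear extension); all
tips implicitly occupy rank `m+1`.  Two timings are **neighbors** when
they differ by swapping two vertices at consecutive ranks that are not
parent and child.

A timing induces a **timed grid**: time slice `s` (for `s = 0..m`) lies
between ranks `s` and `s+1`; the host edge entering vertex `v` from
parent `u` is *alive* in slices `rank(u) .. rank(v)−1` (half-open). A
virtual *handle* edge above the root is alive in slice 0 only; the
parasite root lineage starts there, so duplications and switches above
the host root are representable.

## Event semantics

* **cospeciation** — an internal parasite vertex sits *on* an internal
  host vertex; its children descend into the two host child edges;
* **duplication** — an internal parasite vertex sits on an (edge,
  slice) cell; both children continue on that edge in the same slice;
* **host switch** — as duplication, but exactly one child lands on a
  *different* edge alive in the same slice (switches are contemporaneous
  with the divergence, never "into the past");
* **loss** — each host vertex strictly passed through on the descent
  from a parasite vertex's position to a child's position.

By default a switch is charged the switch cost only.  The
`switch_includes_duplication` flag (CLI:
`--switch-includes-duplication`) additionally charges the duplication
cost per switch — an alternative accounting used by some tools.

## The fixed-timing dynamic program

For each parasite vertex `p` (postorder), host edge `e` and slice `s`
in which `e` is alive, `A[p][e][s]` is the minimum cost of embedding
the subtree of `p` given that `p`'s lineage is on `e` at slice `s`.
Transitions: cospeciation (only at the end of `e`, on an internal host
vertex, two child-assignment orders), duplication, host switch (over
all contemporaneous landing edges with finite switch cost, either child
moving), tip arrival (zero cost, only on the mapped host tip), slice
continuation, and loss (at the end of `e`, into either child edge, one
loss each).  Time zones are enforced as hard feasibility masks on
vertex and edge positions.  The answer is `A[root][handle][0]`.

Backtracking reconstructs one optimal embedding.  Ties are broken by a
fixed option order — cospeciation (child order 0 then 1), duplication,
switch by landing-edge index (index follows host preorder), tip,
continuation, loss by child-edge order — so results are reproducible.

For a fixed timing every reported switch is between edges alive in the
same slice, hence any solution's switch set is realizable under that
timing; the timing-inconsistency failure mode of untimed event methods
cannot occur.  Cost per timing is polynomial (roughly
`O(|P| · m² · (switch candidates))`; in practice `O(n⁴)`-ish), measured
at single-digit milliseconds for trees with ≤ 8 tips.

`evaluate_mapping()` independently re-costs an arbitrary placement map
(optionally with pinned event annotations, which is how simulated true
histories are re-costed exactly); `greedy_no_switch()` implements the
classic most-recent-common-ancestor construction for the no-switch
special case.

## The genetic search over timings

Individuals are timings; fitness is the exact DP cost.

* **selection** — two parents drawn independently with probability
  proportional to `exp(−β · (cost − best))`; default `β = ln 2`, i.e.
  one cost unit halves the selection odds.  Infeasible members get
  weight 0.
* **crossover** — pick a random host subtree `T` (an internal vertex
  and its internal descendants); list non-`T` vertices in first-parent
  order and `T` vertices in second-parent order; fill ranks `1..m`
  choosing, among eligible list heads (parent already placed), the
  vertex whose original time is closest to the rank being filled; exact
  ties are broken uniformly at random (the `tie_break` argument can pin
  a side, used to replay the worked example deterministically).  The
  complement of a subtree is parent-closed, so the fill never deadlocks
  and always yields a valid timing.
* **mutation** — `round(rate · S)` offspring receive one uniformly
  chosen adjacent-rank swap.
* **replacement** — full generational replacement; an external archive
  keeps the best cost seen and *every distinct* timing achieving it.

Defaults `S = 23`, `G = 45`, `mutation_rate = 0.05` follow the guidance
`G ≈ 2S` with `S·G ≈ 1000` DP evaluations, adequate for small-to-medium
trees; increase both for large hosts.  With `S = 1` and zero mutation
the search is stationary (crossover of a timing with itself is the
identity), which the tests use as a sanity invariant.  All randomness
flows from one `numpy.random.Generator`; scoring may be threaded but
results are independent of `thread_count`.

## Oracles

Deliberately independent of the DP recurrence (they share only the
grid/reachability rules and the mapping evaluator):

* `enumerate_reconciliations` — exhaustive minimum over all embeddings
  for a fixed timing (guarded to ≤ 7 tips per tree);
* `global_optimum` — exhaustive minimum over all linear extensions
  (guarded to ≤ 8 internal host vertices);
* `check_switch_compatibility` — classifies a switch set via a
  precedence digraph (ancestry arcs plus, per switch with takeoff
  `(a,b)` and landing `(c,d)`, arcs `a→d` and `c→b`; constraints
  against tips always hold and are dropped): **compatible** iff
  acyclic; otherwise **weakly incompatible** if relocating some
  landings to ancestor edges (paying losses) yields an acyclic graph (a
  witness relocation is returned), else **strongly incompatible**.

## Simulator

`simulate_host` grows a Yule (pure-birth) topology; the birth order *is*
the true timing.  `simulate_coevolution` then propagates parasite
lineages down the timed grid:

* at each host divergence a resident lineage cospeciates with
  probability `p_cosp / (p_cosp + p_loss)`, else follows one uniformly
  chosen child edge (a loss);
* within each slice a lineage duplicates with probability `p_dup` or
  switches to a uniformly chosen contemporaneous edge with probability
  `p_switch` (at most one such event per lineage per slice).

Defaults `p_cosp = 0.85`, `p_dup = 0.05`, `p_switch = 0.05`,
`p_loss = 0.15` produce cospeciation-dominated histories typical of
real datasets; they are implementation choices, not estimates.  All
surviving lineages are kept, so corpora naturally include host tips
with several parasites and host tips with none.  Histories with fewer
than two parasite tips are redrawn (up to `max_retries = 50`, then
`RuntimeError`).  The recorded placements/annotations re-cost exactly
to the recorded total, which upper-bounds the optimum — the basis of
the large-scale solver tests.

## Numerical conventions

* Costs are floats; `inf` is a first-class "forbidden" value (the file
  dialects accept the token `inf`).
* Optima are compared with absolute tolerance `1e-12` when collecting
  co-optimal timings/embeddings; all acceptance comparisons against
  oracles use `1e-9`.
* Ranks, slices and distances are exact integers.
* Determinism: identical seeds give byte-identical JSON reports across
  thread counts and file dialects.

## Limitations

* The GA is a heuristic: beyond the enumerable regime (≈ 8 internal
  host vertices) there is no optimality certificate across timings —
  only within the best timing found.
* `greedy_no_switch` is cost-optimal for the no-switch case only when
  cospeciation is the cheapest event (true of the default scheme); it
  also ignores zones/regions by construction and reports the
  unconstrained no-switch optimum.
* `random_timing` is not uniform over linear extensions; it is a cheap
  diversity source for the GA.
* Trees must be strictly bifurcating; polytomies are diagnosed, not
  resolved.
* One parasite tree per instance; multi-parasite datasets are run
  instance by instance.
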