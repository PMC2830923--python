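# cophylo

Event-based cophylogeny reconciliation: given a host phylogeny, a
parasite (or symbiont, gene, …) phylogeny, and an association of
parasite tips with host tips, `cophylo` reconstructs a cheapest
embedding of the parasite tree into the host tree under the four-event
model — **cospeciation** (the parasite diverges because its host
diverges), **duplication** (the parasite diverges on its host lineage),
**host switch** (one daughter lineage jumps to a contemporaneous host
lineage), and **loss** (a parasite lineage fails to follow one side of a
host divergence).  Each event type has a cost (defaults 0, 1, 1, 2) and
the reconstruction minimizes total cost.

## The timing problem, and how this package solves it

Host switches can only land on a host edge that exists *at the same
time* as the takeoff edge.  Because real phylogenies rarely come with
divergence dates, whether two edges overlap in time depends on the
unknown relative order of the host tree's internal vertices.  Methods
that ignore this can return "optimal" solutions whose switches are
mutually impossible under every timeline.

`cophylo` instead works with explicit **timings**: bijections from the
`m` internal host vertices to ranks `1..m` that respect ancestry (a
linear extension of the tree order), with all tips at rank `m+1`.  The
timing slices the host tree into time zones, and:

* for a **fixed timing**, a dynamic program over (parasite vertex, host
  edge, time slice) cells finds a provably minimum-cost reconciliation —
  and every host switch it reports is between contemporaneous edges by
  construction;
* across timings, a **genetic algorithm** searches the (factorially
  large) timing space: individuals are timings scored by the exact DP,
  recombined by a subtree-merge crossover and perturbed by adjacent-rank
  swap mutations, with selection weight `exp(−β·Δcost)`.

Optional problem features, all expressible in the input files:

* **time zones** — inclusive rank ranges constraining when a host or
  parasite vertex may occur (e.g. from fossil or biogeographic data);
* **regions** — a partition of host vertices with a per-region-pair
  switch-cost matrix replacing the scalar switch cost;
* **switch distance bound** — a cap on the topological distance
  (number of host vertices crossed) of any switch.

The package also ships ground-truth oracles (exhaustive enumeration of
embeddings and of timings, plus a strong/weak switch-compatibility
classifier), a forward coevolution simulator that emits instances with
known true histories, and readers/writers for two file dialects.

## Worked example

Simulate a 6-host-tip instance with a known true history, then solve it:

```text
$ cophylo simulate --host-tips 6 --seed 12 --prefix demo
wrote demo.nex, demo.tab, demo.truth.json (host 6 tips, parasite 6 tips, true cost 3)

$ cat demo.nex
#NEXUS
BEGIN TREES;
    TREE HOST = ((h1,(h2,(h3,h4)H5)H4)H3,(h5,h6)H2)H1;
    TREE PARASITE = ((p1,((p2,p3)P4,p4)P3)P2,(p5,p6)P5)P1;
END;
BEGIN COPHYLOGENY;
    ASSOCIATE p1 : h1;
    ASSOCIATE p2 : h2;
    ASSOCIATE p3 : h6;
    ASSOCIATE p4 : h3;
    ASSOCIATE p5 : h5;
    ASSOCIATE p6 : h6;
    COSTS 0 1 1 2;
END;

$ cophylo solve demo.nex --seed 1 -S 10 -G 20
best cost: 3
events: 4 cospeciations, 0 duplications, 1 host switches, 1 losses
distinct optimal timings found: 4
```

The search recovers the true cost (3).  To see a full embedding, solve
under a specific timing (here the true one, stored in the truth file;
the timing file format is one `vertex<TAB>rank` pair per line):

```text
$ cophylo solve-fixed demo.nex demo.timing
total cost: 3
events: 4 cospeciations, 0 duplications, 1 host switches, 1 losses
placements:
  P1           @H1                  cospeciation
  P2           @H3                  cospeciation
  P3           @H4                  cospeciation
  P4           (H4,h2)#4            host_switch
  P5           @H2                  cospeciation
  p1           @h1                  tip
  p2           @h2                  tip
  p3           @h6                  tip
  p4           @h3                  tip
  p5           @h5                  tip
  p6           @h6                  tip
```

`@H1` is a placement on host vertex `H1`; `(H4,h2)#4` is a placement on
the host edge from `H4` to `h2` during time slice 4, from which one
child of `P4` switches to a contemporaneous edge (its other descendant
line passes host vertex `H5` without diverging — the one loss).

The same instance in the tabular dialect (`demo.tab`) is plain
tab-separated edge lists; `cophylo convert --to tabular demo.nex`
translates between the two.  `--json` on either solve command emits the
complete machine-readable report, and `cophylo enumerate` cross-checks
tiny instances against exhaustive enumeration.

### The crossover operator, worked by hand

The GA's crossover merges two parent timings.  On a 9-internal-vertex
host tree with parents

```
tau1: a:1 b:2 c:3 f:4 d:5 h:6 g:7 e:8 i:9
tau2: a:1 c:2 f:3 b:4 d:5 h:6 g:7 i:8 e:9
```

and the subtree rooted at `f` chosen, the non-subtree vertices are
listed in `tau1` order (`a,b,c,d,g,e`) and the subtree vertices
(`f,h,i`) in `tau2` order.  Ranks `1..9` are then filled by repeatedly
taking, among the eligible list heads (a vertex becomes eligible once
its parent is placed), the one whose original time is closest to the
rank being filled — preferring the subtree candidate on ties.  The
result is the merge order `a,b,c,f,d,h,g,i,e`; in particular `a→1`,
`f→4`, `d→5`:

```python
>>> import numpy as np
>>> from cophylo import crossover, fixture
>>> ex = fixture("crossover_example")
>>> child = crossover(ex.host, ex.tau1, ex.tau2, np.random.default_rng(0),
...                   subtree_root=ex.subtree_root, tie_break="subtree")
>>> sorted(child, key=child.get)
['a', 'b', 'c', 'f', 'd', 'h', 'g', 'i', 'e']
```

## Python API in one screen

```python
import numpy as np
from cophylo import (simulate_tanglegram, solve, run_ga, GAConfig,
                     global_optimum, read_tanglegram)

hist = simulate_tanglegram(6, np.random.default_rng(12))   # known truth
sol  = solve(hist.tanglegram, hist.timing)                 # exact, fixed timing
res  = run_ga(hist.tanglegram, GAConfig(seed=1))           # search over timings
opt  = global_optimum(hist.tanglegram)                     # brute force (tiny only)
assert res.best_cost <= sol.total_cost <= hist.total_cost
```

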