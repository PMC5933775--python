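# Methods

This note records the model implemented by `kpdclear`, the default
parameters and why they were chosen, and the numerical decisions that affect
reproducibility.

## Model

A pool is a set of donor–patient **pairs** and **altruistic donors**. Each
donor and patient has an ABO blood type; each patient has a sensitization
level in [0, 1], interpreted as the probability that a crossmatch against a
random blood-compatible donor is positive. Compatibility arcs connect a
donor to another node's patient; arcs never point into altruistic nodes
(they have no patient).

ABO compatibility follows the standard rules: type-O donors give to anyone,
type-AB patients receive from anyone, and otherwise donor and patient types
must be identical.

Exchanges are enumerated up to a length bound *k* (default 3):

- **Cycles** over 2..*k* pair nodes; a cycle of *c* pairs yields *c*
  transplants. Cycles are stored in a canonical rotation starting at their
  smallest node id, so each cycle appears exactly once.
- **Chains** rooted at an altruistic donor, covering up to *k* nodes in
  total (root included); a chain over *c* nodes yields *c* − 1 transplants.
  Every prefix of a chain is itself listed, because a registry may choose to
  stop a chain early.

Clearing selects a subset of the enumerated list *M* whose exchanges share
no nodes, maximizing total utility (unit weights by default, so utility =
transplants). The exact formulation is weighted set packing: maximize
*u·x* subject to, for every node, Σ of *x* over exchanges containing that
node ≤ 1, *x* binary. It is solved with HiGHS through
`scipy.optimize.milp`.

## Penalized fitness

Metaheuristics search over unconstrained masks, so overlap is penalized
rather than forbidden:

    f(x) = Σ_i u_i x_i − (E1 + E2) · λ

E1 counts distinct nodes that *donate* in more than one selected exchange;
E2 counts distinct nodes that *receive* in more than one. A node is counted
once no matter how many times it is over-booked. The accounting is
arc-based: an exchange's donors are all its nodes except (for chains) the
terminal patient, and its patients are all its nodes except the chain root.
Two exchanges therefore conflict exactly when they share a node.

λ defaults to 10× the number of nodes appearing in *M*. Since total utility
is bounded by the node count (unit weights), any single over-booked node
costs more than the entire attainable utility, so every infeasible mask
scores strictly below every feasible one. The acceptance suite verifies this
separation on random instances.

## Binary ant lion optimizer

Positions are continuous vectors binarized by a rank operator: let *P* be
the 1-based descending argsort of *x* (stable, ties to the lower index);
bit *i* is 1 when *P_i ≥ P_{i+1}*, and the last bit is 0. Each generation,
every ant selects an antlion by roulette (fitness shifted by
−min + 1e−9 so all weights are positive), builds one candidate by a
single-bit flip of that antlion and another by a single-bit flip of the
elite, and combines them with a per-bit uniform crossover. An ant that
strictly beats its antlion replaces it; the elite is updated whenever an
antlion strictly beats it. Defaults: 200 ants, 200 antlions, 200
generations — the benchmark configuration used throughout.

The raw elite can still be infeasible on hard instances, so the reported
solution always passes through repair.

## Greedy repair

`postprocess` takes a feasible mask (an infeasible solver output is
restarted from the empty mask) and applies:

1. **Augment** — scan unselected exchanges in descending utility (ties by
   index) and add any that is node-disjoint from the selection; the result
   is maximal.
2. **Swap** — for each unselected candidate in descending utility, if
   exactly replacing the lowest-utility selected exchange of strictly lower
   utility keeps the selection disjoint, perform the swap.
3. **Augment again** — a swap can free nodes, so a final augmentation pass
   runs by default (`final_augment=False` restores the two-step variant).

Repair never lowers utility and preserves feasibility; the acceptance suite
checks both plus maximality on random instances.

## GA baseline

Generational GA over the same masks and fitness: population 800, 100
generations, roulette parent selection (same fitness shift), single-point
crossover with probability 0.8 (uniform crossover available), single-bit
mutation per offspring with probability 0.2, one elite carried over. The GA
is scored as a standalone solver: if its final best individual is
infeasible, the round counts zero transplants. On mid-sized pools this is
exactly the regime where the penalty landscape defeats the GA while the
ant lion optimizer with repair still clears the pool.

## Pool generator: realism and limitations

Blood types are drawn from U.S. frequencies (O 0.4814, A 0.3373, B 0.1428,
AB 0.0385) independently for donor and patient. Sensitization is drawn from
a three-level mix — PRA 0.05, 0.80, 0.995 with weights 0.08, 0.22, 0.70 —
calibrated once so that simulated pools of 30–200 pairs produce arc counts
and enumeration sizes on the scale of published registry simulations; the
classical low-sensitization mix (0.05/0.45/0.90 at 70/20/10%) yields pools
roughly ten times denser than registries report, because registries
accumulate precisely the hard-to-match patients. This calibration was
frozen before the acceptance criteria were evaluated and is not tuned per
test.

Internally compatible pairs (own donor blood-compatible and crossmatch
negative) are resampled, since they transplant directly; each candidate
pair receives exactly one crossmatch draw. Altruistic donors default to
⌈0.05 · n_pairs⌉. Arcs are drawn independently: donor *d* → patient *p*
exists when blood-compatible and a Bernoulli(1 − PRA_p) succeeds.

Omitted: HLA typing beyond the scalar PRA, donor age/quality edge weights,
arrival/departure dynamics (the orchestration layer supports multi-round
clearing but pools are static within a round), and match-failure reneging.

## Numerical and design decisions

- Seeds: all randomness flows through `numpy.random.default_rng`;
  experiment orchestration spawns independent child streams per
  (size, solver, repeat) via `SeedSequence.spawn`, so adding a solver does
  not perturb the other streams. Derived seeds stay below 2^31.
- Roulette shift ε = 1e−9 keeps weights positive when all fitnesses tie.
- Cycle canonicalization (minimum node id first) and the deterministic
  scan orders in repair (descending utility, ties by index) make all
  components reproducible bit-for-bit for a given seed.
- Enumeration uses `networkx.simple_cycles` with a length bound for cycles
  and a direct depth-first search for chains; both are validated in the
  test suite against exhaustive permutation oracles on graphs of up to 12
  nodes.
- Test problem sizes: exhaustive oracles cap |M| at ~15 (2^|M| scan);
  optimizer-vs-exact comparisons use 30–50-pair pools at default solver
  settings; the optimizer-vs-GA comparison uses 29–71-pair pools and a
  one-sided sign test over per-pool mean transplants.
- The package is a combinatorial optimization tool, not a fitted
  statistical model, so it exposes solver functions returning result
  objects (`SolveResult`, `RoundReport`, `ExperimentSummary`) rather than a
  fit/summary estimator interface.

## Known limitations

- The penalty landscape is flat across infeasible plateaus; the optimizer
  relies on single-bit flips to escape them, which is why repair is part of
  the default pipeline.
- Enumeration is exponential in *k*; *k* ≤ 4 is practical for the pool
  sizes targeted here.
- The exact solver's runtime grows with |M|; for the calibrated generator it
  remains sub-second up to a few thousand exchanges, which covers pools of
  ~200 pairs.
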