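"""Exact clearing and a genetic-algorithm baseline.

``solve_exact`` states clearing as the weighted set-packing integer program

    maximize  sum_c u_c x_c
    s.t.      sum_{c : t in c} x_c <= 1   for every node t,
              x_c in {0, 1},

over the enumerated exchange set M, and solves it with the HiGHS
branch-and-cut backend of :func:`scipy.optimize.milp`.  It is the optimality
oracle the heuristics are measured against.

``ga_solve`` is a standard generational binary GA sharing the penalized
objective with the ant lion optimizer: roulette parent selection (same
negative-fitness shift), single-point or uniform crossover, per-offspring
single-bit mutation, and carry-over of the single best individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .alo import SolveResult, gvp_binarize, _ROULETTE_EPS
from .enumeration import ExchangeSet
from .objective import ExchangeEvaluator, FitnessBreakdown, default_lambda

__all__ = ["GAParams", "solve_exact", "ga_solve"]


def solve_exact(m: ExchangeSet) -> SolveResult:
    """Maximum-total-utility node-disjoint subset of M (integer program)."""
    d = len(m)
    if d == 0:
        return SolveResult(
            np.zeros(0, dtype=np.int8), FitnessBreakdown(0.0, 0, 0, 1.0), np.zeros(0), "exact"
        )
    node_ids = m.node_ids
    index = {nid: i for i, nid in enumerate(node_ids)}
    a = np.zeros((len(node_ids), d))
    for c, e in enumerate(m):
        for nid in e.nodes:
            a[index[nid], c] = 1.0
    res = milp(
        c=-m.utilities,
        constraints=LinearConstraint(a, -np.inf, 1.0),
        integrality=np.ones(d),
        bounds=(0, 1),
    )
    if not res.success:  # pragma: no cover - packing LPs are always feasible
        raise RuntimeError(f"exact solver failed: {res.message}")
    sel = np.rint(res.x).astype(np.int8)
    ev = ExchangeEvaluator(m)
    breakdown = ev.breakdown(sel, default_lambda(m))
    return SolveResult(sel, breakdown, np.array([breakdown.fitness]), "exact")


@dataclass
class GAParams:
    population: int = 800
    iterations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    crossover: str = "single_point"  # or "uniform"
    penalty_lambda: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_prob <= 1.0 and 0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.crossover not in ("single_point", "uniform"):
            raise ValueError(f"unknown crossover {self.crossover!r}")
        if self.population < 2 or self.iterations < 1:
            raise ValueError("population must be >= 2 and iterations >= 1")


def _roulette_indices(fitness: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    shifted = fitness - fitness.min() + _ROULETTE_EPS
    return rng.choice(fitness.size, size=size, p=shifted / shifted.sum())


def ga_solve(m: ExchangeSet, params: GAParams | None = None) -> SolveResult:
    """Generational GA over binary masks; returns the best-ever individual
    and the per-generation best-fitness trace (non-decreasing by elitism)."""
    params = params or GAParams()
    d = len(m)
    if d == 0:
        return SolveResult(
            np.zeros(0, dtype=np.int8), FitnessBreakdown(0.0, 0, 0, 1.0),
            np.zeros(params.iterations), "ga",
        )
    lam = params.penalty_lambda if params.penalty_lambda is not None else default_lambda(m)
    rng = np.random.default_rng(params.seed)
    ev = ExchangeEvaluator(m)

    pop = np.array([gvp_binarize(rng.random(d)) for _ in range(params.population)])
    fitness = ev.fitness_many(pop, lam)
    best_i = int(np.argmax(fitness))
    elite, elite_f = pop[best_i].copy(), float(fitness[best_i])

    trace = np.empty(params.iterations)
    for gen in range(params.iterations):
        parents = pop[_roulette_indices(fitness, params.population, rng)]
        offspring = parents.copy()
        for a in range(0, params.population - 1, 2):
            if rng.random() < params.crossover_prob:
                p1, p2 = parents[a], parents[a + 1]
                if params.crossover == "single_point":
                    cut = int(rng.integers(1, d)) if d > 1 else 0
                    offspring[a, cut:], offspring[a + 1, cut:] = p2[cut:], p1[cut:]
                else:
                    swap = rng.random(d) < 0.5
                    offspring[a, swap], offspring[a + 1, swap] = p2[swap], p1[swap]
        mutate = np.flatnonzero(rng.random(params.population) < params.mutation_prob)
        bits = rng.integers(d, size=mutate.size)
        offspring[mutate, bits] ^= 1
        offspring[0] = elite  # elitist carry-over of the single best
        pop = offspring
        fitness = ev.fitness_many(pop, lam)
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > elite_f:
            elite, elite_f = pop[gen_best].copy(), float(fitness[gen_best])
        trace[gen] = elite_f

    return SolveResult(elite, ev.breakdown(elite, lam), trace, "ga")
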