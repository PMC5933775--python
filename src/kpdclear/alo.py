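"""Binary ant lion optimizer for exchange selection.

The classical ant lion optimizer (ALO) evolves two colonies of continuous
position vectors: *ants* walk the search space and *ant lions* build traps,
with the best ant lion (the *elite*) biasing every walk.  For exchange
selection the positions are binary masks over M, and the continuous random
walk is replaced by discrete operators:

* initialization maps uniform vectors on [0, 1]^d to binary masks through
  great-value-priority (GVP) rank binarization,
* the walk step is a single-bit flip applied to the roulette-selected ant
  lion (RA) and to the elite (RE),
* the new ant position takes each bit from RE with probability 1/2 and from
  RA otherwise (uniform crossover),
* an ant replaces its trap owner when strictly fitter (catch-and-rebuild),
  and the stored elite is updated whenever an ant lion beats it.

Fitness can be strongly negative (penalized infeasibility), so roulette
probabilities use the shifted values f - min(f) + eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enumeration import ExchangeSet
from .objective import ExchangeEvaluator, FitnessBreakdown, default_lambda

__all__ = [
    "ALOParams",
    "ALOState",
    "SolveResult",
    "gvp_binarize",
    "initialize_population",
    "roulette_select",
    "flip_mutation",
    "ant_update",
    "catch_and_rebuild",
    "run_alo",
]

_ROULETTE_EPS = 1e-9


@dataclass
class ALOParams:
    """Solver settings.  The search dimension is |M|, never configured."""

    n_ants: int = 200
    n_antlions: int = 200
    iterations: int = 200
    penalty_lambda: float | None = None  # default: 10x pool nodes, set per instance
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_ants, self.n_antlions, self.iterations) < 1:
            raise ValueError("population sizes and iteration count must be positive")


@dataclass
class ALOState:
    ants: np.ndarray                 # (n_ants, d) binary
    antlions: np.ndarray             # (n_antlions, d) binary
    ant_fitness: np.ndarray
    antlion_fitness: np.ndarray
    elite_position: np.ndarray
    elite_fitness: float
    rng: np.random.Generator = field(repr=False, default=None)


@dataclass
class SolveResult:
    """Best selection found by a solver, with its per-generation elite trace."""

    selection: np.ndarray
    breakdown: FitnessBreakdown
    trace: np.ndarray
    solver: str

    @property
    def utility(self) -> float:
        return self.breakdown.utility


def gvp_binarize(x: np.ndarray) -> np.ndarray:
    """Great-value-priority binarization of a continuous vector.

    Build the permutation P that lists the 1-based indices of x in
    descending value order (ties broken toward the lower index), then set
    Y_i = 1 exactly when P_i >= P_{i+1}; the last bit, which has no
    successor, is 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot binarize an empty vector")
    p = np.argsort(-x, kind="stable") + 1
    y = np.zeros(x.size, dtype=np.int8)
    y[:-1] = p[:-1] >= p[1:]
    return y


def initialize_population(
    evaluator: ExchangeEvaluator, params: ALOParams, penalty_lambda: float, rng: np.random.Generator
) -> ALOState:
    """Both colonies start from GVP-binarized uniform vectors on [0, 1]^d,
    fitness is evaluated, and the fittest ant lion becomes the elite."""
    d = len(evaluator.m)
    ants = np.array([gvp_binarize(rng.random(d)) for _ in range(params.n_ants)])
    antlions = np.array([gvp_binarize(rng.random(d)) for _ in range(params.n_antlions)])
    ant_fitness = evaluator.fitness_many(ants, penalty_lambda)
    antlion_fitness = evaluator.fitness_many(antlions, penalty_lambda)
    best = int(np.argmax(antlion_fitness))
    return ALOState(
        ants=ants,
        antlions=antlions,
        ant_fitness=ant_fitness,
        antlion_fitness=antlion_fitness,
        elite_position=antlions[best].copy(),
        elite_fitness=float(antlion_fitness[best]),
        rng=rng,
    )


def roulette_select(fitness: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportionate index draw after shifting by -min(f) + eps so
    that negative (penalized) fitness is handled."""
    f = np.asarray(fitness, dtype=float)
    if f.size == 0:
        raise ValueError("empty fitness vector")
    shifted = f - f.min() + _ROULETTE_EPS
    cum = np.cumsum(shifted)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def flip_mutation(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip one uniformly chosen bit (the binary stand-in for a random walk)."""
    out = np.array(position, dtype=np.int8, copy=True)
    i = rng.integers(out.size)
    out[i] ^= 1
    return out


def ant_update(ra: np.ndarray, re: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-dimension crossover of the mutated roulette ant lion (RA) and the
    mutated elite (RE): take RE's bit where r < 0.5, RA's otherwise."""
    ra = np.asarray(ra)
    re = np.asarray(re)
    if ra.shape != re.shape:
        raise ValueError("RA and RE must have the same dimension")
    return np.where(rng.random(ra.size) < 0.5, re, ra).astype(np.int8)


def catch_and_rebuild(state: ALOState, ant_index: int, antlion_index: int) -> ALOState:
    """If the ant is strictly fitter than its trap owner, the ant lion
    rebuilds at the ant's position (adopting position and fitness)."""
    if state.ant_fitness[ant_index] > state.antlion_fitness[antlion_index]:
        state.antlions[antlion_index] = state.ants[ant_index]
        state.antlion_fitness[antlion_index] = state.ant_fitness[ant_index]
    return state


def run_alo(m: ExchangeSet, params: ALOParams | None = None) -> SolveResult:
    """Full optimizer loop; returns the elite after ``iterations``
    generations plus the per-generation elite-fitness trace.

    Post-processing (greedy augmentation and swaps) is a separate stage; see
    :func:`kpdclear.postprocess.postprocess`.
    """
    params = params or ALOParams()
    if len(m) == 0:
        empty = np.zeros(0, dtype=np.int8)
        bd = FitnessBreakdown(0.0, 0, 0, params.penalty_lambda or 1.0)
        return SolveResult(empty, bd, np.zeros(params.iterations), "alo")
    lam = params.penalty_lambda if params.penalty_lambda is not None else default_lambda(m)
    rng = np.random.default_rng(params.seed)
    evaluator = ExchangeEvaluator(m)
    state = initialize_population(evaluator, params, lam, rng)

    donor_inc = evaluator.donor_inc
    patient_inc = evaluator.patient_inc
    utilities = evaluator.utilities
    trace = np.empty(params.iterations)
    for gen in range(params.iterations):
        for i in range(params.n_ants):
            j = roulette_select(state.antlion_fitness, rng)
            ra = flip_mutation(state.antlions[j], rng)
            re = flip_mutation(state.elite_position, rng)
            ant = ant_update(ra, re, rng)
            # inline single-mask fitness (hot path)
            e1 = np.count_nonzero(ant @ donor_inc > 1)
            e2 = np.count_nonzero(ant @ patient_inc > 1)
            f = float(ant @ utilities) - (e1 + e2) * lam
            state.ants[i] = ant
            state.ant_fitness[i] = f
            catch_and_rebuild(state, i, j)
            if state.antlion_fitness[j] > state.elite_fitness:
                state.elite_fitness = float(state.antlion_fitness[j])
                state.elite_position = state.antlions[j].copy()
        trace[gen] = state.elite_fitness

    breakdown = evaluator.breakdown(state.elite_position, lam)
    return SolveResult(state.elite_position.copy(), breakdown, trace, "alo")
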