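"""Round-based clearing and the benchmark harness.

``run_round`` performs one complete clearing round on a pool: build the
compatibility matrix, enumerate chains and cycles up to k, solve with the
chosen solver (post-processing the heuristics), then remove the matched
nodes so the pool is ready for the next round.  ``run_experiment`` is the
benchmark harness: per pool size it draws one pool, runs each stochastic
solver over several derived seeds and the exact solver once, and tabulates
best / mean +- sd / worst transplant counts.

Seeding: one top-level seed spawns independent streams per (size, solver,
repeat) through ``numpy.random.SeedSequence``, so adding a solver or repeat
never perturbs another stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alo import ALOParams, SolveResult, run_alo
from .baselines import GAParams, ga_solve, solve_exact
from .enumeration import ExchangeSet, enumerate_exchanges
from .generator import GeneratorParams, generate_pool
from .objective import decode
from .pool import KPDPool, build_compatibility_matrix, remove_matched
from .postprocess import postprocess

__all__ = ["RoundConfig", "RoundReport", "ExperimentSummary", "run_round", "run_experiment", "solve_set"]


@dataclass
class RoundConfig:
    k: int = 3
    solver: str = "alo"  # alo | ga | exact
    alo: ALOParams = field(default_factory=ALOParams)
    ga: GAParams = field(default_factory=GAParams)
    postprocess: bool = True
    seed: int | None = None


@dataclass
class RoundReport:
    pool_size_before: int
    pool_size_after: int
    n_exchanges: int
    chain_counts: dict[int, int]
    cycle_counts: dict[int, int]
    solver: str
    transplants: int
    utility: float
    generations: int
    seed: int | None


@dataclass
class ExperimentSummary:
    """Per (pool size, solver) statistics of transplant counts."""

    table: pd.DataFrame

    def to_markdown(self) -> str:
        df = self.table
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
        rows = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
        return "\n".join([header, sep, *rows])


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def solve_set(m: ExchangeSet, solver: str, *, seed: int | None = None,
              alo: ALOParams | None = None, ga: GAParams | None = None,
              post: bool = True) -> SolveResult:
    """Solve an exchange set with one named solver; heuristics get the
    greedy post-processing pass unless ``post`` is False."""
    if solver == "exact":
        return solve_exact(m)
    if solver == "alo":
        params = replace(alo or ALOParams(), seed=seed)
        result = run_alo(m, params)
    elif solver == "ga":
        params = replace(ga or GAParams(), seed=seed)
        result = ga_solve(m, params)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if post and len(m):
        from .objective import ExchangeEvaluator, default_lambda

        sel = postprocess(_feasible_or_empty(result.selection, m), m)
        ev = ExchangeEvaluator(m)
        result = SolveResult(sel, ev.breakdown(sel, default_lambda(m)), result.trace, result.solver)
    return result


def _feasible_or_empty(selection: np.ndarray, m: ExchangeSet) -> np.ndarray:
    """Heuristics can end on an infeasible mask; post-processing then starts
    from the empty solution (pure greedy repair)."""
    from .objective import is_feasible

    if len(m) and not is_feasible(selection, m):
        return np.zeros(len(m), dtype=np.int8)
    return selection


def run_round(pool: KPDPool, config: RoundConfig | None = None) -> tuple[RoundReport, KPDPool]:
    """One clearing round; returns the report and the updated pool with the
    matched nodes removed."""
    config = config or RoundConfig()
    matrix = build_compatibility_matrix(pool)
    m = enumerate_exchanges(matrix, config.k)
    result = solve_set(m, config.solver, seed=config.seed, alo=config.alo, ga=config.ga,
                       post=config.postprocess)
    chosen = decode(result.selection, m) if len(m) else []
    matched = {n for e in chosen for n in e.nodes}
    report = RoundReport(
        pool_size_before=len(pool),
        pool_size_after=len(pool) - len(matched),
        n_exchanges=len(m),
        chain_counts=m.counts_by_length("chain"),
        cycle_counts=m.counts_by_length("cycle"),
        solver=config.solver,
        transplants=sum(e.transplants for e in chosen),
        utility=float(result.utility),
        generations=len(result.trace),
        seed=config.seed,
    )
    return report, remove_matched(pool, matched)


def run_experiment(
    pool_sizes: list[int],
    repeats: int = 10,
    solvers: tuple[str, ...] = ("alo", "ga", "exact"),
    seed: int | None = None,
    k: int = 3,
    generator_params: GeneratorParams | None = None,
    alo: ALOParams | None = None,
    ga: GAParams | None = None,
) -> ExperimentSummary:
    """Benchmark across pool sizes (number of pairs).

    One pool per size (seeded); stochastic solvers run ``repeats`` times
    with independent derived seeds, the exact solver once.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for size, size_ss in zip(pool_sizes, root.spawn(len(pool_sizes))):
        pool_ss, *solver_ss = size_ss.spawn(1 + len(solvers))
        pool = generate_pool(size, params=generator_params, seed=np.random.default_rng(pool_ss))
        m = enumerate_exchanges(build_compatibility_matrix(pool), k)
        for solver, ss in zip(solvers, solver_ss):
            n_runs = 1 if solver == "exact" else repeats
            counts = []
            for rep_ss in ss.spawn(n_runs):
                res = solve_set(m, solver, seed=_derive_seed(rep_ss), alo=alo, ga=ga)
                counts.append(sum(e.transplants for e in decode(res.selection, m)))
            counts = np.array(counts, dtype=float)
            rows.append(
                {
                    "pool_size": size,
                    "n_exchanges": len(m),
                    "solver": solver,
                    "best": counts.max(),
                    "average": counts.mean(),
                    "sd": counts.std(),
                    "worst": counts.min(),
                    "repeats": n_runs,
                }
            )
    return ExperimentSummary(pd.DataFrame(rows))
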