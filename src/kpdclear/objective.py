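"""Penalized utility objective shared by all solvers.

A candidate solution is a binary selection vector over the enumerated
exchange set M.  Its fitness is

    f(Y) = sum of arc weights of the selected exchanges  -  (E1 + E2) * lambda

where E1 is the number of distinct nodes whose donor gives a kidney in more
than one selected arc and E2 the number of distinct nodes whose patient
receives in more than one selected arc.  A node used three times still
counts once.  With lambda much larger than any attainable utility, every
infeasible selection scores below every feasible one, so the penalty acts as
a soft constraint that separates cleanly.

Usage is counted per arc of each selected exchange: the altruistic donor of
a chain donates through its first arc, intermediate chain pairs both receive
and donate, the terminal chain pair only receives (its donor continues to
the deceased-donor waiting list and is not booked inside the pool), and
every pair of a cycle both donates and receives.  Under this accounting two
exchanges conflict exactly when they share a node, and a chain conflicts
with each of its own prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enumeration import Exchange, ExchangeSet

__all__ = ["FitnessBreakdown", "ExchangeEvaluator", "decode", "evaluate", "is_feasible", "default_lambda"]


@dataclass(frozen=True)
class FitnessBreakdown:
    """Fitness of one selection, with the penalty terms broken out."""

    utility: float
    e1: int          # nodes donating more than once
    e2: int          # nodes receiving more than once
    penalty_lambda: float

    @property
    def penalty(self) -> float:
        return (self.e1 + self.e2) * self.penalty_lambda

    @property
    def fitness(self) -> float:
        return self.utility - self.penalty

    @property
    def feasible(self) -> bool:
        return self.e1 == 0 and self.e2 == 0


def default_lambda(m: ExchangeSet) -> float:
    """Penalty weight: 10x the number of nodes involved in M, and never
    below 10x the total utility share any single node can carry.  Large
    enough that one double-booked node outweighs any utility gain."""
    return 10.0 * max(len(m.node_ids), 1)


class ExchangeEvaluator:
    """Precomputed donor/patient incidence of an exchange set.

    Evaluating a mask is then two small mat-vecs, which is what keeps the
    population solvers (tens of thousands of evaluations per run) cheap.
    """

    def __init__(self, m: ExchangeSet):
        self.m = m
        ids = m.node_ids
        index = {nid: i for i, nid in enumerate(ids)}
        self.n_nodes = len(ids)
        d = len(m)
        self.donor_inc = np.zeros((d, self.n_nodes), dtype=np.int8)
        self.patient_inc = np.zeros((d, self.n_nodes), dtype=np.int8)
        for e_idx, e in enumerate(m):
            for nid in e.donors:
                self.donor_inc[e_idx, index[nid]] = 1
            for nid in e.patients:
                self.patient_inc[e_idx, index[nid]] = 1
        self.utilities = m.utilities

    def breakdown(self, selection: np.ndarray, penalty_lambda: float) -> FitnessBreakdown:
        sel = _as_selection(selection, len(self.m))
        donor_use = sel @ self.donor_inc
        patient_use = sel @ self.patient_inc
        return FitnessBreakdown(
            utility=float(sel @ self.utilities),
            e1=int(np.count_nonzero(donor_use > 1)),
            e2=int(np.count_nonzero(patient_use > 1)),
            penalty_lambda=penalty_lambda,
        )

    def fitness_many(self, population: np.ndarray, penalty_lambda: float) -> np.ndarray:
        """Fitness of each row of a (pop x |M|) binary matrix."""
        pop = np.asarray(population)
        util = pop @ self.utilities
        e1 = np.count_nonzero(pop @ self.donor_inc > 1, axis=1)
        e2 = np.count_nonzero(pop @ self.patient_inc > 1, axis=1)
        return util - (e1 + e2) * penalty_lambda


def _as_selection(selection, d: int) -> np.ndarray:
    sel = np.asarray(selection, dtype=np.int64).ravel()
    if sel.shape != (d,):
        raise ValueError(f"selection length {sel.size} does not match |M| = {d}")
    if not np.isin(sel, (0, 1)).all():
        raise ValueError("selection entries must be 0 or 1")
    return sel


def _evaluator(m: ExchangeSet) -> ExchangeEvaluator:
    # cached on the exchange set: M is immutable once built
    ev = getattr(m, "_evaluator", None)
    if ev is None:
        ev = ExchangeEvaluator(m)
        m._evaluator = ev  # type: ignore[attr-defined]
    return ev


def decode(selection, m: ExchangeSet) -> list[Exchange]:
    """Exchanges at the selected indices, in M order."""
    sel = _as_selection(selection, len(m))
    return [m[i] for i in np.flatnonzero(sel)]


def evaluate(selection, m: ExchangeSet, penalty_lambda: float | None = None) -> FitnessBreakdown:
    """Penalized fitness of a selection over M."""
    if penalty_lambda is None:
        penalty_lambda = default_lambda(m)
    if penalty_lambda <= 0:
        raise ValueError("penalty lambda must be positive")
    return _evaluator(m).breakdown(selection, penalty_lambda)


def is_feasible(selection, m: ExchangeSet) -> bool:
    """True when no node donates or receives more than once."""
    return evaluate(selection, m, penalty_lambda=1.0).feasible
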