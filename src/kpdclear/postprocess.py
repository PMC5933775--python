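"""Greedy post-processing of a feasible solver solution.

Population solvers occasionally stall in a local optimum.  Two cheap
repairs recover most of the gap:

1. *augment*: scan M and add every exchange that is node-disjoint from the
   growing solution (the result is maximal);
2. *swap_improve*: for each unselected exchange, try to replace one selected
   exchange of strictly lower utility, provided the candidate is
   node-disjoint from the rest of the solution.

Both phases scan in descending utility (ties by M index) so the outcome is
deterministic.  The combined pass costs at most |M| + |M|*|solution| trials
versus 2^|M| for exhaustive search.  A final augment pass follows the swap
phase because a swap can shrink the set of used nodes and open room for
another disjoint exchange; set ``final_augment=False`` for the strict
augment-then-swap sweep.
"""

from __future__ import annotations

import numpy as np

from .enumeration import ExchangeSet
from .objective import _as_selection, is_feasible

__all__ = ["augment", "swap_improve", "postprocess"]


def _scan_order(m: ExchangeSet) -> list[int]:
    return sorted(range(len(m)), key=lambda i: (-m[i].utility, i))


def _node_sets(m: ExchangeSet) -> list[frozenset[int]]:
    return [frozenset(e.nodes) for e in m]


def augment(selection, m: ExchangeSet) -> np.ndarray:
    """Add every exchange node-disjoint from the (growing) solution,
    scanning by descending utility.  Input must be feasible; output is
    feasible and maximal."""
    sel = _as_selection(selection, len(m)).copy()
    if not is_feasible(sel, m):
        raise ValueError("augment requires a feasible input solution")
    nodes = _node_sets(m)
    used: set[int] = set().union(*(nodes[i] for i in np.flatnonzero(sel)), set())
    for i in _scan_order(m):
        if not sel[i] and used.isdisjoint(nodes[i]):
            sel[i] = 1
            used |= nodes[i]
    return sel


def swap_improve(selection, m: ExchangeSet) -> np.ndarray:
    """One pass of utility-improving single-exchange swaps.

    For each unselected exchange (descending utility) find a selected one of
    strictly lower utility whose removal makes the candidate node-disjoint
    from the remainder; among eligible victims the lowest-utility one is
    replaced.  Total utility never decreases.
    """
    sel = _as_selection(selection, len(m)).copy()
    if not is_feasible(sel, m):
        raise ValueError("swap_improve requires a feasible input solution")
    nodes = _node_sets(m)
    order = _scan_order(m)
    for i in order:
        if sel[i]:
            continue
        # victims scanned worst-utility-first so the swap gains the most
        for j in reversed(order):
            if not sel[j] or m[j].utility >= m[i].utility:
                continue
            rest = set().union(
                *(nodes[s] for s in np.flatnonzero(sel) if s != j), set()
            )
            if rest.isdisjoint(nodes[i]):
                sel[j] = 0
                sel[i] = 1
                break
    return sel


def postprocess(selection, m: ExchangeSet, final_augment: bool = True) -> np.ndarray:
    """augment -> swap_improve -> augment (the trailing pass optional).

    Preserves feasibility and never decreases utility.
    """
    sel = augment(selection, m)
    sel = swap_improve(sel, m)
    if final_augment:
        sel = augment(sel, m)
    return sel
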