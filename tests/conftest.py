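"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own enumeration/solver code
paths: chains and cycles are found by checking every candidate node
sequence against the raw matrix, and the optimal clearing is found by
scoring all 2^|M| subsets with plain node-set arithmetic.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from kpdclear import (
    BloodType,
    CompatRelation,
    KPDPool,
    NodeKind,
    PoolNode,
    build_compatibility_matrix,
    make_worked_example,
)


# --------------------------------------------------------------------------
# instance builders


def random_pool(rng: np.random.Generator, n_pairs: int, n_alt: int, p_arc: float,
                weighted: bool = False) -> KPDPool:
    """A structurally valid random pool with Bernoulli(p_arc) arcs; blood
    types are placeholders (arcs are drawn directly, not from ABO rules)."""
    nodes = [
        PoolNode(i, NodeKind.PAIR, BloodType.O, BloodType.AB) for i in range(n_pairs)
    ] + [
        PoolNode(n_pairs + a, NodeKind.ALTRUISTIC, BloodType.O) for a in range(n_alt)
    ]
    relations = []
    for i in range(n_pairs + n_alt):
        for j in range(n_pairs):
            if i != j and rng.random() < p_arc:
                w = float(rng.integers(1, 4)) if weighted else 1.0
                relations.append(CompatRelation(i, j, w))
    return KPDPool(nodes, relations)


# --------------------------------------------------------------------------
# brute-force oracles


def oracle_chains(matrix, k: int) -> set[tuple[int, ...]]:
    """Every simple path of 2..k nodes rooted at an altruistic node, found
    by checking all candidate sequences against the matrix."""
    ids = list(matrix.node_ids)
    pair_ids = [i for i in ids if i not in matrix.altruistic]
    out = set()
    for length in range(2, k + 1):
        for root in matrix.altruistic:
            for rest in itertools.permutations(pair_ids, length - 1):
                seq = (root, *rest)
                if all(matrix.weight(a, b) > 0 for a, b in zip(seq, seq[1:])):
                    out.add(seq)
    return out


def oracle_cycles(matrix, k: int) -> set[tuple[int, ...]]:
    """Every simple cycle of 2..k pair nodes, canonicalized by rotating the
    minimum id first."""
    pair_ids = [i for i in matrix.node_ids if i not in matrix.altruistic]
    out = set()
    for length in range(2, k + 1):
        for combo in itertools.combinations(pair_ids, length):
            first = combo[0]  # fix the minimum element as the rotation anchor
            for rest in itertools.permutations(combo[1:]):
                seq = (first, *rest)
                arcs = list(zip(seq, seq[1:])) + [(seq[-1], seq[0])]
                if all(matrix.weight(a, b) > 0 for a, b in arcs):
                    out.add(seq)
    return out


def oracle_optimum(m) -> float:
    """Maximum utility over all node-disjoint subsets of M (2^|M| scan)."""
    node_sets = [frozenset(e.nodes) for e in m]
    utilities = [e.utility for e in m]
    best = 0.0
    for mask in range(1 << len(m)):
        chosen = [i for i in range(len(m)) if mask >> i & 1]
        union: set[int] = set()
        total = 0.0
        ok = True
        for i in chosen:
            if union & node_sets[i]:
                ok = False
                break
            union |= node_sets[i]
            total += utilities[i]
        if ok and total > best:
            best = total
    return best


def feasible_subsets(m) -> list[np.ndarray]:
    """All feasible masks of M (node-disjointness by set arithmetic)."""
    node_sets = [frozenset(e.nodes) for e in m]
    out = []
    for mask in range(1 << len(m)):
        chosen = [i for i in range(len(m)) if mask >> i & 1]
        union: set[int] = set()
        ok = True
        for i in chosen:
            if union & node_sets[i]:
                ok = False
                break
            union |= node_sets[i]
        if ok:
            sel = np.zeros(len(m), dtype=np.int8)
            sel[chosen] = 1
            out.append(sel)
    return out


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def worked_matrix():
    """The worked example's exchange structure realised as an actual pool,
    for tests that need a matrix (enumeration yields a superset of the four
    hand exchanges; the fixture itself is built directly)."""
    pool = KPDPool(
        [PoolNode(i, NodeKind.PAIR, BloodType.O, BloodType.AB) for i in range(7)]
        + [PoolNode(i, NodeKind.ALTRUISTIC, BloodType.O) for i in (7, 8)],
        [
            CompatRelation(7, 0), CompatRelation(8, 1), CompatRelation(1, 2),
            CompatRelation(3, 4), CompatRelation(4, 3),
            CompatRelation(0, 3), CompatRelation(3, 5), CompatRelation(5, 0),
        ],
    )
    return build_compatibility_matrix(pool)
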