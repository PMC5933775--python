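"""Bounded enumeration of exchange chains and cycles.

Clearing is done over an explicitly enumerated exchange set M: every simple
directed path of at most k nodes rooted at an altruistic donor (a *chain*,
yielding len-1 transplants) and every simple directed cycle of 2..k pair
nodes (a *cycle*, yielding len transplants).  The index order of M is the
dimension order of all downstream solvers, so it is fixed deterministically:
all chains first, then all cycles, each group sorted by (length, node
sequence); cycles are stored in the canonical rotation that puts their
minimum node id first.

Chain prefixes are enumerated as separate exchanges: a chain a->n1->n2 and
its prefix a->n1 are both members of M (selecting both is infeasible and is
rejected by the objective).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .pool import CompatibilityMatrix

__all__ = [
    "Exchange",
    "ExchangeSet",
    "extract_chains",
    "extract_cycles",
    "enumerate_exchanges",
    "make_worked_example",
    "write_exchanges_jsonl",
    "read_exchanges_jsonl",
]


@dataclass(frozen=True)
class Exchange:
    """One chain or cycle, as an ordered tuple of node ids.

    For a chain the first node is the altruistic donor and the arcs are the
    consecutive pairs (len - 1 arcs).  For a cycle every node is a pair and
    the arcs include the closing arc (len arcs).  ``utility`` is the sum of
    the arc weights.
    """

    kind: str  # "chain" | "cycle"
    nodes: tuple[int, ...]
    utility: float

    def __post_init__(self) -> None:
        if self.kind not in ("chain", "cycle"):
            raise ValueError(f"unknown exchange kind {self.kind!r}")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("exchange nodes must be distinct")
        if len(self.nodes) < 2:
            raise ValueError("an exchange needs at least two nodes")

    @property
    def arcs(self) -> tuple[tuple[int, int], ...]:
        pairs = list(zip(self.nodes, self.nodes[1:]))
        if self.kind == "cycle":
            pairs.append((self.nodes[-1], self.nodes[0]))
        return tuple(pairs)

    @property
    def transplants(self) -> int:
        """Number of kidneys transplanted inside the pool (= number of arcs)."""
        return len(self.nodes) - 1 if self.kind == "chain" else len(self.nodes)

    @property
    def donors(self) -> tuple[int, ...]:
        """Nodes whose donor gives a kidney within this exchange."""
        return self.nodes[:-1] if self.kind == "chain" else self.nodes

    @property
    def patients(self) -> tuple[int, ...]:
        """Nodes whose patient receives a kidney within this exchange."""
        return self.nodes[1:] if self.kind == "chain" else self.nodes


class ExchangeSet:
    """Ordered exchange list M; index order defines solver dimensions."""

    def __init__(self, exchanges: Iterable[Exchange], k: int):
        self.exchanges: tuple[Exchange, ...] = tuple(exchanges)
        self.k = int(k)
        seen = set()
        for e in self.exchanges:
            key = (e.kind, e.nodes)
            if key in seen:
                raise ValueError(f"duplicate exchange {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.exchanges)

    def __getitem__(self, i: int) -> Exchange:
        return self.exchanges[i]

    def __iter__(self) -> Iterator[Exchange]:
        return iter(self.exchanges)

    @property
    def utilities(self) -> np.ndarray:
        return np.array([e.utility for e in self.exchanges], dtype=float)

    @property
    def node_ids(self) -> list[int]:
        """All node ids appearing in at least one exchange, sorted."""
        return sorted({n for e in self.exchanges for n in e.nodes})

    def counts_by_length(self, kind: str) -> dict[int, int]:
        out: dict[int, int] = {}
        for e in self.exchanges:
            if e.kind == kind:
                out[len(e.nodes)] = out.get(len(e.nodes), 0) + 1
        return out


def _canonical_rotation(nodes: tuple[int, ...]) -> tuple[int, ...]:
    """Rotate a cycle so its minimum node id comes first (rotation-invariant
    identity; direction is preserved)."""
    i = nodes.index(min(nodes))
    return nodes[i:] + nodes[:i]


def _arc_sum(matrix: CompatibilityMatrix, arcs: Iterable[tuple[int, int]]) -> float:
    return float(sum(matrix.weight(a, b) for a, b in arcs))


def extract_chains(matrix: CompatibilityMatrix, k: int) -> list[Exchange]:
    """Depth-first enumeration of every simple path of 2..k nodes rooted at
    an altruistic donor; each prefix is saved as its own chain."""
    if k < 2:
        raise ValueError("k must be at least 2")
    found: list[tuple[int, ...]] = []
    v = matrix.v

    def dfs(path: list[int]) -> None:
        if len(path) >= 2:
            found.append(tuple(path))
        if len(path) == k:
            return
        for nxt in np.flatnonzero(v[path[-1]]):
            if nxt not in path:
                path.append(int(nxt))
                dfs(path)
                path.pop()

    for alt_id in sorted(matrix.altruistic):
        dfs([matrix.id_to_index[alt_id]])

    chains = [
        Exchange(
            "chain",
            nodes := tuple(matrix.node_ids[i] for i in idx_path),
            _arc_sum(matrix, zip(nodes, nodes[1:])),
        )
        for idx_path in found
    ]
    chains.sort(key=lambda e: (len(e.nodes), e.nodes))
    return chains


def extract_cycles(matrix: CompatibilityMatrix, k: int) -> list[Exchange]:
    """All simple directed cycles of 2..k pair nodes, each reported once in
    canonical rotation."""
    if k < 2:
        raise ValueError("k must be at least 2")
    pair_indices = [
        i for i, nid in enumerate(matrix.node_ids) if nid not in matrix.altruistic
    ]
    g = nx.DiGraph()
    g.add_nodes_from(pair_indices)
    sub = matrix.v[np.ix_(pair_indices, pair_indices)]
    for a, b in zip(*np.nonzero(sub)):
        g.add_edge(pair_indices[a], pair_indices[b])

    cycles = []
    for cyc in nx.simple_cycles(g, length_bound=k):
        if len(cyc) < 2:
            continue
        nodes = _canonical_rotation(tuple(matrix.node_ids[i] for i in cyc))
        ex = Exchange("cycle", nodes, 0.0)
        cycles.append(Exchange("cycle", nodes, _arc_sum(matrix, ex.arcs)))
    cycles.sort(key=lambda e: (len(e.nodes), e.nodes))
    return cycles


def enumerate_exchanges(matrix: CompatibilityMatrix, k: int = 3) -> ExchangeSet:
    """Full pre-processing stage: M = chains ++ cycles in deterministic order."""
    return ExchangeSet(extract_chains(matrix, k) + extract_cycles(matrix, k), k)


def make_worked_example() -> ExchangeSet:
    """The four-exchange hand instance used throughout the docs and tests.

    Dimensions, in M order (unit arc weights):

    ======  ======================  =========
    index   exchange                utility
    ======  ======================  =========
    0       chain  7 -> 0           1
    1       chain  8 -> 1 -> 2      2
    2       cycle  3 <-> 4          2
    3       cycle  0 -> 3 -> 5 -> 0 3
    ======  ======================  =========

    Pair node 0 appears in the short chain and in the 3-cycle, and pair node
    3 appears in both cycles, so the global optimum is 5 transplants
    (selecting exchanges {1, 3}, or equivalently {0, 1, 2}); selecting
    {0, 1, 3} double-books node 0 and is penalized.
    """
    exchanges = [
        Exchange("chain", (7, 0), 1.0),
        Exchange("chain", (8, 1, 2), 2.0),
        Exchange("cycle", (3, 4), 2.0),
        Exchange("cycle", (0, 3, 5), 3.0),
    ]
    return ExchangeSet(exchanges, k=3)


def write_exchanges_jsonl(m: ExchangeSet, path: str | Path) -> None:
    """Persist an exchange set as JSON lines so solver runs are replayable
    without re-enumeration.  The first line carries the length bound k."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"k": m.k}) + "\n")
        for e in m:
            fh.write(json.dumps({"kind": e.kind, "nodes": list(e.nodes), "utility": e.utility}) + "\n")


def read_exchanges_jsonl(path: str | Path) -> ExchangeSet:
    with open(path) as fh:
        header = json.loads(fh.readline())
        exchanges = [
            Exchange(d["kind"], tuple(d["nodes"]), float(d["utility"]))
            for line in fh
            if (d := json.loads(line))
        ]
    return ExchangeSet(exchanges, k=header["k"])
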