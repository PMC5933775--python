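"""KPD pool representation and compatibility-matrix construction.

A kidney-paired-donation (KPD) pool holds two kinds of nodes: incompatible
donor--patient *pairs* and *altruistic* (non-directed) donors.  A weighted
directed relation (i -> j, w_ij) states that the donor of node i can give a
kidney to the patient of node j with utility w_ij.  The pool is summarised by
a square compatibility matrix v with v[i, j] = w_ij and zeros elsewhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BloodType",
    "NodeKind",
    "PoolNode",
    "CompatRelation",
    "KPDPool",
    "CompatibilityMatrix",
    "blood_compatible",
    "build_compatibility_matrix",
    "remove_matched",
]


class BloodType(str, enum.Enum):
    """ABO blood group of a donor or patient."""

    A = "A"
    B = "B"
    AB = "AB"
    O = "O"


class NodeKind(str, enum.Enum):
    PAIR = "pair"
    ALTRUISTIC = "altruistic"


def blood_compatible(donor: BloodType, patient: BloodType) -> bool:
    """ABO compatibility: O donates to anyone, AB receives from anyone,
    and identical groups are always compatible."""
    donor = BloodType(donor)
    patient = BloodType(patient)
    return donor is BloodType.O or patient is BloodType.AB or donor is patient


@dataclass(frozen=True, slots=True)
class PoolNode:
    """One pool node: an incompatible pair or an altruistic donor.

    ``sensitization`` is the patient's crossmatch-failure probability (a PRA
    proxy); it is generator metadata and plays no role in clearing.
    """

    id: int
    kind: NodeKind
    donor_blood: BloodType
    patient_blood: BloodType | None = None
    sensitization: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", NodeKind(self.kind))
        object.__setattr__(self, "donor_blood", BloodType(self.donor_blood))
        if self.kind is NodeKind.PAIR:
            if self.patient_blood is None:
                raise ValueError(f"pair node {self.id} requires a patient blood type")
            object.__setattr__(self, "patient_blood", BloodType(self.patient_blood))
        elif self.patient_blood is not None:
            raise ValueError(f"altruistic node {self.id} cannot carry a patient blood type")
        if not 0.0 <= self.sensitization <= 1.0:
            raise ValueError(f"sensitization must lie in [0, 1], got {self.sensitization}")


@dataclass(frozen=True, slots=True)
class CompatRelation:
    """Directed compatibility arc: donor of ``donor_node`` -> patient of
    ``patient_node`` with positive utility ``weight``."""

    donor_node: int
    patient_node: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.donor_node == self.patient_node:
            raise ValueError("self-relations are forbidden: pool pairs are incompatible by definition")
        if not self.weight > 0:
            raise ValueError(f"relation weight must be positive, got {self.weight}")


class KPDPool:
    """A validated KPD pool of pair/altruistic nodes and compatibility arcs.

    Invariants enforced at construction:

    * node ids are unique,
    * every relation endpoint is a pool node,
    * no relation points at an altruistic node (they have no patient),
    * no duplicate (donor, patient) relation.
    """

    def __init__(self, nodes: Iterable[PoolNode], relations: Iterable[CompatRelation] = ()) -> None:
        self.nodes: tuple[PoolNode, ...] = tuple(nodes)
        self.relations: tuple[CompatRelation, ...] = tuple(relations)
        self._by_id: dict[int, PoolNode] = {}
        for node in self.nodes:
            if node.id in self._by_id:
                raise ValueError(f"duplicate node id {node.id}")
            self._by_id[node.id] = node
        seen: set[tuple[int, int]] = set()
        for rel in self.relations:
            for endpoint in (rel.donor_node, rel.patient_node):
                if endpoint not in self._by_id:
                    raise ValueError(f"relation references unknown node id {endpoint}")
            if self._by_id[rel.patient_node].kind is NodeKind.ALTRUISTIC:
                raise ValueError(
                    f"relation {rel.donor_node}->{rel.patient_node} targets an altruistic node"
                )
            key = (rel.donor_node, rel.patient_node)
            if key in seen:
                raise ValueError(f"duplicate relation {key}")
            seen.add(key)

    # -- basic accessors -------------------------------------------------

    def node(self, node_id: int) -> PoolNode:
        return self._by_id[node_id]

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._by_id

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def pair_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.kind is NodeKind.PAIR)

    @property
    def altruistic_ids(self) -> list[int]:
        return sorted(n.id for n in self.nodes if n.kind is NodeKind.ALTRUISTIC)

    @property
    def n_pairs(self) -> int:
        return sum(1 for n in self.nodes if n.kind is NodeKind.PAIR)

    @property
    def n_altruistic(self) -> int:
        return len(self.nodes) - self.n_pairs

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"KPDPool(pairs={self.n_pairs}, altruistic={self.n_altruistic}, "
            f"relations={len(self.relations)})"
        )


@dataclass
class CompatibilityMatrix:
    """Square utility matrix over the pool nodes.

    Rows/columns are ordered pair nodes first (ascending id), then altruistic
    nodes (ascending id).  ``v[i, j]`` is the utility of the arc from the
    donor of the node at index i to the patient of the node at index j, and 0
    where no arc exists.  Columns of altruistic nodes are all zero.
    """

    v: np.ndarray
    node_ids: tuple[int, ...]            # index -> node id
    altruistic: frozenset[int]           # node ids of altruistic donors
    id_to_index: Mapping[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.id_to_index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def size(self) -> int:
        return self.v.shape[0]

    def weight(self, donor_id: int, patient_id: int) -> float:
        return float(self.v[self.id_to_index[donor_id], self.id_to_index[patient_id]])


def build_compatibility_matrix(pool: KPDPool) -> CompatibilityMatrix:
    """Assemble the compatibility matrix from the pool's relation list.

    A pure function of the pool: the matrix starts at zero and each relation
    writes its weight into a single cell, so the number of non-zero entries
    equals the number of relations.
    """
    node_ids = tuple(pool.pair_ids + pool.altruistic_ids)
    index = {nid: i for i, nid in enumerate(node_ids)}
    size = len(node_ids)
    v = np.zeros((size, size), dtype=float)
    for rel in pool.relations:
        v[index[rel.donor_node], index[rel.patient_node]] = rel.weight
    return CompatibilityMatrix(v=v, node_ids=node_ids, altruistic=frozenset(pool.altruistic_ids))


def remove_matched(pool: KPDPool, matched_node_ids: Iterable[int]) -> KPDPool:
    """Return a new pool with the matched nodes and every arc touching them
    removed; the input pool is untouched.  Used between clearing rounds."""
    matched = set(matched_node_ids)
    unknown = matched - {n.id for n in pool.nodes}
    if unknown:
        raise ValueError(f"unknown node ids: {sorted(unknown)}")
    nodes = [n for n in pool.nodes if n.id not in matched]
    relations = [
        r for r in pool.relations
        if r.donor_node not in matched and r.patient_node not in matched
    ]
    return KPDPool(nodes, relations)
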