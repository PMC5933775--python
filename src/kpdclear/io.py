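"""Pool serialization: JSON, two-file CSV, GraphML and DOT export."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .pool import CompatRelation, KPDPool, NodeKind, PoolNode

__all__ = [
    "pool_to_json",
    "pool_from_json",
    "pool_to_csv",
    "pool_from_csv",
    "pool_to_digraph",
    "export_graphml",
    "export_dot",
]


def _node_dict(n: PoolNode) -> dict:
    d = {"id": n.id, "kind": n.kind.value, "donor_blood": n.donor_blood.value}
    if n.kind is NodeKind.PAIR:
        d["patient_blood"] = n.patient_blood.value
        d["sensitization"] = n.sensitization
    return d


def pool_to_json(pool: KPDPool, path: str | Path | None = None) -> dict:
    """Serialize to a dict with ``nodes`` and ``relations`` arrays; written
    to ``path`` when given."""
    payload = {
        "nodes": [_node_dict(n) for n in pool.nodes],
        "relations": [
            {"donor": r.donor_node, "patient": r.patient_node, "weight": r.weight}
            for r in pool.relations
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def pool_from_json(source: str | Path | dict) -> KPDPool:
    data = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    nodes = [
        PoolNode(
            id=d["id"],
            kind=d["kind"],
            donor_blood=d["donor_blood"],
            patient_blood=d.get("patient_blood"),
            sensitization=d.get("sensitization", 0.0),
        )
        for d in data["nodes"]
    ]
    relations = [
        CompatRelation(r["donor"], r["patient"], r.get("weight", 1.0))
        for r in data["relations"]
    ]
    return KPDPool(nodes, relations)


def pool_to_csv(pool: KPDPool, nodes_path: str | Path, relations_path: str | Path) -> None:
    """Two-file CSV dialect: nodes.csv (id,kind,donor_blood,patient_blood,
    sensitization) and relations.csv (donor,patient,weight)."""
    pd.DataFrame(
        [
            {
                "id": n.id,
                "kind": n.kind.value,
                "donor_blood": n.donor_blood.value,
                "patient_blood": n.patient_blood.value if n.patient_blood else "",
                "sensitization": n.sensitization,
            }
            for n in pool.nodes
        ]
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        [
            {"donor": r.donor_node, "patient": r.patient_node, "weight": r.weight}
            for r in pool.relations
        ],
        columns=["donor", "patient", "weight"],
    ).to_csv(relations_path, index=False)


def pool_from_csv(nodes_path: str | Path, relations_path: str | Path) -> KPDPool:
    ndf = pd.read_csv(nodes_path, keep_default_na=False)
    rdf = pd.read_csv(relations_path)
    nodes = [
        PoolNode(
            id=int(row.id),
            kind=row.kind,
            donor_blood=row.donor_blood,
            patient_blood=row.patient_blood or None,
            sensitization=float(getattr(row, "sensitization", 0.0)),
        )
        for row in ndf.itertuples()
    ]
    relations = [
        CompatRelation(int(row.donor), int(row.patient), float(row.weight))
        for row in rdf.itertuples()
    ]
    return KPDPool(nodes, relations)


def pool_to_digraph(pool: KPDPool) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in pool.nodes:
        g.add_node(n.id, kind=n.kind.value, donor_blood=n.donor_blood.value)
    for r in pool.relations:
        g.add_edge(r.donor_node, r.patient_node, weight=r.weight)
    return g


def export_graphml(pool: KPDPool, path: str | Path) -> None:
    nx.write_graphml(pool_to_digraph(pool), str(path))


def export_dot(pool: KPDPool, path: str | Path) -> None:
    """Minimal Graphviz DOT export (altruistic donors drawn as boxes)."""
    lines = ["digraph kpd {"]
    for n in pool.nodes:
        shape = "box" if n.kind is NodeKind.ALTRUISTIC else "ellipse"
        lines.append(f'  {n.id} [shape={shape} label="{n.id}"];')
    for r in pool.relations:
        lines.append(f"  {r.donor_node} -> {r.patient_node} [weight={r.weight}];")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
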