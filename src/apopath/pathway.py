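"""Apoptosis pathway graph: assembly, receptor-rooted layering, import/export.

Physical protein interactions are undirected; the "direction" of signaling is
a derived quantity.  Cell-death receptors are the entry points of the
cascade, so each node's *layer* is its minimum hop distance from any
receptor (breadth-first over the undirected edges).  Ligands are
extracellular: they neither seed nor relay the intracellular traversal and
are assigned the sentinel layer -1.  Nodes unreachable from every receptor
keep layer ``None``.

Edges carry provenance (``database`` for experimentally backed interactions,
``predicted`` for interolog transfers) which every transform and export
preserves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .panel import Category

__all__ = [
    "Role",
    "Compartment",
    "Provenance",
    "PathwayNode",
    "PathwayGraph",
    "GraphValidationError",
    "build_graph",
    "orient_from_receptors",
    "export_graph",
    "import_graph_json",
    "role_for_category",
    "compartment_for_role",
]

LIGAND_LAYER = -1


class Role(str, Enum):
    RECEPTOR = "receptor"
    LIGAND = "ligand"
    EFFECTOR = "effector"
    KINASE = "kinase"
    TRANSCRIPTION_FACTOR = "transcription_factor"
    OTHER = "other"


class Compartment(str, Enum):
    EXTRACELLULAR = "extracellular"
    MEMBRANE = "membrane"
    CYTOPLASM = "cytoplasm"
    MITOCHONDRION = "mitochondrion"
    NUCLEUS = "nucleus"
    UNKNOWN = "unknown"


class Provenance(str, Enum):
    DATABASE = "database"
    PREDICTED = "predicted"


class GraphValidationError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayNode:
    symbol: str
    role: Role = Role.OTHER
    compartment: Compartment = Compartment.UNKNOWN

    def __post_init__(self) -> None:
        # ligands are by definition extracellular death-receptor ligands
        if self.role is Role.LIGAND and self.compartment not in (
            Compartment.EXTRACELLULAR,
            Compartment.UNKNOWN,
        ):
            raise GraphValidationError(
                f"ligand {self.symbol} must be extracellular, got {self.compartment}"
            )
        if self.role is Role.LIGAND:
            object.__setattr__(self, "compartment", Compartment.EXTRACELLULAR)


def role_for_category(category: Category) -> Role:
    """Map a panel functional category to a pathway-map node role."""
    return {
        Category.CELL_DEATH_RECEPTOR: Role.RECEPTOR,
        Category.DECOY_RECEPTOR: Role.RECEPTOR,
        Category.LIGAND: Role.LIGAND,
        Category.PROTEASE: Role.EFFECTOR,
        Category.APOPTOSIS_INHIBITOR: Role.EFFECTOR,
        Category.MITOCHONDRIAL_PROTEIN: Role.EFFECTOR,
        Category.SIGNAL_MOLECULE: Role.KINASE,
        Category.TRANSCRIPTION_FACTOR: Role.TRANSCRIPTION_FACTOR,
    }.get(category, Role.OTHER)


def compartment_for_role(role: Role, category: Optional[Category] = None) -> Compartment:
    if role is Role.LIGAND:
        return Compartment.EXTRACELLULAR
    if role is Role.RECEPTOR:
        return Compartment.MEMBRANE
    if category is Category.MITOCHONDRIAL_PROTEIN:
        return Compartment.MITOCHONDRION
    if role is Role.TRANSCRIPTION_FACTOR:
        return Compartment.NUCLEUS
    return Compartment.CYTOPLASM


class PathwayGraph:
    """Typed undirected pathway graph backed by :class:`networkx.Graph`."""

    def __init__(self, g: Optional[nx.Graph] = None) -> None:
        self.g = g if g is not None else nx.Graph()

    # -- accessors ----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.g.nodes)

    def node(self, symbol: str) -> PathwayNode:
        d = self.g.nodes[symbol]
        return PathwayNode(symbol, Role(d["role"]), Compartment(d["compartment"]))

    def role(self, symbol: str) -> Role:
        return Role(self.g.nodes[symbol]["role"])

    def layer(self, symbol: str) -> Optional[int]:
        return self.g.nodes[symbol].get("layer")

    @property
    def layers(self) -> dict[str, Optional[int]]:
        return {n: self.g.nodes[n].get("layer") for n in self.g.nodes}

    def edges(self) -> list[tuple[str, str, Provenance, float]]:
        return [
            (a, b, Provenance(d["provenance"]), float(d["score"]))
            for a, b, d in self.g.edges(data=True)
        ]

    def provenance_counts(self) -> dict[str, int]:
        counts = {p.value: 0 for p in Provenance}
        for _, _, d in self.g.edges(data=True):
            counts[d["provenance"]] += 1
        return counts

    def receptors(self) -> list[str]:
        return [n for n in self.g.nodes if self.g.nodes[n]["role"] == Role.RECEPTOR.value]

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(self.g.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return (
            dict(self.g.nodes(data=True)) == dict(other.g.nodes(data=True))
            and nx.utils.graphs_equal(self.g, other.g)
        )


def build_graph(
    nodes: Sequence[PathwayNode],
    database_edges: Iterable[tuple[str, str] | tuple[str, str, float]] = (),
    predicted_edges: Iterable[tuple[str, str] | tuple[str, str, float]] = (),
) -> PathwayGraph:
    """Assemble the pathway graph from typed nodes and provenance-tagged edges.

    A pair present in both lists keeps ``database`` provenance (predictions
    are novel by construction; duplicates are defensively deduplicated).
    """
    g = nx.Graph()
    for node in nodes:
        g.add_node(
            node.symbol, role=node.role.value, compartment=node.compartment.value
        )
    known = set(g.nodes)

    def _add(edges, provenance: Provenance, overwrite: bool) -> None:
        offenders = []
        for edge in edges:
            a, b = edge[0], edge[1]
            score = float(edge[2]) if len(edge) > 2 else 1.0
            if a not in known or b not in known:
                offenders.extend(x for x in (a, b) if x not in known)
                continue
            if g.has_edge(a, b) and not overwrite:
                continue
            g.add_edge(a, b, provenance=provenance.value, score=score)
        if offenders:
            raise GraphValidationError(
                f"edges reference unknown nodes: {sorted(set(offenders))}"
            )

    _add(database_edges, Provenance.DATABASE, overwrite=True)
    _add(predicted_edges, Provenance.PREDICTED, overwrite=False)
    return PathwayGraph(g)


def orient_from_receptors(pg: PathwayGraph) -> PathwayGraph:
    """Assign signaling layers by multi-source BFS from the cell-death receptors.

    layer = minimum hop count from any receptor node; ligands get the
    sentinel -1 and do not relay; unreachable nodes keep layer ``None``.
    Idempotent.
    """
    receptors = pg.receptors()
    if not receptors:
        raise GraphValidationError(
            "graph has no receptor nodes; annotate node roles before orienting"
        )
    out = pg.copy()
    ligands = {n for n in out.g.nodes if out.g.nodes[n]["role"] == Role.LIGAND.value}
    traversal = out.g.subgraph(n for n in out.g.nodes if n not in ligands)
    dist = nx.multi_source_dijkstra_path_length(traversal, receptors, weight=None)
    for n in out.g.nodes:
        if n in ligands:
            out.g.nodes[n]["layer"] = LIGAND_LAYER
        elif n in dist:
            out.g.nodes[n]["layer"] = int(dist[n])
        else:
            out.g.nodes[n]["layer"] = None
    return out


# ---------------------------------------------------------------------------
# Export / import


def _graph_to_dict(pg: PathwayGraph) -> dict:
    return {
        "nodes": [
            {
                "symbol": n,
                "role": d["role"],
                "compartment": d["compartment"],
                **({"layer": d["layer"]} if "layer" in d else {}),
                **({"status": d["status"]} if "status" in d else {}),
            }
            for n, d in sorted(pg.g.nodes(data=True))
        ],
        "edges": [
            {"a": min(a, b), "b": max(a, b), "provenance": d["provenance"],
             "score": d["score"]}
            for a, b, d in sorted(
                pg.g.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))
            )
        ],
    }


def export_graph(pg: PathwayGraph, path: str | Path, fmt: str = "json") -> Path:
    """Write the graph as canonical JSON, SIF or GraphML.

    SIF uses the provenance tag as the interaction type; JSON round-trips
    exactly through :func:`import_graph_json`.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(_graph_to_dict(pg), indent=1) + "\n")
    elif fmt == "sif":
        lines = [
            f"{min(a, b)}\t{d['provenance']}\t{max(a, b)}"
            for a, b, d in sorted(
                pg.g.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))
            )
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = nx.Graph()
        for n, d in pg.g.nodes(data=True):
            attrs = {k: v for k, v in d.items() if v is not None}
            if "layer" in d and d["layer"] is None:
                attrs["layer"] = "unreachable"
            g.add_node(n, **{k: str(v) if k == "layer" else v for k, v in attrs.items()})
        for a, b, d in pg.g.edges(data=True):
            g.add_edge(a, b, **d)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format: {fmt!r} (use json, sif or graphml)")
    return path


def import_graph_json(path: str | Path) -> PathwayGraph:
    data = json.loads(Path(path).read_text())
    g = nx.Graph()
    for nd in data["nodes"]:
        attrs = dict(role=nd["role"], compartment=nd["compartment"])
        if "layer" in nd:
            attrs["layer"] = nd["layer"]
        if "status" in nd:
            attrs["status"] = nd["status"]
        g.add_node(nd["symbol"], **attrs)
    for ed in data["edges"]:
        g.add_edge(ed["a"], ed["b"], provenance=ed["provenance"], score=ed["score"])
    return PathwayGraph(g)
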