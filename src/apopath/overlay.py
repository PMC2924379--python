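"""Overlay differential-expression calls on the pathway map and locate foci.

Each pathway node gets a dysregulation status: ``up``/``down`` for called
genes, ``unchanged`` for panel genes that were tested but not called, and
``untested`` for nodes outside the panel.  "Foci of dysregulation" are
formalized as functional-category enrichment: for every panel category the
hypergeometric tail probability of drawing at least the observed number of
dysregulated genes, with Benjamini-Hochberg adjustment across categories.
The enrichment universe is deliberately panel-conditional (panel genes
present in the graph), not genome-wide.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .diffexpr import Direction, GeneCall
from .panel import Category, GenePanel
from .pathway import PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "Status",
    "AnnotatedGraph",
    "FocusReport",
    "overlay",
    "focus_enrichment",
]


class Status(str, Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"
    UNTESTED = "untested"


@dataclass
class AnnotatedGraph:
    graph: PathwayGraph
    status: dict[str, Status]
    categories: dict[str, Category]
    spillover: list[str] = field(default_factory=list)

    def status_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in Status}
        for s in self.status.values():
            counts[s.value] += 1
        return counts

    def dysregulated(self) -> list[str]:
        return [n for n, s in self.status.items() if s in (Status.UP, Status.DOWN)]


@dataclass(frozen=True)
class FocusRow:
    category: Category
    n_genes: int
    n_dysregulated: int
    p_value: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 and 0 <= self.adjusted_p <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.n_dysregulated > self.n_genes:
            raise ValueError("dysregulated count exceeds category size")


@dataclass
class FocusReport:
    rows: list[FocusRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [r.category.value for r in self.rows],
                "n_genes": [r.n_genes for r in self.rows],
                "n_dysregulated": [r.n_dysregulated for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "adjusted_p": [r.adjusted_p for r in self.rows],
            }
        )

    def write(self, path: str | Path, fmt: str = "tsv") -> None:
        path = Path(path)
        if fmt == "tsv":
            self.to_frame().to_csv(path, sep="\t", index=False)
        elif fmt == "json":
            path.write_text(
                json.dumps(self.to_frame().to_dict(orient="records"), indent=1) + "\n"
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")


def overlay(
    g: PathwayGraph, calls: Sequence[GeneCall], panel: GenePanel
) -> AnnotatedGraph:
    """Color pathway nodes by differential-expression status.

    Calls for symbols absent from the graph are collected in a spillover list
    (with a warning) rather than dropped silently.
    """
    panel_symbols = set(panel.symbols)
    call_status = {
        c.symbol: Status.UP if c.direction is Direction.UP else Status.DOWN
        for c in calls
        if c.direction in (Direction.UP, Direction.DOWN)
    }
    graph_nodes = set(g.nodes)
    spillover = sorted(set(call_status) - graph_nodes)
    if spillover:
        logger.warning("calls for %d symbols absent from the graph: %s",
                       len(spillover), spillover)
    status: dict[str, Status] = {}
    for n in g.nodes:
        if n in call_status:
            status[n] = call_status[n]
        elif n in panel_symbols:
            status[n] = Status.UNCHANGED
        else:
            status[n] = Status.UNTESTED
    annotated = g.copy()
    for n, s in status.items():
        annotated.g.nodes[n]["status"] = s.value
    return AnnotatedGraph(
        graph=annotated,
        status=status,
        categories={s: c for s, c in panel.category_map().items() if s in graph_nodes},
        spillover=spillover,
    )


def focus_enrichment(
    a: AnnotatedGraph, direction: Optional[Status] = None
) -> FocusReport:
    """Per-category hypergeometric enrichment of dysregulated panel genes.

    Universe = panel genes present in the graph.  By default "dysregulated"
    is direction-agnostic (up or down); pass ``direction=Status.UP`` or
    ``Status.DOWN`` for a stratified report.  Rows are sorted by adjusted p
    (ties by category name).
    """
    universe = [n for n in a.status if n in a.categories]
    if direction is None:
        dys = {n for n in universe if a.status[n] in (Status.UP, Status.DOWN)}
    else:
        dys = {n for n in universe if a.status[n] is direction}
    by_cat: dict[Category, list[str]] = {}
    for n in universe:
        by_cat.setdefault(a.categories[n], []).append(n)
    if len([c for c, genes in by_cat.items() if genes]) < 2:
        raise ValueError("enrichment needs at least two non-empty categories")

    N, D = len(universe), len(dys)
    cats = sorted(by_cat, key=lambda c: c.value)
    pvals = []
    for cat in cats:
        n_cat = len(by_cat[cat])
        k = sum(1 for g in by_cat[cat] if g in dys)
        # P(X >= k) for X ~ Hypergeom(N, D, n_cat)
        p = float(hypergeom.sf(k - 1, N, D, n_cat)) if D > 0 else 1.0
        pvals.append(min(1.0, p))
    adjusted = [min(1.0, float(x)) for x in false_discovery_control(pvals, method="bh")]
    rows = [
        FocusRow(
            category=cat,
            n_genes=len(by_cat[cat]),
            n_dysregulated=sum(1 for g in by_cat[cat] if g in dys),
            p_value=p,
            adjusted_p=ap,
        )
        for cat, p, ap in zip(cats, pvals, adjusted)
    ]
    rows.sort(key=lambda r: (r.adjusted_p, r.category.value))
    return FocusReport(rows=rows)
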