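"""Curated apoptosis gene panel: loading, validation and the GeneChip result fixture.

The panel is the backbone of the whole analysis: a curated set of apoptosis
pathway genes with functional categories (receptor, decoy receptor, ligand,
protease, IAP, mitochondrial protein, ...) and Affymetrix probeset mappings
used to cut a "virtual subarray" out of a whole-genome expression matrix.

A packaged fixture carries the published GeneChip result table (19
differentially expressed genes with their linear-scale fold changes) that
anchors the regression tests of the differential-expression call rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "GeneRecord",
    "GenePanel",
    "Table1Row",
    "Table1Fixture",
    "MappedCounts",
    "PanelFormatError",
    "PanelValidationError",
    "load_gene_panel",
    "write_gene_panel",
    "count_mapped_genes",
    "load_table1_fixture",
    "packaged_panel_path",
]


class Category(str, Enum):
    """Functional category of a panel gene.

    Vocabulary fixed from the GeneChip result table's "Function" column plus
    the receptor/ligand/transcription-factor roles of the pathway-map legend.
    Unrecognised labels degrade to ``other`` rather than failing.
    """

    CELL_DEATH_RECEPTOR = "cell_death_receptor"
    DECOY_RECEPTOR = "decoy_receptor"
    LIGAND = "ligand"
    SIGNAL_MOLECULE = "signal_molecule"
    PROTEASE = "protease"
    APOPTOSIS_INHIBITOR = "apoptosis_inhibitor"
    MITOCHONDRIAL_PROTEIN = "mitochondrial_protein"
    TRANSCRIPTION_FACTOR = "transcription_factor"
    OTHER = "other"


class PanelFormatError(ValueError):
    """The panel file is structurally malformed (e.g. missing columns)."""


class PanelValidationError(ValueError):
    """The panel file parses but violates an invariant (e.g. duplicate symbol)."""


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    name: str
    category: Category
    probesets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelValidationError("gene symbol must be non-empty")


@dataclass
class GenePanel:
    """A curated gene set; symbols are unique within a panel."""

    records: list[GeneRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise PanelValidationError("panel must contain at least one gene")
        seen: set[str] = set()
        for rec in self.records:
            if rec.symbol in seen:
                raise PanelValidationError(f"duplicate gene symbol: {rec.symbol}")
            seen.add(rec.symbol)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, symbol: str) -> GeneRecord:
        for rec in self.records:
            if rec.symbol == symbol:
                return rec
        raise KeyError(symbol)

    @property
    def symbols(self) -> list[str]:
        return [r.symbol for r in self.records]

    def probeset_to_gene(self) -> dict[str, str]:
        """Map probeset ID -> gene symbol (first claiming gene wins on clashes)."""
        mapping: dict[str, str] = {}
        for rec in self.records:
            for ps in rec.probesets:
                mapping.setdefault(ps, rec.symbol)
        return mapping

    def category_map(self) -> dict[str, Category]:
        return {r.symbol: r.category for r in self.records}


class Table1Row(NamedTuple):
    symbol: str
    probesets: tuple[str, ...]
    fold_change: float
    category: Category
    has_prior_pdac_reference: bool


@dataclass
class Table1Fixture:
    """The published GeneChip result table at printed precision.

    19 genes (11 up-, 8 down-regulated on the tumor/normal linear-scale
    fold-change), 23 probesets, 12 genes with a previously reported role in
    pancreatic ductal adenocarcinoma.
    """

    rows: list[Table1Row]

    def __post_init__(self) -> None:
        if len(self.rows) != 19:
            raise PanelValidationError(
                f"fixture must have exactly 19 rows, got {len(self.rows)}"
            )
        if any(r.fold_change <= 0 for r in self.rows):
            raise PanelValidationError("fold changes must be positive")

    def fold_changes(self) -> dict[str, float]:
        return {r.symbol: r.fold_change for r in self.rows}

    def probeset_fold_changes(self) -> dict[str, float]:
        """Per-probeset fold changes (all probesets of a gene share its FC)."""
        out: dict[str, float] = {}
        for r in self.rows:
            for ps in r.probesets:
                out[ps] = r.fold_change
        return out


class MappedCounts(NamedTuple):
    n_mapped: int
    n_unmapped: int
    n_probesets: int


_PANEL_COLUMNS = ("symbol", "name", "category", "probesets")


def _parse_category(raw: str) -> Category:
    try:
        return Category(raw.strip())
    except ValueError:
        logger.warning("unknown category %r mapped to 'other'", raw)
        return Category.OTHER


def _split_probesets(raw: object) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ()
    text = str(raw).strip()
    if not text:
        return ()
    return tuple(p.strip() for p in text.split(",") if p.strip())


def load_gene_panel(path: str | Path) -> GenePanel:
    """Read a tab-separated gene panel (columns symbol/name/category/probesets).

    ``#`` comment lines are ignored; the ``probesets`` column is comma-joined
    and may be empty for genes without an array identifier.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if "symbol" not in df.columns:
        raise PanelFormatError(f"{path}: missing required column 'symbol'")
    for col in _PANEL_COLUMNS[1:]:
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing required column '{col}'")
    records = [
        GeneRecord(
            symbol=row["symbol"].strip(),
            name=row["name"].strip(),
            category=_parse_category(row["category"]),
            probesets=_split_probesets(row["probesets"]),
        )
        for _, row in df.iterrows()
    ]
    return GenePanel(records=records, provenance=str(path))


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel back to the tab-separated interchange format."""
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in panel.records],
            "name": [r.name for r in panel.records],
            "category": [r.category.value for r in panel.records],
            "probesets": [",".join(r.probesets) for r in panel.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def count_mapped_genes(panel: GenePanel) -> MappedCounts:
    """Panel accounting: genes with/without probesets and distinct probeset IDs."""
    n_mapped = sum(1 for r in panel.records if r.probesets)
    n_unmapped = len(panel.records) - n_mapped
    distinct: set[str] = set()
    for r in panel.records:
        distinct.update(r.probesets)
    return MappedCounts(n_mapped=n_mapped, n_unmapped=n_unmapped, n_probesets=len(distinct))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("apopath").joinpath("data", name)))


def packaged_panel_path() -> Path:
    """Path of the packaged 103-gene apoptosis panel."""
    return _data_path("panel_apoptosis_103.tsv")


def load_packaged_panel() -> GenePanel:
    return load_gene_panel(packaged_panel_path())


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged GeneChip result table (19 genes, printed precision)."""
    df = pd.read_csv(
        _data_path("table1_genechip.tsv"),
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
    )
    rows = [
        Table1Row(
            symbol=row["symbol"],
            probesets=_split_probesets(row["probesets"]),
            fold_change=float(row["fold_change"]),
            category=_parse_category(row["category"]),
            has_prior_pdac_reference=row["has_prior_pdac_reference"].lower()
            in ("1", "true", "yes"),
        )
        for _, row in df.iterrows()
    ]
    return Table1Fixture(rows=rows)
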