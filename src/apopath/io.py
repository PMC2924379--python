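"""File-format readers and writers binding the pipeline stages together.

Formats are deliberately plain text: FASTA for protein sequences, PDB ATOM
records (one CA per residue) or a minimal JSON coordinate dialect for toy
domain structures, JSON for interface templates, tab-separated tables for
expression matrices, group labels, interaction pairs and predictions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import Direction, ExpressionMatrix, GeneCall, ProbesetResult
from .interolog import (
    Confidence,
    DomainAssignment,
    DomainStructure,
    InterfaceTemplate,
    PredictedInteraction,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_structures_pdb",
    "write_structures_pdb",
    "read_structures_json",
    "write_structures_json",
    "read_templates",
    "write_templates",
    "read_pairs",
    "write_pairs",
    "write_predictions",
    "read_predictions",
    "read_expression",
    "write_expression",
]


# -- sequences ---------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {record id (gene symbol): sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=symbol, description="") for symbol, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- structures --------------------------------------------------------------

_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  ALA {chain}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
)


def write_structures_pdb(structures: Sequence[DomainStructure], path: str | Path) -> None:
    """Write toy domains as PDB ATOM records, one CA per residue, chain per domain."""
    if len(structures) > 62:
        raise ValueError("too many domains for single-character PDB chain IDs")
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    serial = 1
    with open(path, "w") as fh:
        for chain, s in zip(chains, structures):
            fh.write(f"REMARK   domain {s.domain_id} chain {chain}\n")
            for idx, xyz in zip(s.residue_indices, s.coords):
                fh.write(
                    _ATOM_FMT.format(
                        serial=serial, chain=chain, resseq=idx,
                        x=xyz[0], y=xyz[1], z=xyz[2],
                    )
                )
                serial += 1
        fh.write("END\n")


def read_structures_pdb(path: str | Path) -> list[DomainStructure]:
    """Read CA-only PDB domains (one domain per chain).

    Domain IDs are taken from the package's own REMARK lines when present,
    otherwise the chain ID is used.
    """
    names: dict[str, str] = {}
    per_chain: dict[str, list[tuple[int, tuple[float, float, float]]]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK   domain "):
            parts = line.split()
            names[parts[4]] = parts[2]
        elif line.startswith("ATOM") and line[12:16].strip() == "CA":
            chain = line[21]
            resseq = int(line[22:26])
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            if chain not in per_chain:
                per_chain[chain] = []
                order.append(chain)
            per_chain[chain].append((resseq, xyz))
    out = []
    for chain in order:
        entries = sorted(per_chain[chain])
        out.append(
            DomainStructure(
                domain_id=names.get(chain, chain),
                residue_indices=tuple(i for i, _ in entries),
                coords=np.array([xyz for _, xyz in entries]),
            )
        )
    return out


def write_structures_json(structures: Sequence[DomainStructure], path: str | Path) -> None:
    data = [
        {
            "domain_id": s.domain_id,
            "residues": [
                [int(i), float(x), float(y), float(z)]
                for i, (x, y, z) in zip(s.residue_indices, s.coords)
            ],
        }
        for s in structures
    ]
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_structures_json(path: str | Path) -> list[DomainStructure]:
    data = json.loads(Path(path).read_text())
    return [
        DomainStructure(
            domain_id=entry["domain_id"],
            residue_indices=tuple(int(r[0]) for r in entry["residues"]),
            coords=np.array([[r[1], r[2], r[3]] for r in entry["residues"]]),
        )
        for entry in data
    ]


# -- templates ---------------------------------------------------------------


def write_templates(templates: Sequence[InterfaceTemplate], path: str | Path) -> None:
    data = [
        {
            "family_a": t.family_a,
            "family_b": t.family_b,
            "seq_a": t.seq_a,
            "seq_b": t.seq_b,
            "interface_a": sorted(t.interface_a),
            "interface_b": sorted(t.interface_b),
            "template_id": t.template_id,
        }
        for t in templates
    ]
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_templates(path: str | Path) -> list[InterfaceTemplate]:
    data = json.loads(Path(path).read_text())
    return [
        InterfaceTemplate(
            family_a=t["family_a"],
            family_b=t["family_b"],
            seq_a=t["seq_a"],
            seq_b=t["seq_b"],
            interface_a=frozenset(t["interface_a"]),
            interface_b=frozenset(t["interface_b"]),
            template_id=t.get("template_id", ""),
        )
        for t in data
    ]


# -- interaction pairs -------------------------------------------------------


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """2-column tab-separated symbol pairs (``#`` comments ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        out.append((a, b))
    return out


def write_pairs(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text("".join(f"{a}\t{b}\n" for a, b in pairs))


def write_predictions(
    predictions: Sequence[PredictedInteraction], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "protein_a": [p.protein_a for p in predictions],
            "protein_b": [p.protein_b for p in predictions],
            "method": [p.method.value for p in predictions],
            "score": [p.score for p in predictions],
            "novel": [p.novel for p in predictions],
            "template_or_source": [p.template_or_source for p in predictions],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[PredictedInteraction]:
    from .interolog import Method

    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    return [
        PredictedInteraction(
            protein_a=row["protein_a"],
            protein_b=row["protein_b"],
            method=Method(row["method"]),
            score=float(row["score"]),
            novel=bool(row["novel"]),
            template_or_source=str(row["template_or_source"]),
        )
        for _, row in df.iterrows()
    ]


# -- expression --------------------------------------------------------------


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Tab-separated matrix (first column probeset ID) + 2-column group file."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "group"], comment="#"
    )
    groups = pd.Series(groups_df["group"].values, index=groups_df["sample"].values)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="probeset_id")
    with open(groups_path, "w") as fh:
        for sample in m.values.columns:
            fh.write(f"{sample}\t{m.groups[sample].value}\n")


def read_assignments(path: str | Path) -> list[DomainAssignment]:
    """3-column tab-separated protein / family / confidence table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        DomainAssignment(
            protein=row["protein"], family=row["family"],
            confidence=Confidence(row["confidence"]),
        )
        for _, row in df.iterrows()
    ]


def write_assignments(assignments: Sequence[DomainAssignment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein": [a.protein for a in assignments],
            "family": [a.family for a in assignments],
            "confidence": [a.confidence.value for a in assignments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_known_seq_interactions(path: str | Path) -> list[tuple[str, str, str]]:
    """Reference interacting sequence pairs: seq_x / seq_y / source columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        (row["seq_x"], row["seq_y"], row["source"]) for _, row in df.iterrows()
    ]


def write_known_seq_interactions(
    interactions: Sequence[tuple[str, str, str]], path: str | Path
) -> None:
    pd.DataFrame(interactions, columns=["seq_x", "seq_y", "source"]).to_csv(
        path, sep="\t", index=False
    )


def write_gene_calls(calls: Sequence[GeneCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "symbol": [c.symbol for c in calls],
            "direction": [c.direction.value for c in calls],
            "supporting_probesets": [",".join(c.supporting_probesets) for c in calls],
            "conflict": [c.conflict for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_calls(path: str | Path) -> list[GeneCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        GeneCall(
            symbol=row["symbol"],
            direction=Direction(row["direction"]),
            supporting_probesets=tuple(
                p for p in row["supporting_probesets"].split(",") if p
            ),
            conflict=row["conflict"].lower() in ("1", "true", "yes"),
        )
        for _, row in df.iterrows()
    ]


def write_probeset_results(
    results: Mapping[str, ProbesetResult], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "probeset_id": list(results),
            "fold_change": [r.fold_change for r in results.values()],
            "d_score": [r.d_score for r in results.values()],
            "q_value": [r.q_value for r in results.values()],
            "called": [r.called for r in results.values()],
            "direction": [r.direction.value for r in results.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)
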