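"""Interolog protein-interaction prediction.

Two proteins are predicted to interact when homology transfers an observed
interaction onto them:

* **structure route** — both proteins carry domains assigned to a SCOP-like
  family pair for which a solved complex provides an interface template.  A
  domain-domain interface is defined geometrically (at least 5 residue pairs
  within 5 Angstrom, one representative point per residue).  The query
  sequence is globally aligned to each template side and the prediction is
  accepted only if strictly more than 30% of the template's interface
  residues are conserved on *both* sides.

* **sequence route** — a known interacting pair (X, Y) transfers to a
  candidate pair (P, Q) when P is a close homolog of X and Q of Y (strictly
  more than 80% global sequence identity on both sides, either orientation).

Predictions already present in the reference interaction set are filtered
out, leaving only novel edges.

Thresholds follow the published wording literally: the contact-distance and
contact-count gates are inclusive ("at least 5 residue pairs within 5 A"),
the conservation and identity gates strict ("more than 30%", ">80%").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "Confidence",
    "Method",
    "DomainStructure",
    "DomainAssignment",
    "InterfaceTemplate",
    "PredictedInteraction",
    "PredictionConfig",
    "residue_contacts",
    "extract_interface",
    "global_align",
    "global_identity",
    "interface_conservation",
    "predict_structural",
    "predict_sequence",
    "filter_novel",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"
GAP = "-"


class Confidence(str, Enum):
    """Fold-recognition confidence of a domain-family assignment."""

    CERTAIN = "certain"
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


class Method(str, Enum):
    STRUCTURE = "structure"
    SEQUENCE = "sequence"
    DATABASE = "database"


@dataclass(frozen=True)
class DomainStructure:
    """A domain reduced to one representative (C-alpha-like) point per residue."""

    domain_id: str
    residue_indices: tuple[int, ...]
    coords: np.ndarray  # (n_residues, 3) in Angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.residue_indices) != coords.shape[0]:
            raise ValueError("residue index / coordinate length mismatch")
        idx = self.residue_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_indices)


@dataclass(frozen=True)
class DomainAssignment:
    protein: str
    family: str
    confidence: Confidence = Confidence.CERTAIN


@dataclass(frozen=True)
class InterfaceTemplate:
    """A family-pair interface: template sequences plus 1-based interface positions."""

    family_a: str
    family_b: str
    seq_a: str
    seq_b: str
    interface_a: frozenset[int]
    interface_b: frozenset[int]
    template_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "interface_a", frozenset(self.interface_a))
        object.__setattr__(self, "interface_b", frozenset(self.interface_b))
        if not self.interface_a or not self.interface_b:
            raise ValueError("both interfaces must be non-empty")
        for iface, seq, side in (
            (self.interface_a, self.seq_a, "a"),
            (self.interface_b, self.seq_b, "b"),
        ):
            if any(p < 1 or p > len(seq) for p in iface):
                raise ValueError(f"interface_{side} positions out of sequence bounds")
        if not self.template_id:
            object.__setattr__(self, "template_id", f"{self.family_a}:{self.family_b}")


@dataclass(frozen=True)
class PredictedInteraction:
    protein_a: str
    protein_b: str
    method: Method
    score: float
    template_or_source: str = ""
    novel: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def pair(self) -> frozenset[str]:
        """Unordered pair identity: (a, b) and (b, a) are the same interaction."""
        return frozenset((self.protein_a, self.protein_b))


@dataclass(frozen=True)
class PredictionConfig:
    contact_cutoff: float = 5.0       # Angstrom, inclusive
    min_contact_pairs: int = 5        # inclusive ("at least 5")
    conservation_threshold: float = 0.30  # strict ("more than 30%")
    identity_threshold: float = 0.80      # strict (">80%")
    allowed_confidences: frozenset[Confidence] = frozenset(
        (Confidence.CERTAIN, Confidence.HIGH)
    )

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.min_contact_pairs <= 0:
            raise ValueError("contact cutoff and minimum pair count must be positive")
        if not (0 < self.conservation_threshold <= 1 and 0 < self.identity_threshold <= 1):
            raise ValueError("thresholds must be fractions in (0, 1]")
        object.__setattr__(
            self, "allowed_confidences", frozenset(self.allowed_confidences)
        )


# ---------------------------------------------------------------------------
# Geometry


def residue_contacts(
    a: DomainStructure, b: DomainStructure, cutoff: float = 5.0
) -> list[tuple[int, int, float]]:
    """All inter-domain residue pairs within ``cutoff`` Angstrom (inclusive).

    Returns (residue_index_in_a, residue_index_in_b, distance) triples, sorted
    by (index_a, index_b).  Empty structures yield an empty list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(a) == 0 or len(b) == 0:
        return []
    dist = cdist(a.coords, b.coords)
    ii, jj = np.nonzero(dist <= cutoff)
    return [
        (a.residue_indices[i], b.residue_indices[j], float(dist[i, j]))
        for i, j in zip(ii.tolist(), jj.tolist())
    ]


def extract_interface(
    a: DomainStructure, b: DomainStructure, cfg: PredictionConfig = PredictionConfig()
) -> Optional[tuple[frozenset[int], frozenset[int]]]:
    """Interface residue sets of a domain pair, or ``None`` below the contact gate.

    The pair qualifies as interacting iff it has at least ``min_contact_pairs``
    residue pairs within ``contact_cutoff``; the interface on each side is the
    set of distinct residues participating in any such contact.
    """
    contacts = residue_contacts(a, b, cfg.contact_cutoff)
    if len(contacts) < cfg.min_contact_pairs:
        return None
    return (
        frozenset(i for i, _, _ in contacts),
        frozenset(j for _, j, _ in contacts),
    )


# ---------------------------------------------------------------------------
# Alignment

# Needleman-Wunsch with the package's fixed scoring (match +1, mismatch 0,
# linear gap -1) and a deterministic traceback preferring
# diagonal-match > diagonal-mismatch > gap-in-second > gap-in-first.
# The tie-break is part of the contract (it fixes which co-optimal alignment
# the identity and conservation fractions are measured on), which is why the
# DP is written out rather than delegated to a generic aligner.

MATCH, MISMATCH, GAP_PENALTY = 1, 0, -1


def _validate_seq(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence must be non-empty")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"{label} sequence has non-amino-acid symbols: {sorted(bad)}")


def global_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment of two sequences; returns the two gapped strings."""
    _validate_seq(seq_a, "first")
    _validate_seq(seq_b, "second")
    n, m = len(seq_a), len(seq_b)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    score[0, :] = np.arange(m + 1) * GAP_PENALTY
    score[:, 0] = np.arange(n + 1) * GAP_PENALTY
    a_arr = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b_arr = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    sub = np.where(a_arr[:, None] == b_arr[None, :], MATCH, MISMATCH)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP_PENALTY
        row = score[i]
        prev = row[0]
        drow = diag
        urow = up
        for j in range(1, m + 1):
            best = drow[j - 1]
            if urow[j - 1] > best:
                best = urow[j - 1]
            left = prev + GAP_PENALTY
            if left > best:
                best = left
            row[j] = best
            prev = best
    # traceback with the stated preference order
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i - 1, j - 1] + sub[i - 1, j - 1] == score[i, j]:
            # diagonal preferred (match and mismatch alike beat opening a gap)
            out_a.append(seq_a[i - 1]); out_b.append(seq_b[j - 1])
            i -= 1; j -= 1
            continue
        if i > 0 and score[i - 1, j] + GAP_PENALTY == score[i, j]:
            out_a.append(seq_a[i - 1]); out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP); out_b.append(seq_b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical positions over the global-alignment length."""
    aln_a, aln_b = global_align(seq_a, seq_b)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != GAP)
    return matches / len(aln_a)


def interface_conservation(
    query_seq: str, template_seq: str, template_interface: Iterable[int]
) -> float:
    """Fraction of template interface residues conserved in the aligned query.

    The query is globally aligned to the template; a template interface
    position counts as conserved iff the aligned query residue is identical.
    Positions aligned to a gap count as non-conserved.
    """
    interface = set(template_interface)
    if not interface:
        raise ValueError("template interface must be non-empty")
    if any(p < 1 or p > len(template_seq) for p in interface):
        raise ValueError("interface positions out of template bounds")
    aln_q, aln_t = global_align(query_seq, template_seq)
    conserved = 0
    t_pos = 0
    for q_char, t_char in zip(aln_q, aln_t):
        if t_char == GAP:
            continue
        t_pos += 1
        if t_pos in interface and q_char == t_char:
            conserved += 1
    return conserved / len(interface)


# ---------------------------------------------------------------------------
# Prediction routes


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def predict_structural(
    assignments: Sequence[DomainAssignment],
    templates: Sequence[InterfaceTemplate],
    sequences: Mapping[str, str],
    cfg: PredictionConfig = PredictionConfig(),
) -> list[PredictedInteraction]:
    """Structure-route interolog transfer.

    A pair (P, Q) is emitted iff some template's family pair matches domain
    families assigned to P and Q (at an allowed confidence) and the interface
    conservation of the query against the template sequence strictly exceeds
    the conservation threshold on *both* sides.  Score = min of the two
    conservation fractions; the best-scoring template is retained per
    unordered pair, ties broken by smallest template id.  Self-pairs are
    allowed only for self-paired families (homodimer templates).
    """
    usable = [a for a in assignments if a.confidence in cfg.allowed_confidences]
    for a in usable:
        if a.protein not in sequences:
            raise KeyError(f"no sequence for assigned protein {a.protein}")
    by_family: dict[str, list[str]] = {}
    for a in usable:
        by_family.setdefault(a.family, []).append(a.protein)
    known_families = set(by_family)

    cons_cache: dict[tuple[str, int, int], float] = {}

    def conservation(protein: str, tmpl: InterfaceTemplate, side: str) -> float:
        seq, iface = (
            (tmpl.seq_a, tmpl.interface_a) if side == "a" else (tmpl.seq_b, tmpl.interface_b)
        )
        key = (protein, id(tmpl), 0 if side == "a" else 1)
        if key not in cons_cache:
            cons_cache[key] = interface_conservation(sequences[protein], seq, iface)
        return cons_cache[key]

    best: dict[tuple[str, str], tuple[float, str]] = {}
    for tmpl in templates:
        if tmpl.family_a not in known_families or tmpl.family_b not in known_families:
            logger.warning(
                "template %s references unassigned family; skipped", tmpl.template_id
            )
            continue
        for p in by_family[tmpl.family_a]:
            for q in by_family[tmpl.family_b]:
                if p == q and tmpl.family_a != tmpl.family_b:
                    continue
                c_a = conservation(p, tmpl, "a")
                if c_a <= cfg.conservation_threshold:
                    continue
                c_b = conservation(q, tmpl, "b")
                if c_b <= cfg.conservation_threshold:
                    continue
                score = min(c_a, c_b)
                key = _pair_key(p, q)
                cur = best.get(key)
                if (
                    cur is None
                    or score > cur[0]
                    or (score == cur[0] and tmpl.template_id < cur[1])
                ):
                    best[key] = (score, tmpl.template_id)
    return [
        PredictedInteraction(
            protein_a=a, protein_b=b, method=Method.STRUCTURE, score=score,
            template_or_source=tid,
        )
        for (a, b), (score, tid) in sorted(best.items())
    ]


def predict_sequence(
    candidate_pairs: Sequence[tuple[str, str]],
    known_interactions: Sequence[tuple[str, str, str]],
    sequences: Mapping[str, str],
    cfg: PredictionConfig = PredictionConfig(),
) -> list[PredictedInteraction]:
    """Sequence-route interolog transfer over supplied candidate pairs.

    ``known_interactions`` are (seq_x, seq_y, source_id) triples of reference
    interacting sequences.  A candidate (P, Q) is emitted iff for some known
    pair both sides exceed the identity threshold strictly, in either
    orientation; score = min of the two identities, best source retained.
    """
    for p, q in candidate_pairs:
        if p not in sequences or q not in sequences:
            missing = p if p not in sequences else q
            raise KeyError(f"no sequence for candidate protein {missing}")

    ident_cache: dict[tuple[str, int, int], float] = {}

    def identity(protein: str, known_idx: int, side: int) -> float:
        key = (protein, known_idx, side)
        if key not in ident_cache:
            ref = known_interactions[known_idx][side]
            ident_cache[key] = global_identity(sequences[protein], ref)
        return ident_cache[key]

    out: list[PredictedInteraction] = []
    seen: set[tuple[str, str]] = set()
    for p, q in candidate_pairs:
        key = _pair_key(p, q)
        if key in seen:
            continue
        best: Optional[tuple[float, str]] = None
        for k, (_, _, source) in enumerate(known_interactions):
            for i_p, i_q in ((identity(p, k, 0), identity(q, k, 1)),
                             (identity(p, k, 1), identity(q, k, 0))):
                if i_p > cfg.identity_threshold and i_q > cfg.identity_threshold:
                    score = min(i_p, i_q)
                    if best is None or score > best[0] or (
                        score == best[0] and source < best[1]
                    ):
                        best = (score, source)
        if best is not None:
            seen.add(key)
            out.append(
                PredictedInteraction(
                    protein_a=key[0], protein_b=key[1], method=Method.SEQUENCE,
                    score=best[0], template_or_source=best[1],
                )
            )
    return out


def filter_novel(
    predicted: Sequence[PredictedInteraction],
    known: Iterable[tuple[str, str] | frozenset[str]],
) -> list[PredictedInteraction]:
    """Keep only predictions absent from the known-interaction set (order stable).

    Matching is on unordered pairs; kept interactions are returned with
    ``novel=True``.
    """
    known_pairs = {frozenset(p) for p in known}
    out = []
    for pred in predicted:
        if pred.pair not in known_pairs:
            out.append(
                PredictedInteraction(
                    protein_a=pred.protein_a, protein_b=pred.protein_b,
                    method=pred.method, score=pred.score,
                    template_or_source=pred.template_or_source, novel=True,
                )
            )
    return out
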