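"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of their config (same seed => identical
output):

* :func:`gen_expression` — two-group linear-scale microarray intensities
  (defaults 19 tumor vs 13 normal, the study design) with multiplicative
  log-normal noise and planted fold changes, plus a truth table.
* :func:`gen_interface_pair` — a toy domain pair (one point per residue),
  its interface template, and query sequences whose global identity and
  interface conservation hit requested targets exactly (mutations are placed
  deterministically on or off the interface positions).
* :func:`gen_pathway_inputs` — a connected receptor-rooted pathway graph
  with hand-computed BFS-layer ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix, Group
from .interolog import AMINO_ACIDS, DomainStructure, InterfaceTemplate
from .pathway import Compartment, PathwayNode, Role

__all__ = [
    "ExpressionSimConfig",
    "TemplateSimConfig",
    "ContactGeometry",
    "InterfaceBundle",
    "gen_expression",
    "gen_interface_pair",
    "gen_pathway_inputs",
]


# ---------------------------------------------------------------------------
# Expression


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Two-group microarray simulation; defaults mirror the study design."""

    n_tumor: int = 19
    n_normal: int = 13
    n_probesets: int = 189
    planted: tuple[tuple[str, float], ...] = ()   # (probeset, true linear FC)
    baseline_mean: float = 300.0                  # linear-scale intensity
    baseline_overrides: tuple[tuple[str, float], ...] = ()
    noise_sigma_log2: float = 0.5
    noise_overrides: tuple[tuple[str, float], ...] = ()  # per-probeset sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor <= 0 or self.n_normal <= 0 or self.n_probesets <= 0:
            raise ValueError("counts must be positive")
        if any(fc <= 0 for _, fc in self.planted):
            raise ValueError("planted fold changes must be positive")
        if self.noise_sigma_log2 < 0:
            raise ValueError("noise sigma must be non-negative")


def default_probeset_ids(n: int) -> list[str]:
    return [f"sim{str(i + 1).zfill(5)}_at" for i in range(n)]


def gen_expression(
    cfg: ExpressionSimConfig,
    probeset_ids: Optional[Sequence[str]] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate linear-scale intensities and return (matrix, truth table).

    Normal-group values are log-normal around the baseline mean
    (value = baseline * 2**N(0, sigma_log2)); tumor values are additionally
    multiplied by the planted fold change.  The truth table records the
    planted effect (or 1.0) per probeset.
    """
    ids = list(probeset_ids) if probeset_ids is not None else default_probeset_ids(
        cfg.n_probesets
    )
    if len(ids) != cfg.n_probesets:
        raise ValueError("probeset_ids length must equal n_probesets")
    planted = dict(cfg.planted)
    unknown = set(planted) - set(ids)
    if unknown:
        raise ValueError(f"planted probesets not in the matrix: {sorted(unknown)}")
    baselines = np.full(cfg.n_probesets, float(cfg.baseline_mean))
    overrides = dict(cfg.baseline_overrides)
    for i, ps in enumerate(ids):
        if ps in overrides:
            baselines[i] = float(overrides[ps])
    fcs = np.array([planted.get(ps, 1.0) for ps in ids])
    sigmas = np.full(cfg.n_probesets, float(cfg.noise_sigma_log2))
    noise_ov = dict(cfg.noise_overrides)
    for i, ps in enumerate(ids):
        if ps in noise_ov:
            sigmas[i] = float(noise_ov[ps])

    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_tumor + cfg.n_normal
    noise = rng.normal(0.0, 1.0, size=(cfg.n_probesets, n_samples))
    values = baselines[:, None] * 2.0 ** (sigmas[:, None] * noise)
    values[:, : cfg.n_tumor] *= fcs[:, None]

    samples = [f"tumor_{i + 1}" for i in range(cfg.n_tumor)] + [
        f"normal_{i + 1}" for i in range(cfg.n_normal)
    ]
    groups = pd.Series(
        [Group.TUMOR] * cfg.n_tumor + [Group.NORMAL] * cfg.n_normal, index=samples
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples), groups=groups
    )
    truth = pd.DataFrame(
        {
            "probeset_id": ids,
            "true_fc": fcs,
            "planted": [ps in planted for ps in ids],
            "baseline_mean": baselines,
        }
    ).set_index("probeset_id")
    return matrix, truth


def gen_sensitivity_inputs(
    seed: int,
    n_whole: int = 2000,
    n_panel: int = 100,
    n_strong: int = 8,
    n_weak: int = 16,
    strong_fc: float = 3.0,
    weak_fc: float = 2.8,
    strong_baseline: float = 600.0,
    weak_baseline: float = 60.0,
    baseline: float = 300.0,
    noise_sigma_log2: float = 0.5,
    weak_noise_sigma_log2: float = 1.8,
    n_tumor: int = 19,
    n_normal: int = 13,
):
    """Whole-matrix vs virtual-subarray sensitivity scenario.

    A whole-genome-like matrix whose first ``n_panel`` probesets form the
    curated panel; planted effects sit only inside the panel, split into a
    strong high-intensity tier (detectable by both analyses) and a
    low-intensity tier with the higher multiplicative noise characteristic
    of the bottom of a microarray's dynamic range, whose marginal statistics
    survive the q-value gate only in the subarray's concentrated testing
    pool.  Returns (matrix, panel, truth table).
    """
    from .panel import Category, GenePanel, GeneRecord

    ids = [f"ps{str(i + 1).zfill(5)}_at" for i in range(n_whole)]
    strong = ids[:n_strong]
    weak = ids[n_strong : n_strong + n_weak]
    planted = tuple((ps, strong_fc) for ps in strong) + tuple(
        (ps, weak_fc) for ps in weak
    )
    overrides = tuple((ps, strong_baseline) for ps in strong) + tuple(
        (ps, weak_baseline) for ps in weak
    )
    cfg = ExpressionSimConfig(
        n_tumor=n_tumor, n_normal=n_normal, n_probesets=n_whole,
        planted=planted, baseline_mean=baseline, baseline_overrides=overrides,
        noise_sigma_log2=noise_sigma_log2,
        noise_overrides=tuple((ps, weak_noise_sigma_log2) for ps in weak),
        seed=seed,
    )
    matrix, truth = gen_expression(cfg, probeset_ids=ids)
    panel = GenePanel(
        [
            GeneRecord(f"G{str(i + 1).zfill(4)}", f"panel gene {i + 1}",
                       Category.OTHER, (ids[i],))
            for i in range(n_panel)
        ],
        provenance="sensitivity simulation",
    )
    return matrix, panel, truth


# ---------------------------------------------------------------------------
# Interface / template bundles


class ContactGeometry(str, Enum):
    TOUCHING = "touching"
    SEPARATED = "separated"


@dataclass(frozen=True)
class TemplateSimConfig:
    n_residues: int = 60
    n_interface: int = 10
    contact_geometry: ContactGeometry = ContactGeometry.TOUCHING
    target_identity: float = 0.9
    target_conservation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_interface <= self.n_residues:
            raise ValueError("need 1 <= n_interface <= n_residues")
        if not (0 <= self.target_identity <= 1 and 0 <= self.target_conservation <= 1):
            raise ValueError("targets must be fractions in [0, 1]")


@dataclass
class InterfaceBundle:
    structure_a: DomainStructure
    structure_b: DomainStructure
    template: InterfaceTemplate
    query_a: str
    query_b: str
    truth: dict


_CONTACT_DISTANCE = 4.0   # within the 5 A cutoff
_FAR_OFFSET = 1000.0      # well outside any cutoff


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    # X excluded so every position can be mutated to a distinct standard residue
    alphabet = AMINO_ACIDS[:-1]
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _mutate(seq: str, positions: Sequence[int]) -> str:
    """Substitute each 1-based position with the next amino acid (cyclic)."""
    alphabet = AMINO_ACIDS[:-1]
    chars = list(seq)
    for pos in positions:
        cur = chars[pos - 1]
        chars[pos - 1] = alphabet[(alphabet.index(cur) + 1) % len(alphabet)]
    return "".join(chars)


def _spread(positions: list[int], k: int) -> list[int]:
    """k deterministically chosen, evenly spaced elements of a sorted list."""
    if k == 0:
        return []
    return sorted({positions[i * len(positions) // k] for i in range(k)})


def _plan_mutations(
    length: int, interface: Sequence[int], identity: float, conservation: float
) -> list[int]:
    """Deterministic mutation positions realizing the identity/conservation targets.

    Mutations are spread evenly over the interface and off-interface position
    sets rather than clustered, so the gap-free alignment stays uniquely
    optimal and the realized fractions are hit exactly.
    """
    n_int = len(interface)
    m_total = round((1.0 - identity) * length)
    m_iface = round((1.0 - conservation) * n_int)
    m_off = m_total - m_iface
    n_off = length - n_int
    if m_off < 0:
        raise ValueError(
            f"targets infeasible: conservation {conservation} requires {m_iface} "
            f"interface mutations but identity {identity} allows only {m_total} total"
        )
    if m_off > n_off:
        raise ValueError(
            f"targets infeasible: {m_off} off-interface mutations needed but only "
            f"{n_off} off-interface positions exist"
        )
    iface_sorted = sorted(interface)
    off_sorted = sorted(set(range(1, length + 1)) - set(interface))
    picked_iface = _spread(iface_sorted, m_iface)
    picked_off = _spread(off_sorted, m_off)
    assert len(picked_iface) == m_iface and len(picked_off) == m_off
    return picked_iface + picked_off


def gen_interface_pair(cfg: TemplateSimConfig) -> InterfaceBundle:
    """Generate a toy domain pair, its interface template, and matched queries.

    ``touching`` geometry places the first ``n_interface`` residues of each
    domain in 1:1 contact (4 A apart, pairs spaced so no cross-contacts
    arise); ``separated`` shifts domain B far away.  Query sequences realize
    the identity/conservation targets exactly up to the 1/length rounding
    quantum; the realized fractions are recorded in the truth dict.
    """
    rng = np.random.default_rng(cfg.seed)
    n, n_int = cfg.n_residues, cfg.n_interface
    # interface positions spread evenly along the chain (1-based)
    interface = tuple(sorted({i * n // n_int + 1 for i in range(n_int)}))
    iface_set = set(interface)

    def coords(side: str) -> np.ndarray:
        sign = 1.0 if side == "a" else -1.0
        xyz = np.zeros((n, 3))
        for i in range(n):
            xyz[i, 0] = 10.0 * i
            if (i + 1) in iface_set:
                xyz[i, 1] = 0.0 if side == "a" else _CONTACT_DISTANCE
            else:
                xyz[i, 1] = sign * _FAR_OFFSET
        if cfg.contact_geometry is ContactGeometry.SEPARATED and side == "b":
            xyz[:, 2] += _FAR_OFFSET
        return xyz

    struct_a = DomainStructure("simA", tuple(range(1, n + 1)), coords("a"))
    struct_b = DomainStructure("simB", tuple(range(1, n + 1)), coords("b"))

    seq_a = _random_sequence(rng, n)
    seq_b = _random_sequence(rng, n)
    template = InterfaceTemplate(
        family_a=f"fam.a.{cfg.seed}",
        family_b=f"fam.b.{cfg.seed}",
        seq_a=seq_a,
        seq_b=seq_b,
        interface_a=frozenset(interface),
        interface_b=frozenset(interface),
        template_id=f"simtmpl.{cfg.seed}",
    )
    mut_positions = _plan_mutations(
        n, interface, cfg.target_identity, cfg.target_conservation
    )
    query_a = _mutate(seq_a, mut_positions)
    query_b = _mutate(seq_b, mut_positions)

    m_total = len(mut_positions)
    m_iface = sum(1 for p in mut_positions if p in iface_set)
    truth = {
        "geometry": cfg.contact_geometry.value,
        "n_contacts": n_int if cfg.contact_geometry is ContactGeometry.TOUCHING else 0,
        "interface_a": sorted(interface),
        "interface_b": sorted(interface),
        "realized_identity": (n - m_total) / n,
        "realized_conservation": (n_int - m_iface) / n_int,
        "mutated_positions": mut_positions,
    }
    return InterfaceBundle(struct_a, struct_b, template, query_a, query_b, truth)


# ---------------------------------------------------------------------------
# Pathway graphs


def gen_pathway_inputs(
    n_receptors: int, n_downstream: int, seed: int = 0, extra_edge_prob: float = 0.15
) -> tuple[list[PathwayNode], list[tuple[str, str]], dict[str, int]]:
    """Random connected receptor-rooted graph with BFS-layer ground truth.

    Each downstream node attaches to a uniformly chosen earlier node, so the
    graph is connected; extra random edges create cycles and shortcut paths.
    The returned truth layers come from a hand-rolled breadth-first search
    independent of the pathway module's implementation.
    """
    if n_receptors <= 0 or n_downstream < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    receptor_names = [f"R{i + 1}" for i in range(n_receptors)]
    down_names = [f"D{i + 1}" for i in range(n_downstream)]
    roles = [Role.EFFECTOR, Role.KINASE, Role.TRANSCRIPTION_FACTOR, Role.OTHER]
    nodes = [
        PathwayNode(r, Role.RECEPTOR, Compartment.MEMBRANE) for r in receptor_names
    ] + [
        PathwayNode(d, roles[int(rng.integers(0, len(roles)))], Compartment.CYTOPLASM)
        for d in down_names
    ]
    names = receptor_names + down_names
    edges: set[tuple[str, str]] = set()
    for k, d in enumerate(down_names):
        parent = names[int(rng.integers(0, n_receptors + k))]
        edges.add((min(parent, d), max(parent, d)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if rng.random() < extra_edge_prob:
                a, b = names[i], names[j]
                edges.add((min(a, b), max(a, b)))

    # independent plain BFS for the layer truth
    adjacency: dict[str, set[str]] = {nm: set() for nm in names}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    truth = {r: 0 for r in receptor_names}
    frontier = list(receptor_names)
    depth = 0
    while frontier:
        depth += 1
        nxt = []
        for node in frontier:
            for nb in adjacency[node]:
                if nb not in truth:
                    truth[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    return nodes, sorted(edges), truth
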