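"""Synthetic CA-trace families with known evolutionary structure.

Every stage of the comparison pipeline is testable without coordinate
downloads: a compact β-meander backbone stands in for a jelly-roll-like CA
trace, families of traces are diverged along a known tree by Brownian
coordinate noise plus loop-restricted indels and arbitrary rigid motions,
and additive (patristic) matrices provide exact oracles for tree building.

The divergence model is deliberately minimal — isotropic Gaussian noise on
coordinates, no side chains, no sequence evolution — because the analysis
downstream consumes only CA geometry. Indels are confined to turn/loop
residues so the strand core persists, mirroring how real capsid-protein
divergence concentrates in surface loops while the fold core is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .phylo import DistanceMatrix, PhyloTree
from .structure_io import CoreTrace

__all__ = [
    "EvolutionSpec",
    "simulate_backbone",
    "evolve_along_tree",
    "make_additive_matrix",
    "random_tree",
]

_STRAND_AA = "VAL"  # strand residues: indel-protected
_LOOP_AA = "GLY"    # turn residues: indel-eligible

_CA_STEP = 3.8          # target consecutive CA distance, Å
_AXIAL_STEP = 3.3       # per-residue advance along a strand, Å
_SHEET_SPACING = 4.8    # inter-strand spacing, Å
_STRAND_LEN = 10


def simulate_backbone(n_residues: int, seed: int) -> CoreTrace:
    """Self-avoiding β-meander CA trace of ``n_residues`` positions.

    Alternating extended strands (zig-zag, ~3.3 Å/residue axial advance)
    connected by single turn residues, with a small seeded jitter so
    different seeds give distinct but equally well-formed backbones.
    Consecutive CA distances stay within 3.8 ± 0.1 Å and non-consecutive
    pairs are kept beyond 3 Å.
    """
    if n_residues < 30:
        raise ValueError(f"n_residues must be >= 30, got {n_residues}")
    rng = np.random.default_rng(seed)
    zig = 0.5 * np.sqrt(_CA_STEP**2 - _AXIAL_STEP**2)  # zig-zag half-amplitude
    lift = np.sqrt(_CA_STEP**2 - (_SHEET_SPACING / 2.0) ** 2)  # turn residue rise

    positions: list[np.ndarray] = []
    kinds: list[str] = []
    y = 0.0
    direction = 1.0
    phase = 1.0
    x = 0.0
    while len(positions) < n_residues:
        # one strand
        for _ in range(_STRAND_LEN):
            positions.append(np.array([x, y, phase * zig]))
            kinds.append(_STRAND_AA)
            if len(positions) >= n_residues:
                break
            x += direction * _AXIAL_STEP
            phase = -phase
        if len(positions) >= n_residues:
            break
        # turn residue: strand ended at (x, y, phase_prev*zig) after the loop
        x -= direction * _AXIAL_STEP  # stay at the strand end
        phase = -phase                # phase of the last placed residue
        positions.append(np.array([x, y + _SHEET_SPACING / 2.0, phase * zig + lift]))
        kinds.append(_LOOP_AA)
        y += _SHEET_SPACING
        direction = -direction
        # next strand resumes at the same x and z-phase as the strand end
    pts = np.array(positions[:n_residues])
    kinds = kinds[:n_residues]
    pts += rng.normal(0.0, 0.02, size=pts.shape)
    tags = [("A", i + 1, "", aa) for i, aa in enumerate(kinds)]
    return CoreTrace(label=f"backbone_seed{seed}", positions=pts, residue_tags=tags)


@dataclass(frozen=True)
class EvolutionSpec:
    """Conditions for diverging one backbone along a tree.

    sigma_per_unit : per-coordinate Gaussian noise, Å per sqrt(unit branch
        length) — Brownian-on-coordinates divergence.
    indel_rate : per-residue, per-unit-branch-length probability of an indel
        event (deletion or duplication of a loop residue).
    """

    tree: PhyloTree
    sigma_per_unit: float = 0.3
    n_residues: int = 200
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_per_unit < 0:
            raise ValueError("sigma_per_unit must be >= 0")
        if not (0 <= self.indel_rate < 0.2):
            raise ValueError("indel_rate must be in [0, 0.2)")
        if self.n_residues < 30:
            raise ValueError("n_residues must be >= 30")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _apply_indels(positions: np.ndarray, kinds: list[str], p_event: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    if p_event <= 0:
        return positions, kinds
    out_pos: list[np.ndarray] = []
    out_kind: list[str] = []
    for pos, kind in zip(positions, kinds):
        if kind == _LOOP_AA and rng.random() < p_event:
            if rng.random() < 0.5:
                continue  # deletion
            out_pos.append(pos)
            out_kind.append(kind)
            out_pos.append(pos + rng.normal(0.0, 0.5, size=3))  # duplication
            out_kind.append(kind)
        else:
            out_pos.append(pos)
            out_kind.append(kind)
    if len(out_pos) < 30:  # never shrink below a valid trace
        return positions, kinds
    return np.array(out_pos), out_kind


def evolve_along_tree(spec: EvolutionSpec) -> dict[str, CoreTrace]:
    """One CA trace per leaf, diverged along the tree from a common ancestor.

    Along each branch of length b: add i.i.d. Gaussian noise with
    per-coordinate sd sigma_per_unit·sqrt(b), apply loop indels at
    probability indel_rate·b per loop residue, then a uniformly random
    proper rigid motion (translations within a 100 Å box). Deterministic for
    a fixed spec (tree traversal order is fixed).
    """
    for edge in spec.tree.tree.preorder_edge_iter():
        if edge.head_node is spec.tree.tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree must have branch lengths on every edge")
    rng = np.random.default_rng(spec.seed)
    root = simulate_backbone(spec.n_residues, spec.seed)
    root_kinds = [tag[3] for tag in root.residue_tags]

    leaves: dict[str, CoreTrace] = {}

    def descend(node: dendropy.Node, positions: np.ndarray, kinds: list[str]) -> None:
        for child in node.child_nodes():
            b = child.edge.length
            pos = positions + rng.normal(0.0, spec.sigma_per_unit * np.sqrt(b),
                                         size=positions.shape)
            pos, kk = _apply_indels(pos, list(kinds), spec.indel_rate * b, rng)
            R = _random_rotation(rng)
            t = rng.uniform(-50.0, 50.0, size=3)
            pos = pos @ R.T + t
            if child.is_leaf():
                label = child.taxon.label
                tags = [("A", i + 1, "", aa) for i, aa in enumerate(kk)]
                leaves[label] = CoreTrace(label=label, positions=pos,
                                          residue_tags=tags)
            else:
                descend(child, pos, kk)

    descend(spec.tree.tree.seed_node, root.positions, root_kinds)
    return leaves


def make_additive_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (path-sum) distance matrix of a tree with branch lengths.

    The result is additive by construction and satisfies the four-point
    condition, making it an exact oracle for neighbor joining.
    """
    t = tree.tree
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree must have branch lengths on every edge")
    pdm = t.phylogenetic_distance_matrix()
    labels = sorted(tree.leaf_labels)
    taxa = {tax.label: tax for tax in t.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def random_tree(n_leaves: int, rng: np.random.Generator,
                blen_range: tuple[float, float] = (0.1, 5.0),
                prefix: str = "T") -> PhyloTree:
    """Random unrooted binary topology with uniform branch lengths.

    Built by random sequential joining; the root is the standard
    trifurcation. Leaf labels are ``{prefix}01 .. {prefix}NN``.
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    labels = [f"{prefix}{i + 1:02d}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    lo, hi = blen_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = blen()
        parent.add_child(nodes[j])
        nodes[j].edge.length = blen()
        nodes[i] = parent
        del nodes[j]
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
        nd.edge.length = blen()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)
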