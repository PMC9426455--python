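"""Distance matrices, neighbor-joining trees, and clade tests.

The structural phylogeny is distance-based: pairwise common-core RMSDs feed
the Saitou–Nei neighbor-joining agglomeration, which is exact on additive
matrices. Trees are unrooted (trifurcating root in Newick); monophyly on an
unrooted tree means some edge bipartitions the leaves into exactly
(clade, rest).

Trees are carried as :class:`dendropy.Tree` objects wrapped in
:class:`PhyloTree`; neighbor joining, bipartition encoding, Robinson–Foulds
and monophyly are implemented here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .align import MultipleAlignment, kabsch

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "build_distance_matrix",
    "neighbor_joining",
    "is_monophyletic",
    "robinson_foulds",
    "write_newick",
    "read_newick",
    "write_phylip",
    "read_phylip",
]


@dataclass
class DistanceMatrix:
    """Symmetric labeled all-vs-all distance matrix (RMSDs in Å)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError(f"values must be ({n}, {n}), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite distance between {self.labels[bad[0]]!r} "
                f"and {self.labels[bad[1]]!r}"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        # enforce exact symmetry / zero diagonal after validation
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def permuted(self, new_order: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lab) for lab in new_order]
        return DistanceMatrix(new_order, self.values[np.ix_(idx, idx)])

    def to_csv(self) -> str:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        return df.to_csv()

    @classmethod
    def from_csv(cls, text: str) -> "DistanceMatrix":
        df = pd.read_csv(io.StringIO(text), index_col=0)
        return cls(list(df.index), df.to_numpy())


def build_distance_matrix(alignment: MultipleAlignment) -> DistanceMatrix:
    """Pairwise common-core optimal-superposition RMSDs of a multiple alignment."""
    labels = alignment.labels
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch(alignment.common_coords[labels[i]],
                       alignment.common_coords[labels[j]]).rmsd
            if not np.isfinite(r):
                raise ValueError(
                    f"non-finite RMSD between {labels[i]!r} and {labels[j]!r}"
                )
            values[i, j] = values[j, i] = r
    return DistanceMatrix(labels, values)


class PhyloTree:
    """Unrooted tree with branch lengths, wrapping a dendropy Tree.

    The seed node is a trifurcation standing in for the unrooted root.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        self._leaves = frozenset(labels)

    @property
    def leaf_labels(self) -> frozenset:
        return self._leaves

    def splits(self, include_trivial: bool = False) -> set[frozenset]:
        """Edge bipartitions, each canonicalized as the side excluding the
        alphabetically first leaf."""
        ref = min(self._leaves)
        n = len(self._leaves)
        out: set[frozenset] = set()
        below: dict[dendropy.Node, frozenset] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([node.taxon.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in
                                                  node.child_nodes()))
            if node is self.tree.seed_node:
                continue
            side = below[node]
            if not include_trivial and not (1 < len(side) < n - 1):
                continue
            if len(side) >= n or len(side) == 0:
                continue
            canon = side if ref not in side else self._leaves - side
            out.add(canon)
        return out

    def total_length(self) -> float:
        return float(sum(e.length or 0.0 for e in self.tree.edges()))


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    At each step the pair minimizing Q(i,j) = (n-2)·d(i,j) − Σ_k d(i,k)
    − Σ_k d(j,k) is joined; ties go to the lexicographically smallest pair of
    cluster representatives (the alphabetically first leaf below each
    cluster). Branch lengths follow the standard limb-length formulas, with
    negative values clamped to zero. Additive matrices are recovered exactly
    (topology and edge lengths). The result is unrooted with a trifurcating
    root.
    """
    n = len(d)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    tns = dendropy.TaxonNamespace(d.labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in d.labels]
    reps = list(d.labels)  # representative = min leaf label below the cluster
    D = d.values.copy()

    def join(i: int, j: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        del nodes[j], reps[j]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - (r[:, None] + r[None, :])
        # search the strict upper triangle only (Q is symmetric by construction)
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        candidates = [
            (tuple(sorted((reps[i], reps[j]))), int(i), int(j))
            for i, j in zip(*np.where(Q == qmin))
        ]
        _, i, j = min(candidates)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        join(i, j, li, lj)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)

    # final trifurcation
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def is_monophyletic(tree: PhyloTree, taxa: set, outgroup_free: bool = True) -> bool:
    """True iff some edge bipartitions the leaves into exactly (taxa, rest).

    On an unrooted tree this is the edge-separation sense of monophyly; the
    whole leaf set and single leaves are trivially monophyletic.
    """
    taxa = frozenset(taxa)
    unknown = taxa - tree.leaf_labels
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if taxa == tree.leaf_labels:
        return True
    if not taxa:
        raise ValueError("empty taxon set")
    ref = min(tree.leaf_labels)
    canon = taxa if ref not in taxa else tree.leaf_labels - taxa
    return canon in tree.splits(include_trivial=True)


def monophyly_edge(tree: PhyloTree, taxa: set) -> frozenset | None:
    """The separating bipartition side (as the clade set) if one exists."""
    return frozenset(taxa) if is_monophyletic(tree, set(taxa)) else None


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Count of nontrivial bipartitions present in exactly one tree."""
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError(
            "leaf sets differ: "
            f"{sorted(t1.leaf_labels ^ t2.leaf_labels)} not shared"
        )
    return len(t1.splits() ^ t2.splits())


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths at 6 significant digits."""
    return tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    ).strip() + "\n"


def read_newick(text: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return PhyloTree(tree)


def midpoint_rooted_newick(tree: PhyloTree) -> str:
    """Display-only midpoint-rooted rendering (figure-style)."""
    clone = dendropy.Tree(tree.tree)
    clone.reroot_at_midpoint(update_bipartitions=False)
    return clone.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        real_value_format_specifier=".6g",
    ).strip() + "\n"


def write_phylip(d: DistanceMatrix) -> str:
    """Square PHYLIP with relaxed labels (no 10-character truncation)."""
    lines = [str(len(d))]
    for lab, row in zip(d.labels, d.values):
        lines.append(lab + "  " + "  ".join(f"{v:.10g}" for v in row))
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> DistanceMatrix:
    tokens = text.split()
    if not tokens:
        raise ValueError("empty PHYLIP text")
    try:
        n = int(tokens[0])
    except ValueError:
        raise ValueError(f"PHYLIP first token must be the taxon count, got {tokens[0]!r}")
    body = tokens[1:]
    if len(body) != n * (n + 1):
        raise ValueError(
            f"PHYLIP body has {len(body)} tokens; expected {n * (n + 1)} "
            f"for a square matrix of {n} taxa"
        )
    labels, rows = [], []
    for i in range(n):
        chunk = body[i * (n + 1):(i + 1) * (n + 1)]
        labels.append(chunk[0])
        try:
            rows.append([float(v) for v in chunk[1:]])
        except ValueError as exc:
            raise ValueError(f"PHYLIP row {chunk[0]!r}: {exc}") from exc
    return DistanceMatrix(labels, np.array(rows))
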