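"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the RMSD oracle is
Horn's quaternion closed form (the package uses constrained SVD), the split
oracle enumerates bipartitions from the Newick structure via dendropy, and
the arc-length oracle integrates the helix numerically.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum RMSD over proper rotations, via the 4x4 key-matrix eigenvalue."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    n = len(A)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    M = Ac.T @ Bc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = float(np.linalg.eigvalsh(K)[-1])
    e0 = float(np.sum(Ac * Ac) + np.sum(Bc * Bc))
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / n))


def newick_splits(newick: str) -> set[frozenset]:
    """Nontrivial bipartitions of an unrooted Newick tree, by brute
    enumeration over dendropy's bipartition encoding."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    tree.encode_bipartitions()
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    n = len(leaves)
    out = set()
    for bip in tree.bipartition_encoding:
        side = frozenset(
            tax.label for tax in tree.taxon_namespace
            if bip.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(tax)
        )
        if not (1 < len(side) < n - 1):
            continue
        canon = side if ref not in side else leaves - side
        out.add(canon)
    return out


def helix_arc_length_numeric(radius: float, pitch: float, n_turns: float,
                             n_steps: int = 200_000) -> float:
    """Polyline arc length of the helix, refined enough for sub-bp accuracy."""
    t = np.linspace(0.0, n_turns, n_steps)
    x = radius * np.cos(2 * np.pi * t)
    y = radius * np.sin(2 * np.pi * t)
    z = pitch * t
    pts = np.column_stack([x, y, z])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
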