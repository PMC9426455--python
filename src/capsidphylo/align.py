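"""Sequence-independent rigid-body superposition of CA traces.

The comparison unit downstream is the optimal-superposition RMSD (Procrustes
distance) between fold cores. Because the compared capsid proteins share no
usable sequence similarity, residue correspondences are found geometrically:
a best-superposing gapless seed window is refined by iterating
superposition → distance-based scoring → global sequential dynamic
programming until the pair set is stable. This reproduces the common-core
behaviour of standard multiple structure aligners.

All operations are deterministic; there is no randomness anywhere in this
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .structure_io import CoreTrace

__all__ = [
    "AlignParams",
    "Correspondence",
    "SuperpositionResult",
    "MultipleAlignment",
    "kabsch",
    "kabsch_rmsd",
    "find_correspondence",
    "superpose",
    "pairwise_core_rmsd",
    "multiple_superpose",
    "write_correspondence_table",
]


@dataclass(frozen=True)
class AlignParams:
    """Tunable constants of the correspondence search.

    mode : "auto" runs the seeded iterative-DP search; "one_to_one" forces
        the positional identity correspondence (equal-length traces whose
        residues already correspond, e.g. simulated families without indels).
    d0 : distance scale of the similarity score s = 1/(1 + (d/d0)^2), Å.
    pair_cutoff : post-superposition distance below which an aligned column
        is accepted as an equivalenced pair, Å.
    seed_window / seed_stride : gapless window length and stride of the
        exhaustive seed search.
    max_iter : cap on refine iterations.
    gap_frac : DP gap penalty as a fraction of the maximum pair score.
    min_pairs : alignments shorter than this are flagged low-confidence.
    """

    mode: str = "auto"
    d0: float = 3.0
    pair_cutoff: float = 6.0
    seed_window: int = 15
    seed_stride: int = 4
    max_iter: int = 20
    gap_frac: float = 0.6
    min_pairs: int = 30

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "one_to_one"):
            raise ValueError(f"mode must be 'auto' or 'one_to_one', got {self.mode!r}")


@dataclass(frozen=True)
class Correspondence:
    """Sequential residue correspondence: index pairs strictly increasing in both."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        if len(pairs) < 3:
            raise ValueError(f"correspondence needs >= 3 pairs, got {len(pairs)}")
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            if i1 <= i0 or j1 <= j0:
                raise ValueError("correspondence must be strictly increasing (no crossings)")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def indices_a(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs], dtype=int)

    @property
    def indices_b(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs], dtype=int)

    def swapped(self) -> "Correspondence":
        return Correspondence(tuple((j, i) for i, j in self.pairs))


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rigid motion x -> R x + t taking set A onto set B, with its RMSD."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    correspondence: Correspondence | None
    rmsd: float
    degenerate: bool = False
    low_confidence: bool = False

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def kabsch(points_a: Sequence, points_b: Sequence,
           correspondence: Correspondence | None = None) -> SuperpositionResult:
    """Optimal proper rigid superposition of A onto B (SVD solution).

    With ``correspondence`` given, only the corresponded pairs enter the fit;
    otherwise a 1:1 correspondence by position is implied and the inputs must
    have equal length >= 3. Reflections are never returned: the smallest
    singular direction is sign-flipped when the naive solution is improper.
    Degenerate inputs (collinear or coincident points) are flagged but still
    yield a minimizing rotation.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if correspondence is not None:
        A = A[correspondence.indices_a]
        B = B[correspondence.indices_b]
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must be matching (n, 3); got {A.shape} vs {B.shape}")
    n = len(A)
    if n < 3:
        raise ValueError(f"need >= 3 corresponded points, got {n}")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diffs = Ac @ R.T - Bc
    rmsd = float(np.sqrt(np.mean(np.sum(diffs * diffs, axis=1))))
    degenerate = bool(S[1] < 1e-9 * max(S[0], 1.0))
    return SuperpositionResult(
        rotation=R, translation=t, correspondence=correspondence,
        rmsd=rmsd, degenerate=degenerate,
    )


def kabsch_rmsd(points_a: Sequence, points_b: Sequence) -> float:
    return kabsch(points_a, points_b).rmsd


# ---------------------------------------------------------------------------
# seed search: batched SVD superposition of all gapless window pairs


def _window_starts(n: int, window: int, stride: int) -> np.ndarray:
    starts = np.arange(0, max(n - window, 0) + 1, stride)
    if len(starts) == 0:
        starts = np.array([0])
    return starts


def _ranked_window_seeds(A: np.ndarray, B: np.ndarray, window: int, stride: int,
                         top_k: int, pair_cutoff: float) -> list[tuple[int, int]]:
    """Seed window pairs ranked by global extendability.

    Every gapless window pair is superposed (batched SVD). Window RMSD alone
    cannot pick the register of repetitive folds — a β-meander shifted by a
    full strand period superposes as well as the true register — so pairs
    are ranked primarily by how many residues of the *whole* traces fall
    within ``pair_cutoff`` along the diagonal implied by the window offset
    (± 2 residues of drift), and only then by window RMSD.
    """
    sa = _window_starts(len(A), window, stride)
    sb = _window_starts(len(B), window, stride)
    w = min(window, len(A), len(B))
    offs = np.arange(w)
    WA = A[sa[:, None] + offs]          # (ka, w, 3)
    WB = B[sb[:, None] + offs]          # (kb, w, 3)
    ca, cb = WA.mean(axis=1), WB.mean(axis=1)
    WAc, WBc = WA - ca[:, None], WB - cb[:, None]
    ka, kb = len(sa), len(sb)
    K = ka * kb
    H = np.einsum("awi,bwj->abij", WAc, WBc).reshape(K, 3, 3)
    U, S, Vt = np.linalg.svd(H)
    V = np.transpose(Vt, (0, 2, 1))
    UT = np.transpose(U, (0, 2, 1))
    d = np.sign(np.linalg.det(V @ UT))
    d[d == 0] = 1.0
    D3 = np.zeros((K, 3, 3))
    D3[:, 0, 0] = D3[:, 1, 1] = 1.0
    D3[:, 2, 2] = d
    R = V @ D3 @ UT                      # (K, 3, 3): window A -> window B
    trace_sum = S[:, 0] + S[:, 1] + d * S[:, 2]
    e0 = (np.einsum("awi,awi->a", WAc, WAc)[:, None]
          + np.einsum("bwi,bwi->b", WBc, WBc)[None, :]).ravel()
    msd = np.maximum(e0 - 2.0 * trace_sum, 0.0) / w

    ca_p = np.repeat(ca, kb, axis=0)
    cb_p = np.tile(cb, (ka, 1))
    t = cb_p - np.einsum("kij,kj->ki", R, ca_p)
    off = (np.tile(sb, ka) - np.repeat(sa, kb))           # (K,)
    nA, nB = len(A), len(B)
    idx_a = np.arange(nA)
    cutoff2 = pair_cutoff * pair_cutoff
    extend = np.empty(K, dtype=int)
    chunk = max(1, 4_000_000 // max(nA, 1))               # bound peak memory
    for lo in range(0, K, chunk):
        hi = min(lo + chunk, K)
        At = np.einsum("kij,nj->kni", R[lo:hi], A) + t[lo:hi, None, :]
        best_d2 = np.full((hi - lo, nA), np.inf)
        for delta in (-2, -1, 0, 1, 2):
            j = idx_a[None, :] + off[lo:hi, None] + delta
            valid = (j >= 0) & (j < nB)
            jc = np.clip(j, 0, nB - 1)
            diff = At - B[jc]
            d2 = np.einsum("kni,kni->kn", diff, diff)
            d2[~valid] = np.inf
            best_d2 = np.minimum(best_d2, d2)
        extend[lo:hi] = (best_d2 < cutoff2).sum(axis=1)

    order = np.lexsort((msd, -extend))[:top_k]
    out = []
    for flat in order:
        ia, ib = np.unravel_index(int(flat), (ka, kb))
        out.append((int(sa[ia]), int(sb[ib])))
    return out


# ---------------------------------------------------------------------------
# global sequential DP (Needleman–Wunsch on the similarity score matrix)

try:  # numba kernel; pure-python fallback keeps the package importable without JIT
    from numba import njit

    @njit(cache=True)
    def _nw_fill(S, gap):  # pragma: no cover - exercised via wrapper
        n, m = S.shape
        F = np.zeros((n + 1, m + 1))
        P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
        for i in range(1, n + 1):
            F[i, 0] = -gap * i
            P[i, 0] = 1
        for j in range(1, m + 1):
            F[0, j] = -gap * j
            P[0, j] = 2
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                diag = F[i - 1, j - 1] + S[i - 1, j - 1]
                up = F[i - 1, j] - gap
                left = F[i, j - 1] - gap
                best = diag
                ptr = 0
                if up > best:
                    best, ptr = up, 1
                if left > best:
                    best, ptr = left, 2
                F[i, j] = best
                P[i, j] = ptr
        return F, P

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _nw_fill(S, gap):
        n, m = S.shape
        F = np.zeros((n + 1, m + 1))
        P = np.zeros((n + 1, m + 1), dtype=np.int8)
        F[1:, 0] = -gap * np.arange(1, n + 1)
        P[1:, 0] = 1
        F[0, 1:] = -gap * np.arange(1, m + 1)
        P[0, 1:] = 2
        for i in range(1, n + 1):
            Si = S[i - 1]
            for j in range(1, m + 1):
                diag = F[i - 1, j - 1] + Si[j - 1]
                up = F[i - 1, j] - gap
                left = F[i, j - 1] - gap
                best, ptr = diag, 0
                if up > best:
                    best, ptr = up, 1
                if left > best:
                    best, ptr = left, 2
                F[i, j] = best
                P[i, j] = ptr
        return F, P


def _nw_traceback(P: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    i, j = P.shape[0] - 1, P.shape[1] - 1
    while i > 0 or j > 0:
        ptr = P[i, j]
        if ptr == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif ptr == 1 and i > 0:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def find_correspondence(a: CoreTrace, b: CoreTrace,
                        params: AlignParams = AlignParams()) -> Correspondence:
    """Geometric residue correspondence between two CA traces.

    ``auto`` mode: (1) exhaustively superpose all gapless windows
    (length ``seed_window``, stride ``seed_stride``) of A against B and keep
    the few best-RMSD seeds — repetitive architectures (β-sheets, meanders)
    make single-seed registration ambiguous, so each candidate seed is
    refined and the longest (then lowest-RMSD) result wins; (2) refinement
    iterates up to ``max_iter`` times — superpose on the current pairs,
    score s(i,j) = 1/(1+(d_ij/d0)^2), run global sequential DP with gap
    penalty ``gap_frac``·s_max, and rebuild the pair set from aligned
    columns closer than ``pair_cutoff`` — stopping when the pair set no
    longer changes. Deterministic for fixed inputs and params.
    """
    A, B = a.positions, b.positions
    if len(A) < 3 or len(B) < 3:
        raise ValueError("both traces need >= 3 positions")
    if params.mode == "one_to_one":
        n = min(len(A), len(B))
        return Correspondence(tuple((i, i) for i in range(n)))

    w = min(params.seed_window, len(A), len(B))
    seeds = _ranked_window_seeds(A, B, w, params.seed_stride, top_k=5,
                                 pair_cutoff=params.pair_cutoff)

    def refine(seed: tuple[int, int]) -> list[tuple[int, int]] | None:
        sa, sb = seed
        pairs = [(sa + k, sb + k) for k in range(w)]
        for _ in range(params.max_iter):
            sup = kabsch(A, B, Correspondence(tuple(pairs)))
            At = sup.transform(A)
            diff = At[:, None, :] - B[None, :, :]
            D = np.sqrt(np.sum(diff * diff, axis=2))
            S = 1.0 / (1.0 + (D / params.d0) ** 2)
            gap = params.gap_frac * float(S.max())
            _, P = _nw_fill(S, gap)
            aligned = _nw_traceback(np.asarray(P))
            new_pairs = [(i, j) for i, j in aligned
                         if D[i, j] < params.pair_cutoff]
            if len(new_pairs) < 3:
                return None
            if new_pairs == pairs:
                break
            pairs = new_pairs
        return pairs

    best: list[tuple[int, int]] | None = None
    best_key: tuple[int, float] | None = None
    for seed in seeds:
        pairs = refine(seed)
        if pairs is None:
            continue
        rmsd = kabsch(A, B, Correspondence(tuple(pairs))).rmsd
        key = (-len(pairs), rmsd)
        if best_key is None or key < best_key:
            best, best_key = pairs, key
    if best is None:
        raise ValueError(
            f"alignment failed between {a.label!r} and {b.label!r}: "
            f"no seed produced >= 3 pairs within {params.pair_cutoff} Å"
        )
    return Correspondence(tuple(best))


def superpose(a: CoreTrace, b: CoreTrace,
              params: AlignParams = AlignParams()) -> SuperpositionResult:
    """Correspondence search + optimal superposition of A onto B."""
    corr = find_correspondence(a, b, params)
    result = kabsch(a.positions, b.positions, corr)
    if len(corr) < params.min_pairs:
        result = replace(result, low_confidence=True)
    return result


def pairwise_core_rmsd(a: CoreTrace, b: CoreTrace,
                       params: AlignParams = AlignParams()) -> float:
    """Optimal-superposition RMSD over the geometric correspondence, Å.

    Inputs are ordered canonically by label before aligning so the value is
    exactly symmetric under argument swap.
    """
    if b.label < a.label:
        a, b = b, a
    return superpose(a, b, params).rmsd


@dataclass
class MultipleAlignment:
    """Progressive reference-based multiple superposition.

    ``columns`` maps each reference residue index to {label: residue index};
    ``common_columns`` are the reference indices covered by every structure
    (the common core). ``common_coords`` carries, per structure, the original
    coordinates restricted to the common columns in column order — the raw
    material for pairwise common-core RMSDs. ``transforms`` superpose each
    structure onto the iteratively refined consensus.
    """

    labels: list[str]
    reference_label: str
    columns: list[dict[str, int]]
    common_columns: list[int]
    common_coords: dict[str, np.ndarray]
    transforms: dict[str, tuple[np.ndarray, np.ndarray]]
    traces: dict[str, CoreTrace] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.common_columns) < 3:
            raise ValueError("no common core: fewer than 3 common columns")


def multiple_superpose(traces: Sequence[CoreTrace],
                       params: AlignParams = AlignParams()) -> MultipleAlignment:
    """Align >= 3 traces on their common core.

    The reference is the trace minimizing mean pairwise RMSD (ties to the
    alphabetically first label). Every other trace is mapped onto the
    reference via its pairwise correspondence; columns present in all
    structures form the common core. The consensus is refined by iterating
    superposition onto the mean coordinates until the mean shift is below
    1e-6 Å (at most 50 iterations).
    """
    if len(traces) < 3:
        raise ValueError(f"multiple superposition needs >= 3 traces, got {len(traces)}")
    labels = [t.label for t in traces]
    if len(set(labels)) != len(labels):
        raise ValueError("trace labels must be unique")
    by_label = {t.label: t for t in traces}
    order = sorted(labels)

    # all-pairs RMSD to pick the reference; cache correspondences
    corr_cache: dict[tuple[str, str], Correspondence] = {}
    rmsds = {lab: [] for lab in order}
    for i, la in enumerate(order):
        for lb in order[i + 1:]:
            corr = find_correspondence(by_label[la], by_label[lb], params)
            corr_cache[(la, lb)] = corr
            r = kabsch(by_label[la].positions, by_label[lb].positions, corr).rmsd
            rmsds[la].append(r)
            rmsds[lb].append(r)
    reference = min(order, key=lambda lab: (float(np.mean(rmsds[lab])), lab))

    ref_trace = by_label[reference]
    nref = len(ref_trace)
    columns: list[dict[str, int]] = [{reference: i} for i in range(nref)]
    for lab in order:
        if lab == reference:
            continue
        key = (min(lab, reference), max(lab, reference))
        corr = corr_cache[key]
        if key[0] != reference:  # stored as (lab, reference); flip to ref->lab
            corr = corr.swapped()
        for ref_idx, other_idx in corr.pairs:
            columns[ref_idx][lab] = other_idx

    common = [i for i, col in enumerate(columns) if len(col) == len(order)]
    if len(common) < 3:
        raise ValueError("no common core: fewer than 3 columns shared by all structures")

    common_coords = {
        lab: np.array([by_label[lab].positions[columns[i][lab]] for i in common])
        for lab in order
    }

    # consensus refinement on the common core
    transforms: dict[str, tuple[np.ndarray, np.ndarray]] = {
        lab: (np.eye(3), np.zeros(3)) for lab in order
    }
    placed = {lab: common_coords[lab].copy() for lab in order}
    mean = placed[reference].copy()
    for _ in range(50):
        new_placed = {}
        for lab in order:
            sup = kabsch(common_coords[lab], mean)
            transforms[lab] = (sup.rotation, sup.translation)
            new_placed[lab] = sup.transform(common_coords[lab])
        new_mean = np.mean(np.stack(list(new_placed.values())), axis=0)
        shift = float(np.mean(np.linalg.norm(new_mean - mean, axis=1)))
        placed, mean = new_placed, new_mean
        if shift < 1e-6:
            break

    return MultipleAlignment(
        labels=order,
        reference_label=reference,
        columns=columns,
        common_columns=common,
        common_coords=common_coords,
        transforms=transforms,
        traces=dict(by_label),
    )


def write_correspondence_table(a: CoreTrace, b: CoreTrace, corr: Correspondence,
                               sup: SuperpositionResult) -> str:
    """Tab-separated pair table: label_a, res_a, label_b, res_b, distance (Å)."""
    At = sup.transform(a.positions)
    lines = ["label_a\tres_a\tlabel_b\tres_b\tdistance_A"]
    for i, j in corr.pairs:
        d = float(np.linalg.norm(At[i] - b.positions[j]))
        ra = a.residue_tags[i][1]
        rb = b.residue_tags[j][1]
        lines.append(f"{a.label}\t{ra}\t{b.label}\t{rb}\t{d:.3f}")
    return "\n".join(lines) + "\n"
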