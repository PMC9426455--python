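# Methods

## Scope and data model

The package compares capsid-protein chains as CA-only point sequences. A
structure (`StructureModel`) is an ordered set of chains of residues keyed
by author numbering plus insertion code; a `CoreDefinition` names one chain
and a sorted union of inclusive residue ranges (e.g. `60-365,378-384`), and
extracting it yields a `CoreTrace` — the unit every downstream stage
consumes. Waters and non-polymer heteroatoms are dropped at parse time;
non-standard amino acids with a CA are kept under their own 3-letter code.
Alternate conformations resolve to the highest-occupancy CA, ties to the
alphabetically first altloc, so a file always yields one deterministic
trace. Residues without a CA are skipped, never interpolated: fabricating
coordinates would silently bias RMSDs.

## Rigid superposition

`kabsch` solves the orthogonal Procrustes problem by SVD of the centered
covariance, with the smallest singular direction sign-flipped whenever the
unconstrained optimum is a reflection; returned rotations therefore always
have determinant +1. Degenerate inputs (rank < 2: collinear or coincident
points) still return a minimizer but are flagged. The test suite checks the
SVD path against Horn's quaternion eigenvalue closed form, which is kept
independent of the implementation.

## Correspondence search

Capsid folds at these distances share no usable sequence signal, so
residue equivalences are found geometrically:

1. **Seeding.** All gapless windows (length 15, stride 4) of trace A are
   superposed on all windows of B in one batched SVD. Window RMSD alone
   cannot identify the register of repetitive architectures — in a
   β-meander (or a real β-sandwich) a window shifted by a full strand
   period superposes essentially as well as the true register — so seeds
   are ranked primarily by *global extendability*: after each window
   superposition, the number of residues of the whole traces that land
   within the pair cutoff along the diagonal implied by the window offset
   (±2 residues of drift). The few best seeds are each refined and the
   longest, then lowest-RMSD, result wins. This is the one place the
   procedure deviates from a plain best-window seed; without it, shifted
   seeds are unrecoverable because the global alignment cannot pay for an
   ~80-column gap jump.
2. **Refinement.** Up to 20 iterations of: superpose on current pairs;
   score all residue pairs s(i,j) = 1/(1+(d_ij/d₀)²) with d₀ = 3.0 Å; run
   global sequential (Needleman–Wunsch-style) dynamic programming with gap
   penalty 0.6·s_max; accept aligned columns with post-superposition
   distance < 6 Å. Iteration stops when the pair set is stable.

Everything is deterministic — there is no randomness in the aligner — and
`pairwise_core_rmsd` orders its arguments by label before aligning so the
distance is exactly symmetric. Alignments shorter than 30 pairs are flagged
low-confidence rather than rejected. The DP fill runs as a numba kernel
(pure-Python fallback included); all other heavy steps are vectorized
numpy.

Defaults (`AlignParams`): d₀ = 3.0 Å, pair cutoff 6 Å, seed window 15,
stride 4, ≤ 20 iterations, gap fraction 0.6, low-confidence threshold 30
pairs. The 6 Å cutoff keeps spurious tiny cores from dominating RMSD; d₀
weights the DP toward sub-3 Å matches.

## Multiple superposition and the distance matrix

The reference is the trace minimizing mean pairwise RMSD (ties to the
alphabetically first label). Other traces map onto reference residues via
their pairwise correspondences; columns covered by every structure form the
common core, and the consensus is refined by iterating superposition onto
the mean coordinates until the mean shift drops below 1e-6 Å (≤ 50
iterations). Matrix entries are pairwise optimal-superposition RMSDs
restricted to the common core. Common-core values can differ by a few
tenths of an Å from aligners that report consensus-restricted or
pair-specific-core RMSDs; within one run the convention is uniform, which
is what a distance-based tree requires.

## Neighbor joining

Standard Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), assign limb lengths by the
usual formulas, reduce, and finish with a trifurcation. Conventions:

- ties in Q break to the lexicographically smallest pair of cluster
  representatives (each cluster represented by its alphabetically first
  leaf) — repeated runs on tied inputs give identical trees;
- negative limb lengths are clamped to zero, not redistributed (matrices
  here are small and near-additive);
- the output is unrooted (trifurcating seed node); midpoint rooting is a
  display option only;
- no bootstrap values — resampling is not defined for coordinate-derived
  distances.

On additive matrices NJ is exact; the acceptance suite verifies topology
(Robinson–Foulds 0) and every edge length to 1e-9 on 500 random trees of
4–12 leaves. Trees serialize as Newick with 6-significant-digit branch
lengths; matrices as relaxed square PHYLIP (full labels, first line = n)
and CSV.

## Virion geometry

`CapsidLattice` validates the triangulation number (T = h² + hk + k²) and
returns 60·T subunits and T quasi-equivalent positions per asymmetric
unit. The genome spool is a single continuous solenoid of constant radius
r, pitch p (axial separation of adjacent turns) and n turns; capacity is
⌊n·√((2πr)² + p²)/rise⌋ with rise 3.4 Å/bp (ideal B-form), a 1e-9 bp
tolerance absorbing exact-multiple roundoff, and `radius_for_capacity` is
the closed-form inverse. Generated traces place one point per base pair
with the angular step solved so consecutive points are separated by
exactly the rise (constant chord): at this sampling the chord–arc
difference (~1e-4 Å at a 113 Å radius) is irrelevant physically but
constant-chord stepping makes spacing uniform to machine precision, which
is the property tests and downstream consumers rely on. Turn spacing is
measured by unwrapping the azimuth about the axis and interpolating the
axial coordinate at each return to the starting azimuth — this also
handles the pitch-0 limit of stacked closed rings.

The model covers only the coiled region; flanking segments that do not
follow the spooling arrangement are outside the parametric description.
Whether the turns are truly one helix or stacked rings is not resolvable at
the supporting resolution; the helix with pitch equal to the observed turn
spacing is this package's declared convention, and at fixed arc length the
choice moves capacity by well under one base pair.

## Synthetic data

`simulate_backbone` builds a compact β-meander: straight zig-zag strands of
10 residues (3.3 Å axial advance, zig-zag amplitude set so consecutive CAs
sit 3.8 Å apart), strands 4.8 Å apart, joined by single turn residues, plus
a 0.02 Å seeded jitter. Strand residues are tagged VAL, turns GLY; that tag
is the indel mask. The generator emulates exactly the features the
pipeline consumes — chain connectivity, strand repetition (which is what
makes registration hard), a persistent core with variable loops — and none
it does not (no side chains, no hydrogen bonding, no real jelly-roll
topology of two facing sheets). Passing tests therefore demonstrate
correctness of the geometry pipeline, not performance on real β-sandwiches.

`evolve_along_tree` implements Brownian-on-coordinates divergence: along a
branch of length b each coordinate gains N(0, σ²b) noise
(σ default 0.3 Å/√unit), each loop residue suffers an indel (delete or
duplicate) with probability `indel_rate`·b (default 0.01), and the chain
receives a uniformly random proper rigid motion with translations in a
100 Å box. The default chain length is 200 residues, a typical jelly-roll
core span. Everything is reproducible from the spec's single seed.

Under this model the expected RMSD between leaves at patristic distance L
is σ√(3L): observed distances are a *concave* (square-root) transform of
the additive tree metric, not additive themselves. NJ topology recovery on
such matrices is therefore good but not guaranteed — measured ≈95% over
random 6–10-leaf trees with branch lengths in [0.5, 3] — and the residual
failures are a property of RMSD-based distances generally, not of this
implementation. In the σ = 0 limit all leaves are exact rigid copies, the
matrix is identically zero, and the generating topology is unrecoverable
in principle; the pipeline then returns the deterministic tie-break tree.

## Pipeline and provenance

`run_pipeline` validates the config (unique labels, clade membership,
mode/core-table consistency) before touching any file, then runs
load → align → matrix → tree, aborting with the stage name and offending
structure label on error. Artifacts (PHYLIP + CSV matrix, Newick tree,
clade report) are byte-identical across reruns of the same config and
inputs; the log records the package version, a SHA-256 config hash and
per-stage timings (the log is the one artifact allowed to differ between
reruns). Structure download is a separate explicit `fetch` command —
network access is never implicit. Raw RMSDs feed NJ directly: no distance
transform, weighting or multiple-testing machinery is applied anywhere.

## Known limitations

- The aligner is a generic iterative-DP structural aligner; it reproduces
  the common-core behaviour of established multiple-structure aligners but
  not any specific program's correspondences, so absolute RMSDs may differ
  from published matrices by a few tenths of an Å.
- No flexible or hinged superposition; a domain swap or hinge motion
  inflates the rigid RMSD.
- Distance-based trees from RMSDs have no substitution model; branch
  lengths are in Å of structural divergence and are not comparable to
  sequence-derived branch lengths.
- The spool model is a constant-radius solenoid; it does not fit density
  maps or build nucleotide-level DNA.
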