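# capsidphylo

Structure-based phylogenetics of viral jelly-roll capsid proteins, with
quantitative models of icosahedral capsid lattices and spooled genome
layers.

## The problem

Single-stranded DNA viruses such as the diatom-infecting bacilladnavirus
CtenDNAV-II are thought to have acquired their capsid gene horizontally
from ssRNA viruses. At these evolutionary distances sequence identity is
gone, but the capsid fold — the eight-stranded antiparallel β-sandwich
known as the jelly roll — is conserved, so relationships must be read from
structure. The standard workflow is distance-based phylogenetics over
superposition RMSDs:

1. extract the jelly-roll **core** of each capsid-protein chain (a chain id
   plus inclusive author-numbered residue ranges per structure);
2. compute all-vs-all **optimal-superposition RMSDs** (Procrustes
   distances) over a sequence-independent common-core alignment;
3. build a **neighbor-joining** tree from the RMSD matrix and test named
   clades for monophyly (on an unrooted tree: some edge separates exactly
   the clade from everything else).

Cores matter: the compared chains run from ~170 to ~640 residues, and the
surface domains inserted into or appended to the fold misalign full-length
chains, so the package supports both a `core` and a `full_length` mode.

The same virion-scale study motivates two small geometry models included
here: the icosahedral lattice accounting (a T = 3 capsid has 60·3 = 180
subunits in 3 quasi-equivalent positions) and a solenoidal model of a
partially spooled genome layer, which converts helix radius, pitch and turn
count into a base-pair capacity at the ideal B-DNA rise of 3.4 Å/bp.

## Methods in brief

- **Superposition** is the closed-form Kabsch/SVD solution constrained to
  proper rotations; RMSD(A,B) = min over rigid motions of
  √(Σᵢ‖R·aᵢ+t−bᵢ‖²/n).
- **Correspondences** are found geometrically (no sequence): best-extending
  seed windows refined by iterating superposition → similarity scoring
  s = 1/(1+(d/d₀)²) → global sequential dynamic programming, keeping pairs
  closer than 6 Å.
- **Neighbor joining** is the Saitou–Nei Q-criterion agglomeration with
  standard limb lengths, deterministic tie-breaking and non-negative
  branch clamping; it is exact on additive matrices.
- **Synthetic families** for validation: β-meander CA backbones diverged
  along known trees by Brownian coordinate noise, loop-restricted indels
  and random rigid motions, plus additive patristic matrices as oracles.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a five-structure family, then rebuild its tree from the true
additive matrix:

```
$ capsidphylo simulate --leaves 5 --seed 3 --out-dir sim --n-residues 80 --sigma 0.2
5 structures -> sim
$ capsidphylo tree sim/true_matrix.phy
(((T01:2.50319,T04:1.95541):1.58282,T05:1.69763):0.899347,T02:2.33644,T03:0.78418);
$ capsidphylo superpose sim/T01.pdb sim/T02.pdb
rmsd_A=0.8393 n_pairs=80
```

The Newick output is the unrooted neighbor-joining tree (branch lengths in
the matrix's units — Å when the matrix holds RMSDs); the superposition line
reports the optimal-superposition RMSD and the number of equivalenced
residue pairs.

Genome-spool geometry — the radius at which a three-turn solenoid with
28 Å turn spacing holds 630 bp of B-form DNA, and the round trip back:

```
$ capsidphylo spool radius --bp 630 --pitch 28 --turns 3
113.55 A
$ capsidphylo spool capacity --radius 113.55 --pitch 28 --turns 3
630 bp
```

Capsid accounting is available from the library:

```python
>>> from capsidphylo.geometry import CapsidLattice, subunit_count, asymmetric_unit_size
>>> subunit_count(CapsidLattice(3)), asymmetric_unit_size(CapsidLattice(3))
(180, 3)
```

A full run over real coordinate files is configured in YAML (see
`examples/pipeline_example.yaml`); structures are fetched only by the
explicit `capsidphylo fetch` command, and the per-structure core residue
ranges are supplied by the user in a tab-separated table
(`examples/cores_example.tsv` shows the format). Outputs per run: the RMSD
matrix (square PHYLIP + CSV), the Newick tree, a clade-monophyly report,
and a log with the config hash.

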