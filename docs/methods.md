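# Methods

This note documents the models and procedures implemented in symflux,
the parameters that matter, the numerical choices, and what the
synthetic-data suites do and do not demonstrate.

## Symmetry-aware docking-pose similarity

### Scoring and reference selection

Docking models carry six energy components (composite score `hs`, van
der Waals, electrostatics, desolvation, restraint-violation `e_air`, and
buried surface area). The modified score used for ranking is the linear
combination `w_vdw·E_vdw + w_elec·E_elec + w_desolv·E_desolv +
w_air·E_air` with default weights (1.0, 0.2, 1.0, 0.0) — the standard
water-refinement weighting with the restraint-violation term removed,
because ambiguous symmetry-replicated restraints inflate `E_air` for
physically good poses. The weights are exposed in `SymClusterParams`; a
model lacking `e_air` remains scorable under the default. Reference =
argmin of this score, ties broken by lowest model id.

### The similarity metric

For a pair (model, reference), the model's receptor is superposed onto
the reference receptor by the Kabsch algorithm (SVD of the
cross-covariance, proper rotations only) over a configurable atom set —
**CA by default**: the conventional choice for ligand-RMSD measures on
docking models, robust to side-chain noise; `backbone` and `all` are
available. The aligned ligand is then rotated about the reference's
symmetry axis by each of the n symmetry angles (k·360/n, i.e. 0°, 72°,
144°, 216°, 288° for C5) and compared with the reference ligand under
the identity and, for a two-chain ligand, the swapped chain
correspondence. The minimum over the ≤ 2n combinations is the
symmetry-aware ligand RMSD. The 0°/identity combination *is* the naive
RMSD, so the metric can never exceed it.

Two implementation notes:

- The procedure is often described as "superpose the model receptor onto
  the reference receptor rotated by angle θ"; that is algebraically
  equivalent to "superpose once, then rotate the aligned ligand by θ",
  because the rigid rotation commutes through the least-squares fit. The
  latter form is implemented (one superposition instead of n per pair)
  and the equivalence is pinned by an exhaustive-enumeration oracle
  test.
- The chain-swap correspondence equals a physical 180° rotation of the
  ligand about its own C2 axis exactly when the ligand is a symmetric
  homodimer; for quasi-symmetric dimers it is the standard
  approximation. A literal coordinate-rotation mode is not provided —
  swapping the chain blocks is the exact operation for the use case.

### Symmetry axis

The axis defaults to the best-fit normal of the plane through the
receptor protomer (chain) centroids, passing through their mean — well
defined for any Cn receptor with n ≥ 3 and exactly the symmetry axis of
an ideal oligomer. The axis is estimated **per reference model**: in an
ensemble whose members sit in slightly different frames, a single global
axis would be wrong in every other member's frame. A user-supplied axis
overrides the estimate everywhere.

### Clustering

All n(n−1)/2 unordered pairs are evaluated (the reported comparison
count is n(n−1), the ordered-pair convention that reproduces the
published count of 39,800 for 200 models). The similarity graph has an
edge where RMSD ≤ 7.5 Å; clusters are its connected components —
the minimal reading of "similar if RMSD ≤ cutoff" — relabeled 0, 1, …
by size descending. Components smaller than max(⌈0.05·n⌉, 10) are
reported unclustered; the ceiling is used so 5% of 201 models demands
11, never under-counting. Per-cluster summaries are box statistics
(quartiles by linear interpolation, whiskers at the most extreme points
within 1.5·IQR, raw points attached) for each energy component and the
minimum ligand-atom distance to the symmetry axis.

## Trajectory localization

### Geometry and folding

The simulated box contains two facing membrane systems (membrane centers
z = 0 and z = −93 Å). Rows with z below the midpoint c = −46.618 belong
to the second system and are reflected by z′ = 2c − z, mapping it onto
the first system's frame; the transform is an involution on the folded
half and the identity elsewhere, so folding is idempotent. The
reflection is a pure z-mirror (x, y untouched): only z enters the
compartment classifier and the radial filter is symmetric about the box
axis.

### Compartment classifier

Descending thresholds (21, 15, 5, −5, −15, −21 Å) map z to: periplasm,
outer periplasmic membrane, inner periplasmic membrane, central
membrane, inner cytoplasmic membrane, outer cytosolic membrane,
cytoplasm — the first threshold with z ≥ t wins; below all thresholds is
cytoplasm. The chain is total (every finite z gets exactly one label)
and symmetric about the membrane center, making all seven labels
reachable. Both thresholds and labels are configurable.

### Exclusions and the "Other" category

Substrate positions are tested against a cylinder of radius 40 Å about
the box axis — the protein's radial boundary. Timepoints outside the
cylinder *and* inside the lipid headgroup band (|z| ≤ 21) are transient
membrane associations: they are excluded from compartment statistics and
counted as "Other", so occupancy fractions (7 compartments + Other) sum
to one per observation. A replicate is removed entirely when a substrate
path transitions cytoplasm ↔ periplasm with its traversal of the
membrane band lying outside the cylinder (membrane leakage); a traversal
with any in-band, in-cylinder frame is in-pore permeation and is kept. A
scripted or instantaneous compartment jump with no outside-cylinder
evidence is also kept — the filter targets leakage outside the protein,
not discontinuities of the path.

### Observables

One observation = one substrate/channel (segment) in one replicate; 5
protomer channels × 3 replicates = 15 observations. Substrate positions
are unweighted centers of geometry of named atom sets (formate
{C1, O2, O3}; formic acid {C, O2, O3}; residue-209 backbone
{C, N, CA, O}) — arithmetic means, not mass-weighted, matching the
extraction convention of the tables this module consumes. Contacts use a
4.0 Å atom–atom cutoff reduced to residue level (a residue counts at
most once per frame); frequencies are contacting frames / total frames.
RMSD series superpose each frame's backbone selection on the reference;
the per-residue profile is the RMS deviation of each residue's backbone
atoms across frames *after* that global fit (fit-first is a
documented choice; computing on raw coordinates would conflate global
drift with local flexibility). Leaflet composition ratios are literal
lipid counts; totals are their sums (78 outer, 76 inner).

## Pore profiling

The tracer initializes the path as the straight segment between the two
anchor-residue centroids and relaxes each interior station center in the
plane perpendicular to the path to maximize the all-atom clearance
radius (coordinate pattern search, initial step 1 Å, halved until below
0.01 Å). The in-plane search basis is derived from the structure itself,
so the whole profile is exactly covariant under rigid motion of the
input. Stations are spaced 0.5 Å by default. Per station:

- radius = max(0, min over atoms of (‖center − atom‖ − vdW)),
- free radius = the same over main-chain atoms {N, CA, C, O} only,
- dynamic range = free radius − radius (≥ 0 because the main chain is a
  subset of all atoms),
- lining = residues with any atom surface within radius + 3.0 Å,
  classed positive {ARG, LYS, HIS}, negative {ASP, GLU}, hydrophilic
  {SER, THR, ASN, GLN, TYR, CYS}, hydrophobic otherwise; a station mixing
  hydrophobic with polar/charged lining is flagged amphipathic,
- blocked where radius < bottleneck radius (default 1.0 Å).

vdW radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å;
configurable. Gate detection reports local radius minima whose nearest
side-chain atoms (within 0.5 Å of the closest surface) belong to ≥ 2
distinct residues of the gate residue name (PHE by default).

This tracer is a deliberate simplification adequate for near-straight
pores and toy structures: it is **not** a Voronoi-diagram channel finder,
does not enumerate multiple channels, and can under-report a constriction
formed by a single off-axis atom, because the clearance maximization
legitimately dodges it (a full pinch ring is reported faithfully).

## Conservation profiling

Family sequences are aligned to the reference by global
Needleman–Wunsch via Biopython's PairwiseAligner with BLOSUM62 and
affine gaps (open −10, extend −1; a run of L gaps scores
−10 − (L−1)·1). Scores are pinned against an independent three-state
(Gotoh) dynamic program in the tests; among co-optimal alignments the
aligner's deterministic first path is taken. Each alignment is projected
onto reference coordinates: every reference position maps to one family
residue or a gap; insertions relative to the reference are not
addressable in reference numbering and are ignored — which is also why
regional gap fractions are computed over reference-coordinate columns.
An alignment is kept when its gap fraction within the region is ≤ 0.10
(the boundary is inclusive: exactly 10% is not "more than 10%");
coverage percentages round half away from zero (8515 of 22242 → 38%).
Column frequencies run over 20 residues + X + gap and sum to 1; the
information content is log₂20 minus the Shannon entropy of the
gap-excluded, renormalized residue distribution (X excluded as carrying
no conservation signal), undefined (NaN) for all-gap columns.

## Synthetic data: what it emulates, what it does not

All generators consume one explicit `numpy.random.Generator` per call
and are bit-reproducible from (parameters, seed); planted parameters are
returned as a `GroundTruth` that serializes to JSON.

**Docking ensembles.** The toy receptor is five protomers of three
stacked 10-atom CA arcs whose point set is *exactly* C5-invariant; the
toy ligand is a two-chain homodimer whose chains are exact 180° images.
Default scenario: clusters of 45 and 111 members plus 44 decoys (200
models); each member is its prototype pose + Gaussian noise (σ = 1 Å,
roughly the coordinate spread of water refinement within a pose family),
rotated to a uniformly random symmetry point, chain-flipped with
probability 0.5, and given a small random rigid motion of the whole
complex (±8°, ±4 Å) to exercise the superposition. Decoy poses are
placed at a fixed 60 Å axis radius, 12 Å apart in z, so no symmetry
operation can bring two of them (or a decoy and a cluster) within the
7.5 Å cutoff: exact recovery (ARI = 1.0) is then a property of the
method, not of a lucky seed. Energies are drawn from per-cluster
normals. Not emulated: receptor deformation, partially symmetric
receptors, ligand conformational change — so the suites show the
clustering resolves the symmetry degeneracy, not that it handles
flexible docking.

**Trajectories.** Scripted dwell sequences place the substrate's center
of geometry at each compartment's mid-z (slab half-widths 3–5 Å), with
truncated Gaussian jitter kept inside the scripted slab, optionally in
the second membrane system (emitted un-folded to exercise the fold) and
optionally at a radial offset outside the protein cylinder to plant
leaks. Three formate atoms with zero-sum offsets make the center of
geometry exact. Not emulated: diffusion kinetics, dwell-time
distributions, protein coordinates (contacts are tested against
separately constructed protein tables) — occupancy bookkeeping is
validated, not transport physics.

**Pore structures.** Stacked 12-atom rings whose inner wall follows the
prescribed probe radius (atom centers at radius + vdW); side-chain-bearing
rings put CB on the inner wall with CA a fixed `side_chain_delta`
(1.5 Å) further out, so both the radius and the free radius have exact
planted values; glycine rings collapse the local dynamic range to zero.
Anchor rings are single residues with on-axis centroids, giving the
tracer exact endpoints. Ring spacing 1 Å keeps the between-ring radius
ripple below ~0.03 Å, well inside the 0.1 Å recovery tolerance. Not
emulated: curved pores, anisotropic walls.

**Sequence families.** Per column, the reference residue is kept with
the column's conservation probability, else substituted uniformly;
columns are deleted independently at the indel rate (insertions are not
generated — they would be invisible in reference coordinates anyway).
Consensus-frequency recovery is binomial, tested at 3σ.

## Numerical and interface conventions

- Coordinates in Å; angles in degrees at API boundaries, radians
  internally; rotations proper (det +1, checked to 1e-6).
- Kabsch requires ≥ 3 non-collinear paired points and rejects degenerate
  clouds rather than returning an arbitrary branch.
- PDB I/O: strict fixed-column ATOM/HETATM parser that names the
  offending line on malformed fields, keeps the first altloc, rejects
  insertion codes (the keying invariant (chain, residue, atom) must be
  unique), writes coordinates at 3 decimals; CRYST1 and other records
  ignored. Chain consolidation renumbers chain k by +k·1000 and keeps the
  reverse map on the structure for restraint tables in original
  numbering.
- Docking energies are parsed from a `REMARK energies key=value` header
  (with a spelling dialect for common engine layouts) or a sidecar TSV;
  absent components are `None`, never zero.
- Tabular outputs are TSV, summaries JSON; every CLI run echoes its
  resolved configuration and tool version to `PREFIX.config.json`; exit
  codes: 2 configuration error, 1 failed stage, 0 success.

## Problem sizes

The test and acceptance runs use the scenario sizes above: one
200-model ensemble (19,900 evaluated pairs) plus twenty 24-model
ensembles for repeated recovery; 15-observation trajectory datasets of
100 frames each; 41-station pore profiles; families of 400–1000
sequences of length 40 for conservation recovery. These sizes give exact
or 3σ-tight planted checks while keeping the full suite inside a few
minutes on one CPU.

## Known limitations

- Connected-component clustering is the documented minimal rule; density
  or clique-based rules would behave differently near the cutoff and are
  not provided.
- The pore tracer assumes a near-straight channel between the anchors;
  strongly curved channels need a curved-path tracer (out of scope).
- The symmetry fold order n is user-supplied, never detected from
  coordinates.
- Pairwise (reference-projected) alignment ignores family-internal
  insertions; column statistics are strictly in reference coordinates.
- mmCIF, density maps and binary trajectory formats are not read; export
  tables or uncompressed PDB/FASTA first.
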