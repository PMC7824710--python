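# Methods

This note documents the models, numerical choices and design decisions
behind `zernmatch`, and what the synthetic closed-loop experiments do and do
not demonstrate.

## Surface model

The molecular surface is the probe-inflated union of atomic spheres
rasterized on a cubic grid: voxel centres within `radius + probe` of any
heavy atom are occupied, and *surface voxels* are occupied voxels with at
least one empty 6-neighbour. This is a solvent-accessible-style surface;
there is no triangulated mesh and no re-entrant (solvent-excluded) surface.
Defaults: spacing 0.5 Å, probe 1.4 Å (a water radius), both configurable.
The grid origin follows the atom bounding box, which makes the construction
exactly translation-covariant up to floating-point rounding of borderline
voxels.

Pocket patches are the surface voxels within a cutoff (default 6 Å) of any
heavy atom of the pocket's residues; small ligands contribute their whole
surface rather than a patch, since a free peptide has no predefined
interface. Pockets are residue-number lists; the two kinase-domain pockets
BP3 (9 residues, N-lobe) and BP4 (11 residues, inter-lobe cleft) ship as
built-ins in UniProt numbering, and no renumbering is attempted — user
structures must already match.

## Charges and electrostatics

Per-atom partial charges and radii come from a bundled united-atom
(implicit-hydrogen) table whose per-residue sums equal the formal charges
exactly (ASP/GLU −1, LYS/ARG +1, others 0, neutral termini). The table is a
deterministic stand-in for a PDB2PQR run; users needing force-field fidelity
should supply PQR input, which takes precedence. Radii are Bondi-style
van der Waals values per element.

The surface potential is a screened Coulomb sum over point charges,
φ(x) = Σᵢ qᵢ/(ε(rᵢ)·rᵢ), with the distance-dependent dielectric ε(r) = 4r
by default (so φ ∝ q/4r²) and a uniform-ε mode for closed-form tests.
Distances below 0.5 Å are clamped with a warning. This is not a
Poisson–Boltzmann solution; it is the simplest defensible screened model
for ranking sign patterns on a surface. The potential-mapped patch is split
by sign into the elec+ and elec− sub-surfaces; each carries |φ| rescaled
linearly to [0, 1] per patch (switchable off), which makes the downstream
metric insensitive to the overall potential scale.

## Zernike expansion

The field on a patch is rasterized back onto its native lattice, centred on
its value-weighted centre of mass, and scaled so the farthest support voxel
sits at radius 0.6 inside the unit ball. The 0.6 margin keeps support away
from r = 1 where the radial basis degrades; it is standard practice in 3D
Zernike shape retrieval. The normalization transform is recorded in the
descriptor metadata.

Moments are computed by direct voxel quadrature,
C_nlm = (3/4π) Σ f(xᵢ) conj(Z_nlm(xᵢ)) h³, over support voxels strictly
inside the ball. The basis uses complex orthonormal spherical harmonics
(Condon–Shortley phase) and radial polynomials built from Jacobi
polynomials, R_nl(r) = sqrt((4π/3)(2n+3)) rˡ P_k^(0, l+½)(2r²−1) with
k = (n−l)/2 — an analytically orthonormal construction, verified
numerically (Gram matrix of the sampled basis at N ≤ 8 is the identity
within 5%). Conjugate symmetry C_{n,l,−m} = (−1)^m conj(C_nlm) is enforced
by construction for the real input fields, and Parseval's identity
Σ D_nl² = Σ |C_nlm|² holds to machine precision by definition of the
invariants.

Truncation order N = 20 (121 invariants) is the working default; the
scaled-down ensemble experiments run at N = 10 (36 invariants), which
preserves the shape contrasts at a sixth of the cost. Direct quadrature was
chosen over the geometric-moment recurrence for transparency and
verifiability; a recurrence could be added as an optimization provided it
matches quadrature within 1e-6.

Rotation invariance is quadrature-limited: on smooth fields sampled at
0.5 Å the descriptor vector changes by well under 1% across random
rotations and tightens at 0.25 Å; on one-voxel-thick binary surface shells
the aliasing is larger (a few percent), which is why the ensemble
experiments compare like with like (all surfaces built on the same lattice
parameters).

## Complementarity metrics and matching design

Both metrics are cosine distances between non-negative descriptor vectors,
hence bounded in [0, 1], symmetric, and zero for identical (shape) or
perfectly cross-matched (electrostatic) inputs. Descriptors enter raw — no
per-component standardization — because cosine distance is already
scale-free. The ensemble design is all-vs-all: every ligand conformer
against every receptor snapshot, one row per pair. Pairs whose
electrostatic channels are missing (a sub-surface with no points of that
sign) are flagged undefined and excluded from distribution summaries, never
imputed or silently zeroed.

The aromatic-separation correlation pairs each conformer's side-chain
centroid distance (heavy atoms only, backbone N/CA/C/O excluded) with its
**median** shape distance across snapshots (an all-pairs mode exists). The
median aggregation reduces the 20 × 50 table to one point per conformer and
is robust to snapshot outliers.

## The synthetic closed loop

The generators emulate the study conditions of a peptide/kinase matching
experiment: 60 conformers × 500 snapshots at full scale, 20 × 50 in the
scaled-down default used by the tests (the full size is a parameter away).
Coordinate jitter of 0.25 Å stands in for thermal positional noise.

**Receptor.** Alanine-like residues (N, CA, C, O, CB pseudo-atoms) packed
on a Fibonacci ball lattice form a solid globule (radius ≈ 2.05·n^⅓ Å,
≈ 10.6 Å at the default 140 residues). A coarse helical chain was
considered and rejected: at test scale it cannot produce a solid body with
carvable concave pockets. Two pockets are carved on opposite faces by
deleting atoms inside a pair of "socket" spheres (radius 3.4 Å = ring
radius + carbon van der Waals + clearance, the negative image of one ring
lobe of the bare ligand surface). The socket centre separation is the
pocket's *imprint distance*: P1 imprints an open conformer (1.5·R ≈ 16 Å),
P2 a compact one (0.38·R ≈ 4 Å, a merged two-sphere cavity). Displacing
atoms instead of deleting them was tried and rejected — displaced atoms
pile into a raised crown that merges the sockets into one compact sheet and
destroys the imprint signal.

**Ligand.** Three residues: two phenyl-like hexagon rings (residues 1 and
3) whose side-chain centroid is exactly the ring centre, and a short basic
stub (residue 2) carrying +1 with backbone N/O partial negatives so both
potential signs exist. The ring-centroid separation follows a uniform
schedule over the preset's hinge range: **wide** (4–12 Å, an i, i+2
aromatic arrangement exploring open and compact states) and **narrow**
(6.2–6.8 Å, an i, i+1 arrangement with nearly fixed separation).
Conformational noise deliberately separates into distance-preserving and
distance-changing parts: a random bend of the inter-ring axis (σ = 40°),
rigid ring tilts (σ = 30°) and a random stub azimuth change the molecular
shape while leaving the centroid distance mathematically unchanged; only
the isotropic 0.25 Å atom jitter perturbs the realized distance. This
mirrors real peptides, where one internal coordinate never determines the
whole shape.

**Matching configuration.** The toy pockets imprint the *bare* ligand
surface, so the scaled-down experiments match with probe 0 and a tight 3 Å
patch cutoff that keeps the patch to the socket linings (pipeline defaults
remain probe 1.4 Å / cutoff 6 Å for real surfaces).

**Calibration.** The two preset bands and the pocket imprints were placed
using noiseless distance-vs-separation sweeps of the pipeline: against P1
the distance decreases monotonically over the whole wide range (the
imprint lies past its top), so opening the hinge genuinely improves
complementarity and the recovered Pearson r is negative (mean ≈ −0.8
across seeds, comparable in sign and magnitude to ensemble experiments on
real kinase pockets); against P2 the curve has its minimum at ≈ 6.5 Å, and
the narrow band straddles that optimum, where the derivative vanishes and
the correlation is noise-dominated (mean r ≈ 0). Each preset is therefore
diagnosed against the pocket imprinted from its own conformational regime —
wide vs P1, narrow vs P2; the other two cells of the 2 × 2 design are
reported too (narrow vs P1 is weakly negative, wide vs P2 positive past the
optimum), and all four follow from the generator's geometry.

**What passing does and does not show.** The closed loop demonstrates that
the pipeline recovers a known geometric complementarity signal through
every stage (generator → surface → expansion → metric → statistics), with
correct nulls under shuffling and at-optimum ensembles. It does not
demonstrate force-field realism, solvation, protonation effects, or
anything about a particular protein: the toy receptor does not attempt any
real fold, and the electrostatic model is a screened Coulomb stand-in.

## Numerical edge cases

- Zero descriptor vectors make cosine distance undefined: an error, never 0.
- Surface points coincident with an atom centre clamp the Coulomb distance
  at 0.5 Å (one warning per patch).
- Single-voxel support cannot be scale-normalized: an error.
- Pocket volume is the count of empty voxels inside the convex hull of the
  pocket-lining heavy atoms times the voxel volume; a convex (pocket-free)
  region scores ≈ 0. Degenerate hulls return 0 with a warning.
- Unresolvable pocket residues warn (partial) or raise (none resolvable);
  snapshots with unresolvable pockets are skipped and counted, not dropped
  silently.

## Problem sizes

The test suite and the replicate studies use the scaled-down design
(20 conformers × 50 snapshots, N = 10, 140-residue receptor; 20 seeded
replicates for the sign-recovery check), chosen so the full closed loop
stays inexpensive while every statistic remains well-powered. The rotation
and orthonormality checks run at N = 20 and N = 8 on finer lattices
(0.25 Å and 0.05 ball units respectively).
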