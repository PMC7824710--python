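# zernmatch

Rotation-invariant 3D Zernike descriptors of molecular surfaces, and
shape/electrostatic complementarity statistics over conformer ensembles.

## The problem

When a flexible peptide binds a protein pocket, which property drives the
recognition — the geometric fit of the two surfaces, or their electrostatic
match? A practical way to ask this question quantitatively is to describe
each candidate surface with a compact rotation-invariant fingerprint, score
surface pairs by the distance between fingerprints, and examine how those
scores distribute over the conformations that both partners explore in
solution. `zernmatch` implements this pipeline for structures in PDB/PQR
form: residue-defined binding pockets on a receptor (e.g. the kinase-domain
pockets of a MAP2K, given as UniProt residue-number lists) matched against
whole-surface descriptions of small-ligand conformers, across hundreds of
snapshot structures standing in for molecular-dynamics frames.

## The method

A scalar field f(r, θ, φ) sampled on a voxel grid — the molecular surface
occupancy, or the magnitude of the surface electrostatic potential of one
sign — is mapped into the unit ball and expanded in the orthonormal 3D
Zernike basis

    f(r, θ, φ) = Σₙ Σₗ Σₘ C_nlm · Z_nlm(r, θ, φ),     Z_nlm = R_nl(r) · Y_lm(θ, φ),

valid for 0 ≤ l ≤ n with n − l even. The rotation-invariant descriptors are
the per-(n, l) norms over m,

    D_nl = ‖C_nl·‖ = sqrt( Σₘ |C_nlm|² ),

a vector of **121** components at the default truncation order N = 20.
Complementarity between surfaces A and B is the cosine distance
D(x, y) = 1 − x·y/(|x||y|) between their descriptor vectors:

    [A−B]shape = D(X_A^shape, X_B^shape)
    [A−B]elec  = ½ [ D(X_A^elec+, X_B^elec−) + D(X_A^elec−, X_B^elec+) ]

(electrostatics is compared **cross-sign**: the positive patch of one
partner should mirror the negative patch of the other). Smaller distance
means higher complementarity. On top of the all-vs-all conformer × snapshot
distance tables, the package provides two-sample Kolmogorov–Smirnov
comparisons between ligand ensembles, the Pearson correlation between each
conformer's aromatic ring separation and its shape distance, and the
standard trajectory metrics (backbone RMSD, radius of gyration, per-residue
RMSF, grid-based pocket volume).

Because no structures or trajectories ship with the package, a synthetic
data module generates every input with embedded ground truth: a globular
pseudo-protein with two pockets carved as negative imprints of a two-ring
ligand at known ring separations, and hinged ligand ensembles whose
aromatic-centroid distance follows a programmed schedule ("wide" and
"narrow" presets emulating an i, i+2 versus i, i+1 aromatic arrangement).

## Worked example

```python
from zernmatch import ComplementarityAnalysis

model = ComplementarityAnalysis.from_synthetic(seed=7, n_conformers=10, n_snapshots=10)
results = model.fit()
print(results.summary())
```

prints

```
Surface complementarity matching study
======================================================
order N=10  spacing=0.5 A  probe=0.0 A  cutoff=3.0 A
snapshots: 10   conformers: {'wide': 10, 'narrow': 10}

median distances by (ligand set, pocket):
                     shape_distance  elec_distance
  ligand_set pocket
  narrow     P1              0.0789            NaN
             P2              0.0113            NaN
  wide       P1              0.0499            NaN
             P2              0.0394            NaN

KS tests (shape channel):
  wide vs narrow @ P1: D=0.570  p=2.46e-15
  wide vs narrow @ P2: D=0.870  p=1.95e-39

aromatic distance vs shape distance (median aggregation):
  wide @ P1: r=-0.872  p=0.00102  n=10
  wide @ P2: r=+0.277  p=0.439  n=10
  narrow @ P1: r=-0.320  p=0.368  n=10
  narrow @ P2: r=+0.082  p=0.821  n=10

pairs with undefined electrostatic distance: 400
```

Reading the output: P1 is the pocket carved as the imprint of an *open*
ligand conformer, P2 of a *compact* one. The wide ensemble's shape distances
to P1 anticorrelate strongly with its ring separation (r = −0.87): the wider
the rings spread toward the imprint geometry, the better the surface
complementarity — the behaviour the method is designed to detect. The
narrow ensemble, sitting at the optimum of its matched pocket P2, shows no
correlation (r = +0.08): its shape variation is dominated by degrees of
freedom other than the ring separation. The KS tests confirm the two
ensembles' distance distributions differ. Electrostatic distances are
undefined here because this configuration computes the shape channel only
(`MatchConfig(channels=("shape", "elec"))` enables both).

For real data, build the model from files instead:

```python
from zernmatch import BUILTIN_POCKETS, ComplementarityAnalysis, MatchConfig, read_structures

ligands = read_structures("peptide_conformers.pdb")      # multi-MODEL PDB
receptor = read_structures("receptor_snapshots.pdb")
model = ComplementarityAnalysis(
    {"peptide": ligands}, receptor,
    {"BP3": BUILTIN_POCKETS["BP3"], "BP4": BUILTIN_POCKETS["BP4"]},
    config=MatchConfig(order=20),
)
```

Charges come from the bundled united-atom table, or from PQR files
(`read_structures(path, "pqr-like")`) produced by PDB2PQR for users who need
force-field-accurate electrostatics.

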