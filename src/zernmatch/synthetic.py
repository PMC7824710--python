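"""Synthetic structures with embedded ground truth for closed-loop testing.

Nothing in this package requires real crystal structures, MD trajectories or
docking runs: this module generates every input the pipeline consumes.

* :func:`make_toy_receptor` builds a globular pseudo-protein (alanine-like
  residues packed on a Fibonacci ball lattice) and carves two two-lobed
  binding pockets into its surface.  Each pocket is the negative imprint of a
  two-ring ligand at a known ring-ring separation, so pocket/ligand
  complementarity has a controllable geometric ground truth.
* :func:`make_hinged_ligand_ensemble` emulates a D-tripeptide with two
  aromatic rings whose centroid separation follows a programmed schedule —
  the "wide" preset spans open and compact conformers (an i, i+2 aromatic
  arrangement), the "narrow" preset only compact ones (i, i+1).
* :func:`make_complementary_pair` builds a spherical-cap bump surface and its
  negative-image cavity, the analytic oracle for the shape metric.
* :func:`make_charged_plate_pair` builds flat patches with known-sign
  potential regions, the oracle for the cross-sign electrostatic metric.

All generators are deterministic for a fixed seed, and every generated
object carries the parameters that produced it in its metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .charges import assign_charges_radii
from .structures import ConformerEnsemble, PocketDefinition, Structure
from .surface import SurfacePatch, VoxelGrid

__all__ = [
    "PRESETS",
    "ToyEnsembleSpec",
    "ensemble_spec_preset",
    "make_charged_plate_pair",
    "make_complementary_pair",
    "make_hinged_ligand_ensemble",
    "make_receptor_snapshots",
    "make_toy_receptor",
    "receptor_pockets",
    "write_ground_truth",
]

#: Aromatic-ring centroid distance ranges (Angstrom) for the two peptide
#: emulations: "wide" spans compact through open conformers (the ligand's two
#: ring lobes separate at the top of the range), "narrow" stays compact.
PRESETS: dict[str, tuple[float, float]] = {
    "wide": (4.0, 12.0),
    "narrow": (6.2, 6.8),
}

# Ring geometry shared by ligand lobes and pocket imprints.  The socket
# radius is the ring radius plus a carbon van der Waals radius plus a small
# clearance, so each carved socket is the negative image of one ring lobe of
# the ligand's bare (probe-free) molecular surface.
_RING_RADIUS = 1.4
_LOBE_SOCKET_RADIUS = 3.4


@dataclass
class ToyEnsembleSpec:
    """Study-design parameters for a synthetic matching experiment.

    The full-scale design matches 60 ligand conformers against 500 receptor
    snapshots; the default here is the scaled-down 20 x 50 used throughout
    the test suite (the full size is a config choice away).
    """

    n_ligand_conformers: int = 20
    n_receptor_snapshots: int = 50
    hinge_distance_range: tuple[float, float] = PRESETS["wide"]
    noise_sigma: float = 0.25
    bend_sigma_deg: float = 40.0
    ring_tilt_sigma_deg: float = 30.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.hinge_distance_range
        if self.n_ligand_conformers < 1 or self.n_receptor_snapshots < 1:
            raise ValueError("ensemble counts must be >= 1")
        if not lo < hi:
            raise ValueError("hinge_distance_range must be an increasing interval")
        if min(self.noise_sigma, self.bend_sigma_deg, self.ring_tilt_sigma_deg) < 0:
            raise ValueError("noise parameters must be non-negative")


def ensemble_spec_preset(preset: str, **overrides) -> ToyEnsembleSpec:
    """Spec with the hinge range of a named preset ('wide' or 'narrow')."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = {"hinge_distance_range": PRESETS[preset]}
    kwargs.update(overrides)
    return ToyEnsembleSpec(**kwargs)


# ---------------------------------------------------------------------------
# Toy receptor


def _fibonacci_ball(n: int, radius: float) -> np.ndarray:
    """~Uniform points in a ball: golden-spiral directions, cubic-root radii."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i
    dirs = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    radii = radius * ((i + 0.5) / n) ** (1.0 / 3.0)
    # shells and spiral interleave -> roughly constant nearest-neighbour spacing
    return dirs[np.argsort(theta % (2 * np.pi))] * radii[:, None]


_RESIDUE_OFFSETS = {
    "N": np.array([1.15, 0.45, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([-1.0, 0.8, 0.3]),
    "O": np.array([-1.3, 1.8, 0.6]),
    "CB": np.array([0.0, -1.2, 0.8]),
}


def _socket_centers(radius: float, axis: np.ndarray, tangent: np.ndarray, separation: float):
    """Two points on the sphere of *radius* with chord distance *separation*."""
    if separation >= 2 * radius:
        raise ValueError(
            f"imprint separation {separation} A does not fit on a receptor of radius {radius:.1f} A"
        )
    alpha = np.arcsin(separation / (2.0 * radius))
    c1 = radius * (np.cos(alpha) * axis + np.sin(alpha) * tangent)
    c2 = radius * (np.cos(alpha) * axis - np.sin(alpha) * tangent)
    return c1, c2


def make_toy_receptor(
    seed: int,
    n_residues: int = 140,
    pocket_imprint_distances: tuple[float, float] | None = None,
    socket_radius: float = _LOBE_SOCKET_RADIUS,
) -> Structure:
    """Globular pseudo-protein with two concave, two-lobed binding pockets.

    Residues (alanine-like: N, CA, C, O, CB) are packed on a Fibonacci ball
    lattice; two pockets are carved on opposite faces by pushing atoms out of
    a pair of "socket" spheres whose centre separation is the pocket's
    imprint distance — the ring-ring distance of the ligand conformer whose
    negative image the pocket is.  Pocket-lining residue numbers and imprint
    distances are recorded in the returned structure's metadata.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues for a carvable globule")
    rng = np.random.default_rng(seed)
    radius = 2.05 * n_residues ** (1.0 / 3.0)
    if pocket_imprint_distances is None:
        # scale with receptor size: P1 imprints an open conformer (so the
        # socket separation sits past the top of the wide hinge range at the
        # default 140-residue size, ~16 A), P2 a compact one (~4 A)
        pocket_imprint_distances = (1.5 * radius, 0.38 * radius)
    sites = _fibonacci_ball(n_residues, radius)

    serial, names, elements, res_names, res_numbers, coords = [], [], [], [], [], []
    s = 1
    for ri, site in enumerate(sites, start=1):
        for atom_name, off in _RESIDUE_OFFSETS.items():
            jitter = rng.normal(0.0, 0.15, size=3)
            serial.append(s)
            names.append(atom_name)
            elements.append(atom_name[0])
            res_names.append("ALA")
            res_numbers.append(ri)
            coords.append(site + off + jitter)
            s += 1
    coords = np.array(coords)

    # carve the two pockets: remove atoms inside each socket sphere, leaving a
    # concave bowl lined by the surviving shell atoms
    axes = (np.array([1.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
    tangent = np.array([0.0, 0.0, 1.0])
    pockets: dict[str, dict] = {}
    all_centers = []
    for pname, axis, imprint in zip(("P1", "P2"), axes, pocket_imprint_distances):
        c1, c2 = _socket_centers(radius, axis, tangent, imprint)
        all_centers.append((pname, imprint, c1, c2))
    carved = np.zeros(len(coords), dtype=bool)
    for pname, imprint, c1, c2 in all_centers:
        for c in (c1, c2):
            carved |= np.linalg.norm(coords - c, axis=1) < socket_radius
    keep = ~carved
    coords = coords[keep]
    serial = list(np.arange(1, keep.sum() + 1))
    names = list(np.array(names, dtype=object)[keep])
    elements = list(np.array(elements, dtype=object)[keep])
    res_names = list(np.array(res_names, dtype=object)[keep])
    res_numbers_arr = np.array(res_numbers)[keep]
    for pname, imprint, c1, c2 in all_centers:
        near = np.zeros(len(coords), dtype=bool)
        for c in (c1, c2):
            near |= np.linalg.norm(coords - c, axis=1) < socket_radius + 2.0
        lining = sorted(set(res_numbers_arr[near].tolist()))
        pockets[pname] = {
            "residue_numbers": lining,
            "imprint_distance": float(imprint),
            "socket_centers": [c1.tolist(), c2.tolist()],
            "socket_radius": float(socket_radius),
        }

    structure = Structure(
        serial=np.array(serial, dtype=int),
        name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(res_names, dtype=object),
        res_number=res_numbers_arr,
        chain=np.array(["A"] * len(serial), dtype=object),
        coords=coords,
        metadata={
            "kind": "toy-receptor",
            "seed": int(seed),
            "n_residues": int(n_residues),
            "radius": float(radius),
            "pockets": pockets,
        },
    )
    return assign_charges_radii(structure)


def receptor_pockets(receptor: Structure) -> dict[str, PocketDefinition]:
    """PocketDefinition objects recorded in a toy receptor's metadata."""
    return {
        name: PocketDefinition(name, tuple(info["residue_numbers"]))
        for name, info in receptor.metadata["pockets"].items()
    }


def make_receptor_snapshots(
    receptor: Structure,
    n_snapshots: int = 50,
    noise_sigma: float = 0.25,
    seed: int = 0,
) -> ConformerEnsemble:
    """Jittered copies of a receptor, standing in for MD snapshots."""
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    rng = np.random.default_rng(seed)
    members, meta = [], []
    for i in range(n_snapshots):
        snap = receptor.copy()
        snap.coords = snap.coords + rng.normal(0.0, noise_sigma, size=snap.coords.shape)
        snap.model_index = i
        members.append(snap)
        meta.append({"frame": i, "noise_sigma": float(noise_sigma)})
    return ConformerEnsemble(members, meta)


# ---------------------------------------------------------------------------
# Hinged two-ring ligand


def _ring_atoms(center: np.ndarray, prefix_names, tilt: np.ndarray | None = None):
    """Regular hexagon of carbons around *center*, optionally rigidly rotated.

    A rigid rotation about the ring centre leaves the side-chain centroid --
    and hence the programmed ring-ring distance -- exactly unchanged.
    """
    out = []
    for k, nm in enumerate(prefix_names):
        ang = np.pi / 3.0 * k
        off = _RING_RADIUS * np.array([np.cos(ang), np.sin(ang), 0.0])
        if tilt is not None:
            off = tilt @ off
        out.append((nm, "C", center + off))
    return out


_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _random_rotation(rng, sigma_deg: float) -> np.ndarray:
    """Small random rotation: angle ~ N(0, sigma), uniform random axis."""
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, sigma_deg))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _build_ligand_conformer(
    d: float,
    rng=None,
    sigma: float = 0.0,
    bend_sigma_deg: float = 0.0,
    ring_tilt_sigma_deg: float = 0.0,
) -> Structure:
    """Three-residue ligand: ring / charged linker / ring, ring-ring distance d.

    The two rings are residues 1 and 3 (phenyl-like hexagons whose side-chain
    heavy-atom centroid is exactly the ring centre); residue 2 carries a
    short basic stub (+1), giving the electrostatic channel a signal while
    leaving the two rings to dominate the molecular shape.

    Conformational variability has three parts, emulating the thermal motion
    of a flexible peptide: a random bend of the inter-ring axis and rigid
    tilts of each ring (both of which change the molecular shape but preserve
    the centroid-centroid distance exactly), plus isotropic per-atom jitter
    of scale *sigma*.  With all three at zero the realized centroid distance
    equals *d* exactly.
    """
    atoms: list[tuple[str, str, str, int, np.ndarray]] = []

    def add(res_name, res_number, entries):
        for nm, el, pos in entries:
            atoms.append((nm, el, res_name, res_number, pos))

    # inter-ring axis: x, optionally bent by a random polar angle
    u = np.array([1.0, 0.0, 0.0])
    if rng is not None and bend_sigma_deg > 0:
        theta = np.deg2rad(rng.normal(0.0, bend_sigma_deg))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array(
            [np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
        )
    c_a = np.zeros(3)
    c_b = d * u
    tilt_a = tilt_b = None
    if rng is not None and ring_tilt_sigma_deg > 0:
        tilt_a = _random_rotation(rng, ring_tilt_sigma_deg)
        tilt_b = _random_rotation(rng, ring_tilt_sigma_deg)
    # stub direction: perpendicular to the inter-ring axis; its azimuth about
    # that axis is a free torsion (another distance-preserving shape DOF)
    down = np.array([0.0, -1.0, 0.0])
    p = down - np.dot(down, u) * u
    p = p / np.linalg.norm(p) if np.linalg.norm(p) > 1e-6 else np.array([0.0, 0.0, -1.0])
    if rng is not None and (bend_sigma_deg > 0 or ring_tilt_sigma_deg > 0):
        from scipy.spatial.transform import Rotation

        p = Rotation.from_rotvec(rng.uniform(0.0, 2.0 * np.pi) * u).as_matrix() @ p
    mid = (c_a + c_b) / 2.0 + 1.8 * p
    t = np.cross(u, p)  # third local axis, for the backbone N/O flanks

    add("PHE", 1, _ring_atoms(c_a, _RING_NAMES, tilt_a))
    add("PHE", 1, [("CA", "C", c_a + 2.4 * p)])
    # the stub carries the +1 amine; backbone N and carbonyl O give the
    # molecule negative partial charge so both potential signs exist
    lys = [
        ("N", "N", mid - 1.2 * t),
        ("CA", "C", mid),
        ("O", "O", mid + 1.2 * t),
        ("CE", "C", mid + 1.2 * p),
        ("NZ", "N", mid + 2.2 * p),
    ]
    add("LYS", 2, lys)
    add("PHE", 3, _ring_atoms(c_b, _RING_NAMES, tilt_b))
    add("PHE", 3, [("CA", "C", c_b + 2.4 * p)])
    if rng is not None and sigma > 0:
        atoms = [
            (nm, el, rn, ri, pos + rng.normal(0.0, sigma, size=3))
            for nm, el, rn, ri, pos in atoms
        ]

    structure = Structure(
        serial=np.arange(1, len(atoms) + 1),
        name=np.array([a[0] for a in atoms], dtype=object),
        element=np.array([a[1] for a in atoms], dtype=object),
        res_name=np.array([a[2] for a in atoms], dtype=object),
        res_number=np.array([a[3] for a in atoms], dtype=int),
        chain=np.array(["L"] * len(atoms), dtype=object),
        coords=np.array([a[4] for a in atoms]),
        metadata={"kind": "hinged-ligand", "aromatic_residues": (1, 3)},
    )
    return assign_charges_radii(structure)


def make_hinged_ligand_ensemble(spec: ToyEnsembleSpec) -> ConformerEnsemble:
    """Conformer ensemble with a programmed ring-centroid distance schedule.

    The schedule is a uniform sweep of the hinge range; Gaussian coordinate
    jitter of ``spec.noise_sigma`` is applied on top, so realized centroid
    distances scatter around the schedule.  The programmed distance is stored
    per conformer as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.hinge_distance_range
    schedule = np.linspace(lo, hi, spec.n_ligand_conformers)
    any_noise = max(spec.noise_sigma, spec.bend_sigma_deg, spec.ring_tilt_sigma_deg) > 0
    members, meta = [], []
    for i, d in enumerate(schedule):
        s = _build_ligand_conformer(
            float(d),
            rng=rng if any_noise else None,
            sigma=spec.noise_sigma,
            bend_sigma_deg=spec.bend_sigma_deg,
            ring_tilt_sigma_deg=spec.ring_tilt_sigma_deg,
        )
        s.model_index = i
        s.metadata["programmed_distance"] = float(d)
        members.append(s)
        meta.append({"frame": i, "programmed_distance": float(d)})
    return ConformerEnsemble(members, meta)


# ---------------------------------------------------------------------------
# Analytic bump / cavity oracle


def make_complementary_pair(
    radius: float, grid_spacing: float = 0.5
) -> tuple[VoxelGrid, VoxelGrid]:
    """Spherical-cap bump surface and its negative-image cavity surface.

    The bump is a slab with a half-ball of the given radius on top; the
    cavity is the complementary block with the matching half-ball removed.
    Both are returned as surface-shell voxel grids restricted to a fixed
    region of interest around the interface, so that a bump and the cavity
    carved at the *same* radius expose congruent surfaces (the shared
    spherical cap plus the flat annulus), while mismatched radii do not.
    """
    if radius <= 0 or grid_spacing <= 0:
        raise ValueError("radius and spacing must be positive")
    if grid_spacing > radius / 4.0:
        raise ValueError(
            f"spacing {grid_spacing} too coarse for radius {radius}; "
            f"need spacing <= {radius / 4.0:.3f} A"
        )
    half = 9.0
    depth = radius + 2.0  # block thickness on either side of the interface
    roi = 8.5
    h = grid_spacing

    def build(kind: str) -> VoxelGrid:
        if kind == "bump":
            z0, z1 = -depth - 1.0, radius + 1.0
        else:
            z0, z1 = -1.0, depth + 1.0
        ax_xy = np.arange(-half - 1.0, half + 1.0 + h / 2, h)
        ax_z = np.arange(z0, z1 + h / 2, h)
        X, Y, Z = np.meshgrid(ax_xy, ax_xy, ax_z, indexing="ij")
        in_box = (np.abs(X) <= half) & (np.abs(Y) <= half)
        ball = X * X + Y * Y + Z * Z <= radius * radius
        # the two solids are mirror-image complements across the z = 0 plane,
        # so their interface-region surface shells are congruent for equal radii
        if kind == "bump":
            occ = (in_box & (Z <= 0) & (Z >= -depth)) | ball
        else:
            occ = in_box & (Z >= 0) & (Z <= depth) & ~ball
        from .surface import surface_mask

        grid = VoxelGrid(
            origin=np.array([ax_xy[0], ax_xy[0], ax_z[0]]),
            spacing=h,
            values=occ.astype(float),
        )
        surf = surface_mask(grid)
        # interface region only: the shared cap plus the flat annulus; the far
        # face of each block is an artifact of the construction, not of the
        # complementary interface, and is excluded
        keep = surf & (X * X + Y * Y <= roi * roi) & (np.abs(Z) <= radius + 1.0)
        return VoxelGrid(origin=grid.origin, spacing=h, values=keep.astype(float))

    return build("bump"), build("cavity")


# ---------------------------------------------------------------------------
# Charged plate oracle


def make_charged_plate_pair(sign_pattern: str) -> tuple[SurfacePatch, SurfacePatch]:
    """Two flat patches with a known sign relation of their potential.

    Each plate carries a positive region and a (smaller) negative region so
    that all four electrostatic channels exist.  With ``sign_pattern
    'opposite'`` the second plate is the sign-flipped copy of the first — a
    perfect cross-sign match; with ``'like'`` it is an identical copy.
    """
    if sign_pattern not in ("opposite", "like"):
        raise ValueError("sign_pattern must be 'opposite' or 'like'")
    h = 0.5
    ax = np.arange(-5.0, 5.0 + h / 2, h)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=1)
    phi = np.where(pts[:, 0] < 1.0, 1.0, -0.6)
    a = SurfacePatch(points=pts, spacing=h, provenance="plate-A", potential=phi)
    phi_b = -phi if sign_pattern == "opposite" else phi.copy()
    b = SurfacePatch(points=pts.copy(), spacing=h, provenance="plate-B", potential=phi_b)
    return a, b


# ---------------------------------------------------------------------------
# Ground-truth sidecar


def write_ground_truth(obj, path) -> None:
    """JSON sidecar with the generation parameters of a synthetic object."""
    if isinstance(obj, ConformerEnsemble):
        payload = {
            "n_members": len(obj),
            "members": obj.metadata,
            "structure_metadata": _jsonable(obj.members[0].metadata),
        }
    elif isinstance(obj, Structure):
        payload = _jsonable(obj.metadata)
    elif isinstance(obj, ToyEnsembleSpec):
        payload = asdict(obj)
    else:
        raise TypeError(f"cannot serialize ground truth for {type(obj)}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    return x
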