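"""Voxelized molecular surfaces, pocket patches and electrostatic mapping.

The surface model is deliberately simple and deterministic: a probe-inflated
union of atomic spheres rasterized on a cubic grid (a solvent-accessible-like
surface), with surface voxels defined as occupied voxels having at least one
empty 6-neighbour.  This avoids triangulated meshes entirely; the Zernike
expansion only needs a sampled scalar field.

Electrostatic potential is a screened Coulomb sum over the assigned point
charges, by default with the distance-dependent dielectric eps(r) = 4r.  The
potential is mapped onto surface points and split by sign into the "elec+"
and "elec-" sub-surfaces whose descriptors are compared cross-sign
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree, Delaunay

__all__ = [
    "SurfacePatch",
    "VoxelGrid",
    "extract_patch",
    "map_potential",
    "pocket_volume",
    "split_by_sign",
    "surface_points",
    "voxelize_surface",
]

MAX_VOXELS_DEFAULT = 40_000_000


@dataclass
class VoxelGrid:
    """Cubic scalar field: origin (Angstrom), spacing (Angstrom), values.

    ``values`` holds occupancy in [0, 1] or any scalar field sampled at voxel
    centres.  Voxel (i, j, k) is centred at ``origin + spacing * (i, j, k)``.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.isfinite(self.values).all():
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self, mask=None) -> np.ndarray:
        """Cartesian centres of voxels where *mask* (default: values != 0)."""
        if mask is None:
            mask = self.values != 0
        idx = np.argwhere(mask)
        return self.origin + self.spacing * idx

    def to_dx(self, path) -> None:
        """Write the grid in OpenDX scalar-field format."""
        nx, ny, nz = self.dims
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*self.origin))
            fh.write(f"delta {self.spacing:.6f} 0 0\n")
            fh.write(f"delta 0 {self.spacing:.6f} 0\n")
            fh.write(f"delta 0 0 {self.spacing:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
            )
            flat = self.values.ravel(order="C")
            for i in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")


@dataclass
class SurfacePatch:
    """A set of surface sample points, optionally carrying potential values.

    ``label`` is one of ``shape``, ``elec+``, ``elec-``; ``provenance`` names
    the pocket (or ``whole-ligand``).  For the electrostatic channels,
    ``values`` holds the per-point function value fed to the Zernike
    expansion (|phi|, optionally rescaled to [0, 1]).
    """

    points: np.ndarray
    spacing: float
    label: str = "shape"
    provenance: str = "whole-ligand"
    potential: np.ndarray | None = None
    values: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.potential is not None:
            self.potential = np.asarray(self.potential, dtype=float)
            if self.potential.shape[0] != self.points.shape[0]:
                raise ValueError("potential length mismatch")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def is_empty(self) -> bool:
        return self.n_points == 0

    def function_values(self) -> np.ndarray:
        """Per-point field value for the Zernike expansion (1 for shape)."""
        if self.values is not None:
            return self.values
        return np.ones(self.n_points)


def voxelize_surface(
    structure,
    spacing: float = 0.5,
    probe: float = 1.4,
    *,
    pad: float = 1.0,
    max_voxels: int = MAX_VOXELS_DEFAULT,
) -> VoxelGrid:
    """Rasterize the probe-inflated union of atomic spheres.

    Returns a binary occupancy grid; heavy atoms only.  Radii must already be
    assigned on the structure.
    """
    if structure.n_atoms == 0:
        raise ValueError("structure has no atoms")
    if not (0.2 < spacing < 2.0):
        raise ValueError(f"spacing {spacing} outside the supported (0.2, 2.0) range")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if structure.radius is None:
        raise ValueError("structure has no radii; assign charges/radii first")
    heavy = structure.heavy_mask
    coords = structure.coords[heavy]
    radii = structure.radius[heavy] + probe
    lo = (coords - radii[:, None]).min(axis=0) - pad
    hi = (coords + radii[:, None]).max(axis=0) + pad
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(dims)) > max_voxels:
        needed = (np.prod(hi - lo) / max_voxels) ** (1 / 3)
        raise ValueError(
            f"grid of {np.prod(dims)} voxels exceeds budget {max_voxels}; "
            f"try spacing >= {needed:.2f} A"
        )
    occ = np.zeros(tuple(dims), dtype=bool)
    # Per-atom local sub-grid stamping keeps memory bounded.
    for c, r in zip(coords, radii):
        i0 = np.maximum(np.floor((c - r - lo) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((c + r - lo) / spacing).astype(int) + 1, dims)
        ax = [lo[d] + spacing * np.arange(i0[d], i1[d]) - c[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        occ[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= d2 <= r * r
    return VoxelGrid(origin=lo, spacing=spacing, values=occ.astype(np.float64))


def surface_mask(grid: VoxelGrid) -> np.ndarray:
    """Occupied voxels with at least one empty 6-neighbour."""
    occ = grid.values > 0.5
    eroded = ndimage.binary_erosion(occ, structure=ndimage.generate_binary_structure(3, 1))
    return occ & ~eroded


def surface_points(grid: VoxelGrid) -> np.ndarray:
    """Cartesian coordinates of all surface voxels of an occupancy grid."""
    return grid.voxel_centers(surface_mask(grid))


def extract_patch(
    grid: VoxelGrid,
    structure,
    pocket=None,
    cutoff: float = 6.0,
) -> SurfacePatch:
    """Surface voxels within *cutoff* of any pocket-residue heavy atom.

    With ``pocket=None`` (whole-ligand mode) the entire surface is returned:
    small peptide ligands contribute their full surface rather than a patch.
    """
    from .structures import select_pocket_atoms

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pts = surface_points(grid)
    if pocket is None:
        return SurfacePatch(points=pts, spacing=grid.spacing, provenance="whole-ligand")
    sel = select_pocket_atoms(structure, pocket)
    anchors = sel.coords[sel.heavy_mask]
    tree = cKDTree(anchors)
    d, _ = tree.query(pts, k=1)
    keep = d <= cutoff
    if not keep.any():
        raise ValueError(
            f"pocket {pocket.name!r}: no surface voxels within {cutoff} A; "
            "increase the cutoff"
        )
    return SurfacePatch(points=pts[keep], spacing=grid.spacing, provenance=pocket.name)


def map_potential(
    patch: SurfacePatch,
    structure,
    model: str = "coulomb_ddd",
    *,
    clamp: float = 0.5,
) -> SurfacePatch:
    """Evaluate the point-charge electrostatic potential at each patch point.

    ``coulomb_ddd`` uses the distance-dependent dielectric eps(r) = 4r, so
    phi(x) = sum_i q_i / (4 r_i^2); ``coulomb_uniform`` uses eps = 1.
    Distances below *clamp* (Angstrom) are clamped, with a single warning per
    patch, to avoid the point-charge singularity.
    """
    if model not in ("coulomb_ddd", "coulomb_uniform"):
        raise ValueError(f"unknown potential model {model!r}")
    if structure.charge is None:
        raise ValueError("structure has no charges; assign charges first")
    pts = patch.points
    phi = np.zeros(pts.shape[0])
    clamped = False
    # chunk over atoms to bound the distance-matrix memory
    q = structure.charge
    xyz = structure.coords
    step = max(1, int(5e7 // max(pts.shape[0], 1)))
    for a0 in range(0, xyz.shape[0], step):
        d = np.linalg.norm(pts[:, None, :] - xyz[None, a0 : a0 + step, :], axis=2)
        if (d < clamp).any():
            clamped = True
        d = np.maximum(d, clamp)
        if model == "coulomb_ddd":
            phi += (q[a0 : a0 + step] / (4.0 * d * d)).sum(axis=1)
        else:
            phi += (q[a0 : a0 + step] / d).sum(axis=1)
    if clamped:
        warnings.warn("patch points within clamp distance of atom centres; clamped", stacklevel=2)
    return SurfacePatch(
        points=pts,
        spacing=patch.spacing,
        label=patch.label,
        provenance=patch.provenance,
        potential=phi,
        flags=dict(patch.flags),
    )


def split_by_sign(patch: SurfacePatch, *, normalize_magnitude: bool = True):
    """Partition a potential-mapped patch into elec+ and elec- sub-surfaces.

    Zero-potential points belong to neither side.  Each sub-surface carries
    |phi| as its function value, linearly rescaled to [0, 1] per patch when
    *normalize_magnitude* (the default), which makes the downstream cosine
    metric insensitive to the overall potential scale.
    """
    if patch.potential is None:
        raise ValueError("patch has no mapped potential")
    phi = patch.potential
    out = []
    for label, mask in (("elec+", phi > 0), ("elec-", phi < 0)):
        mag = np.abs(phi[mask])
        if normalize_magnitude and mag.size and mag.max() > 0:
            mag = mag / mag.max()
        out.append(
            SurfacePatch(
                points=patch.points[mask],
                spacing=patch.spacing,
                label=label,
                provenance=patch.provenance,
                potential=phi[mask],
                values=mag,
                flags={"empty": not mask.any(), **patch.flags},
            )
        )
    return out[0], out[1]


def pocket_volume(grid: VoxelGrid, structure, pocket) -> float:
    """Grid-based pocket volume in cubic Angstrom.

    The pocket region is the convex hull of the pocket residues' heavy atoms;
    the volume is the count of unoccupied voxels inside that hull times the
    voxel volume.  A convex surface with no cavity therefore scores ~0.
    """
    from .structures import select_pocket_atoms

    sel = select_pocket_atoms(structure, pocket)
    anchors = sel.coords[sel.heavy_mask]
    if anchors.shape[0] < 4:
        warnings.warn("fewer than 4 pocket atoms; volume undefined, returning 0")
        return 0.0
    try:
        hull = Delaunay(anchors)
    except Exception:
        warnings.warn("degenerate pocket geometry; returning 0")
        return 0.0
    empty = grid.values <= 0.5
    idx = np.argwhere(empty)
    if idx.size == 0:
        return 0.0
    centers = grid.origin + grid.spacing * idx
    inside = hull.find_simplex(centers) >= 0
    n = int(inside.sum())
    if n == 0:
        warnings.warn("no empty voxels inside the pocket region")
    return n * grid.spacing**3
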