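"""3D Zernike moments and rotation-invariant shape descriptors.

A scalar field f(r, theta, phi) supported on the unit ball is expanded in the
orthonormal 3D Zernike basis

    Z_nlm(r, theta, phi) = R_nl(r) * Y_lm(theta, phi),

valid for 0 <= l <= n with n - l even, where Y_lm are orthonormal complex
spherical harmonics (Condon-Shortley phase) and the radial part is built from
Jacobi polynomials:

    R_nl(r) = sqrt((4*pi/3) * (2n+3)) * r^l * P_k^(0, l+1/2)(2 r^2 - 1),

with k = (n - l) / 2.  Under the inner product (3 / 4 pi) * integral over the
unit ball, this basis is orthonormal, so the moments are

    C_nlm = (3 / 4 pi) * sum_voxels f(x) * conj(Z_nlm(x)) * h^3

(direct numerical quadrature on the voxel grid).  The rotation-invariant
descriptors are per-(n, l) norms over m:

    D_nl = sqrt( sum_m |C_nlm|^2 ),

a vector of 121 components at the default truncation order N = 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_jacobi, sph_harm_y

from .surface import SurfacePatch, VoxelGrid

__all__ = [
    "NormalizedGrid",
    "ZernikeDescriptor",
    "ZernikeMoments",
    "compute_moments",
    "descriptor_from_patch",
    "descriptor_index_set",
    "invariants_from_moments",
    "normalize_to_unit_ball",
    "patch_to_grid",
    "reconstruct",
]

DEFAULT_ORDER = 20
DEFAULT_SCALE_MARGIN = 0.6


def descriptor_index_set(N: int) -> list[tuple[int, int]]:
    """All valid (n, l) index pairs up to order *N*, lexicographically sorted.

    Validity: 0 <= n <= N, 0 <= l <= n, n - l even.  At N = 20 there are
    exactly 121 pairs, hence 121 invariant descriptors.
    """
    if N < 0:
        raise ValueError("order N must be non-negative")
    return [(n, l) for n in range(N + 1) for l in range(n % 2, n + 1, 2)]


def moment_index_set(N: int) -> list[tuple[int, int, int]]:
    """All valid (n, l, m) triples up to order *N* (full -l..l range of m)."""
    return [
        (n, l, m)
        for (n, l) in descriptor_index_set(N)
        for m in range(-l, l + 1)
    ]


@dataclass
class NormalizedGrid:
    """A voxel grid mapped into the unit ball, with its normalization record."""

    grid: VoxelGrid
    center: np.ndarray
    scale: float
    scale_margin: float

    def support(self):
        """(points, values, voxel_volume) of nonzero voxels inside the ball."""
        mask = self.grid.values != 0
        pts = self.grid.voxel_centers(mask)
        vals = self.grid.values[mask]
        r = np.linalg.norm(pts, axis=1)
        keep = r < 1.0
        return pts[keep], vals[keep], self.grid.spacing**3


@dataclass
class ZernikeMoments:
    """Complex Zernike moments C_nlm for one channel of one patch."""

    order: int
    values: np.ndarray  # complex, aligned with moment_index_set(order)
    channel: str = "shape"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = len(moment_index_set(self.order))
        if self.values.shape[0] != expected:
            raise ValueError(
                f"expected {expected} moments for order {self.order}, got {self.values.shape[0]}"
            )

    def as_dict(self) -> dict[tuple[int, int, int], complex]:
        return dict(zip(moment_index_set(self.order), self.values))


@dataclass
class ZernikeDescriptor:
    """Rotation-invariant descriptor vector D_nl for one channel."""

    order: int
    values: np.ndarray  # aligned with descriptor_index_set(order)
    channel: str = "shape"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = len(descriptor_index_set(self.order))
        if self.values.shape[0] != expected:
            raise ValueError(
                f"expected {expected} descriptors for order {self.order}, "
                f"got {self.values.shape[0]}"
            )
        if (self.values < -1e-12).any():
            raise ValueError("descriptors must be non-negative")

    def __len__(self):
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("n\tl\tD_nl\n")
            for (n, l), v in zip(descriptor_index_set(self.order), self.values):
                fh.write(f"{n}\t{l}\t{v:.10e}\n")


# ---------------------------------------------------------------------------
# Normalization


def normalize_to_unit_ball(
    grid: VoxelGrid, scale_margin: float = DEFAULT_SCALE_MARGIN
) -> NormalizedGrid:
    """Centre a grid's support on its centre of mass and scale into the ball.

    The farthest support voxel lands at radius *scale_margin* (< 1); keeping
    the support away from r = 1 avoids the degradation of the Zernike basis
    near the ball boundary.  The transform is recorded so descriptors are
    reproducible and comparable.
    """
    if not (0 < scale_margin < 1):
        raise ValueError("scale_margin must lie in (0, 1)")
    mask = grid.values != 0
    n_support = int(mask.sum())
    if n_support == 0:
        raise ValueError("grid has empty support")
    if n_support == 1:
        raise ValueError("single-voxel support cannot be scale-normalized")
    pts = grid.voxel_centers(mask)
    w = np.abs(grid.values[mask])
    center = (pts * w[:, None]).sum(axis=0) / w.sum()
    rmax = np.linalg.norm(pts - center, axis=1).max()
    scale = scale_margin / rmax
    out = VoxelGrid(
        origin=(grid.origin - center) * scale,
        spacing=grid.spacing * scale,
        values=grid.values,
    )
    return NormalizedGrid(grid=out, center=center, scale=scale, scale_margin=scale_margin)


def patch_to_grid(patch: SurfacePatch) -> VoxelGrid:
    """Rasterize a surface patch back onto its native voxel lattice.

    Patch points are voxel centres, so this is exact; point values (1 for the
    shape channel, |phi| for electrostatic channels) become voxel values.
    """
    if patch.is_empty:
        raise ValueError("cannot rasterize an empty patch")
    h = patch.spacing
    lo = patch.points.min(axis=0)
    idx = np.rint((patch.points - lo) / h).astype(int)
    dims = idx.max(axis=0) + 1
    values = np.zeros(tuple(dims))
    values[idx[:, 0], idx[:, 1], idx[:, 2]] = patch.function_values()
    return VoxelGrid(origin=lo, spacing=h, values=values)


# ---------------------------------------------------------------------------
# Moments


def _radial(n: int, l: int, r: np.ndarray) -> np.ndarray:
    k = (n - l) // 2
    return (
        np.sqrt((4.0 * np.pi / 3.0) * (2 * n + 3))
        * r**l
        * eval_jacobi(k, 0.0, l + 0.5, 2.0 * r * r - 1.0)
    )


def compute_moments(normalized: NormalizedGrid, N: int = DEFAULT_ORDER) -> ZernikeMoments:
    """Zernike moments of a normalized grid by direct voxel quadrature.

    C_nlm = (3 / 4 pi) * sum_i f_i * conj(Z_nlm(x_i)) * h^3 over support
    voxels strictly inside the unit ball.
    """
    if not isinstance(normalized, NormalizedGrid):
        raise TypeError("compute_moments requires a NormalizedGrid; call normalize_to_unit_ball first")
    if N < 0:
        raise ValueError("order N must be non-negative")
    pts, vals, h3 = normalized.support()
    nlm = moment_index_set(N)
    out = np.zeros(len(nlm), dtype=complex)
    if pts.shape[0] == 0:
        return ZernikeMoments(order=N, values=out)
    r = np.linalg.norm(pts, axis=1)
    rsafe = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(pts[:, 2] / rsafe, -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    prefac = 3.0 / (4.0 * np.pi) * h3
    # offsets of each (n, l) block inside the flat (n, l, m) layout
    offsets = {}
    pos = 0
    for (n, l) in descriptor_index_set(N):
        offsets[(n, l)] = pos
        pos += 2 * l + 1
    for l in range(N + 1):
        ns = [n for n in range(l, N + 1) if (n - l) % 2 == 0]
        if not ns:
            continue
        # conj(Y_lm) * f for m = 0..l; negative m via conjugate symmetry
        Y = np.stack([sph_harm_y(l, m, theta, phi) for m in range(l + 1)])
        W = vals[None, :] * np.conj(Y)  # (l+1, P)
        R = np.stack([_radial(n, l, r) for n in ns])  # (len(ns), P)
        block = prefac * (R @ W.T)  # (len(ns), l+1) -> C_nl,m for m >= 0
        for bi, n in enumerate(ns):
            off = offsets[(n, l)]
            for m in range(l + 1):
                c = block[bi, m]
                out[off + l + m] = c
                if m > 0:
                    # real input: C_{n,l,-m} = (-1)^m conj(C_{n,l,m})
                    out[off + l - m] = (-1) ** m * np.conj(c)
    return ZernikeMoments(
        order=N,
        values=out,
        metadata={
            "center": np.asarray(normalized.center).tolist(),
            "scale": float(normalized.scale),
            "scale_margin": float(normalized.scale_margin),
        },
    )


def invariants_from_moments(moments: ZernikeMoments) -> ZernikeDescriptor:
    """Reduce moments to rotation invariants: D_nl = sqrt(sum_m |C_nlm|^2)."""
    N = moments.order
    pairs = descriptor_index_set(N)
    vals = np.empty(len(pairs))
    pos = 0
    for i, (n, l) in enumerate(pairs):
        block = moments.values[pos : pos + 2 * l + 1]
        vals[i] = np.sqrt((np.abs(block) ** 2).sum())
        pos += 2 * l + 1
    return ZernikeDescriptor(
        order=N, values=vals, channel=moments.channel, metadata=dict(moments.metadata)
    )


def evaluate_basis(n: int, l: int, m: int, points: np.ndarray) -> np.ndarray:
    """Sample Z_nlm at Cartesian points inside the unit ball."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    r = np.linalg.norm(points, axis=1)
    rsafe = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(points[:, 2] / rsafe, -1.0, 1.0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    if m >= 0:
        Y = sph_harm_y(l, m, theta, phi)
    else:
        Y = (-1) ** (-m) * np.conj(sph_harm_y(l, -m, theta, phi))
    return _radial(n, l, r) * Y


def reconstruct(moments: ZernikeMoments, shape: tuple[int, int, int]) -> VoxelGrid:
    """Truncated reconstruction f = sum C_nlm * Z_nlm on a [-1, 1]^3 grid.

    The imaginary part of the sum vanishes for conjugate-symmetric moments;
    the real part is returned.  Reconstruction error on smooth inputs
    decreases with the truncation order.
    """
    dims = np.asarray(shape, dtype=int)
    spacing = 2.0 / (dims.max() - 1) if dims.max() > 1 else 2.0
    origin = -spacing * (dims - 1) / 2.0
    axes = [origin[d] + spacing * np.arange(dims[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = np.linalg.norm(pts, axis=1) < 1.0
    fld = np.zeros(pts.shape[0], dtype=complex)
    pin = pts[inside]
    acc = np.zeros(pin.shape[0], dtype=complex)
    for (n, l, m), c in zip(moment_index_set(moments.order), moments.values):
        if c == 0:
            continue
        acc += c * evaluate_basis(n, l, m, pin)
    fld[inside] = acc
    return VoxelGrid(origin=origin, spacing=spacing, values=fld.real.reshape(tuple(dims)))


# ---------------------------------------------------------------------------
# Convenience pipeline step


def descriptor_from_patch(
    patch: SurfacePatch,
    N: int = DEFAULT_ORDER,
    scale_margin: float = DEFAULT_SCALE_MARGIN,
) -> ZernikeDescriptor:
    """Patch -> grid -> unit-ball normalization -> moments -> invariants."""
    grid = patch_to_grid(patch)
    norm = normalize_to_unit_ball(grid, scale_margin=scale_margin)
    mom = compute_moments(norm, N=N)
    mom.channel = patch.label
    desc = invariants_from_moments(mom)
    desc.metadata["provenance"] = patch.provenance
    return desc
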