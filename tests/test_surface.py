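"""Voxelized surfaces, patches, potential mapping, sign split, pocket volume."""

import numpy as np
import pytest
from scipy import ndimage

from zernmatch import (
    extract_patch,
    map_potential,
    pocket_volume,
    split_by_sign,
    voxelize_surface,
)
from zernmatch.structures import PocketDefinition, Structure
from zernmatch.surface import SurfacePatch, VoxelGrid, surface_points

from conftest import make_chain


def atom_cloud(positions, radius=1.7, res_numbers=None):
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = positions.shape[0]
    res = np.asarray(res_numbers if res_numbers is not None else np.arange(1, n + 1))
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(["CB"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        res_name=np.array(["ALA"] * n, dtype=object),
        res_number=res,
        chain=np.array(["A"] * n, dtype=object),
        coords=positions,
        charge=np.zeros(n),
        radius=np.full(n, float(radius)),
    )


class TestVoxelize:
    def test_single_atom_volume_matches_sphere(self):
        st = atom_cloud([[0, 0, 0]], radius=2.0)
        grid = voxelize_surface(st, spacing=0.25, probe=0.0)
        vol = (grid.values > 0.5).sum() * grid.spacing**3
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 8.0, rel=0.05)

    def test_disjoint_atoms_give_two_components(self):
        st = atom_cloud([[0, 0, 0], [12, 0, 0]])
        grid = voxelize_surface(st, spacing=0.5, probe=0.0)
        _, n = ndimage.label(grid.values > 0.5)
        assert n == 2

    def test_spacing_preconditions(self):
        st = atom_cloud([[0, 0, 0]])
        with pytest.raises(ValueError):
            voxelize_surface(st, spacing=5.0)
        with pytest.raises(ValueError):
            voxelize_surface(st, spacing=0.1)
        with pytest.raises(ValueError):
            voxelize_surface(st, spacing=0.5, probe=-1.0)

    def test_voxel_budget(self):
        st = atom_cloud([[0, 0, 0], [60, 60, 60]])
        with pytest.raises(ValueError, match="spacing"):
            voxelize_surface(st, spacing=0.25, max_voxels=10_000)

    def test_translation_moves_grid_contents(self):
        st = atom_cloud([[0, 0, 0], [3, 0, 0]])
        g0 = voxelize_surface(st, spacing=0.5, probe=0.0)
        g1 = voxelize_surface(st.translated([5.0, 0, 0]), spacing=0.5, probe=0.0)
        assert np.array_equal(g0.values, g1.values)
        assert np.allclose(g1.origin - g0.origin, [5.0, 0, 0])


class TestPatch:
    def test_infinite_cutoff_returns_whole_surface(self, toy_receptor, toy_pockets):
        grid = voxelize_surface(toy_receptor, spacing=0.6, probe=0.0)
        whole = surface_points(grid)
        patch = extract_patch(grid, toy_receptor, toy_pockets["P1"], cutoff=1e6)
        assert patch.n_points == whole.shape[0]

    def test_pocket_patch_is_proper_subset(self, toy_receptor, toy_pockets):
        grid = voxelize_surface(toy_receptor, spacing=0.6, probe=0.0)
        whole = surface_points(grid).shape[0]
        patch = extract_patch(grid, toy_receptor, toy_pockets["P1"], cutoff=4.0)
        assert 0 < patch.n_points < whole

    def test_disjoint_pockets_give_disjoint_patches(self):
        from zernmatch import make_toy_receptor, receptor_pockets

        # full-size receptor: the two carved faces are far apart
        receptor = make_toy_receptor(seed=1, n_residues=140)
        pockets = receptor_pockets(receptor)
        grid = voxelize_surface(receptor, spacing=0.6, probe=0.0)
        p1 = extract_patch(grid, receptor, pockets["P1"], cutoff=3.0)
        p2 = extract_patch(grid, receptor, pockets["P2"], cutoff=3.0)
        a = {tuple(np.round(p, 3)) for p in p1.points}
        b = {tuple(np.round(p, 3)) for p in p2.points}
        assert not (a & b)

    def test_empty_patch_is_error(self):
        st = atom_cloud([[0, 0, 0], [40, 0, 0]], res_numbers=[1, 2])
        grid = voxelize_surface(st, spacing=0.6, probe=0.0)
        # residue 2 exists but give a cutoff so small nothing is within reach
        far = PocketDefinition("far", (2,))
        st2 = st.copy()
        st2.coords[1] = [0.0, 0.0, 0.0]  # selection anchor away from surface
        with pytest.raises(ValueError, match="cutoff"):
            extract_patch(grid, st2, far, cutoff=0.05)


class TestPotential:
    def test_zero_charges_zero_potential(self):
        st = atom_cloud([[0, 0, 0]])
        patch = SurfacePatch(points=np.array([[3.0, 0, 0], [0, 4.0, 0]]), spacing=0.5)
        mapped = map_potential(patch, st, model="coulomb_uniform")
        assert np.all(mapped.potential == 0.0)

    def test_coulomb_ratio(self):
        st = atom_cloud([[0, 0, 0]])
        st.charge = np.array([1.0])
        patch = SurfacePatch(points=np.array([[1.0, 0, 0], [2.0, 0, 0]]), spacing=0.5)
        mapped = map_potential(patch, st, model="coulomb_uniform")
        assert mapped.potential[0] / mapped.potential[1] == pytest.approx(2.0)

    def test_ddd_ratio_is_quadratic(self):
        st = atom_cloud([[0, 0, 0]])
        st.charge = np.array([1.0])
        patch = SurfacePatch(points=np.array([[1.0, 0, 0], [2.0, 0, 0]]), spacing=0.5)
        mapped = map_potential(patch, st, model="coulomb_ddd")
        assert mapped.potential[0] / mapped.potential[1] == pytest.approx(4.0)

    def test_mirror_pair_antisymmetric(self):
        st = atom_cloud([[-2, 0, 0], [2, 0, 0]])
        st.charge = np.array([1.0, -1.0])
        pts = np.array([[x, 1.2, 0.7] for x in (-3.0, -1.0, 1.0, 3.0)])
        mirrored = pts.copy()
        mirrored[:, 0] *= -1
        a = map_potential(SurfacePatch(points=pts, spacing=0.5), st).potential
        b = map_potential(SurfacePatch(points=mirrored, spacing=0.5), st).potential
        assert np.allclose(a, -b, atol=1e-9)

    def test_clamp_warns(self):
        st = atom_cloud([[0, 0, 0]])
        st.charge = np.array([1.0])
        patch = SurfacePatch(points=np.array([[0.0, 0, 0]]), spacing=0.5)
        with pytest.warns(UserWarning, match="clamp"):
            map_potential(patch, st)

    def test_unknown_model(self):
        st = atom_cloud([[0, 0, 0]])
        with pytest.raises(ValueError):
            map_potential(SurfacePatch(points=np.zeros((1, 3)), spacing=0.5), st, model="pb")


class TestSignSplit:
    def test_partition_property(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100, 3))
        phi = rng.normal(size=100)
        phi[:10] = 0.0
        patch = SurfacePatch(points=pts, spacing=0.5, potential=phi)
        pos, neg = split_by_sign(patch)
        assert pos.n_points + neg.n_points + 10 == patch.n_points
        assert np.all(pos.potential > 0) and np.all(neg.potential < 0)

    def test_uniform_positive_flags_empty_negative(self):
        patch = SurfacePatch(
            points=np.random.default_rng(1).normal(size=(20, 3)),
            spacing=0.5,
            potential=np.ones(20),
        )
        pos, neg = split_by_sign(patch)
        assert neg.is_empty and neg.flags["empty"]
        assert not pos.flags["empty"]

    def test_magnitude_normalization(self):
        pts = np.random.default_rng(2).normal(size=(30, 3))
        phi = np.linspace(-2, 4, 30)
        pos, _ = split_by_sign(SurfacePatch(points=pts, spacing=0.5, potential=phi))
        assert pos.values.max() == pytest.approx(1.0)
        pos_raw, _ = split_by_sign(
            SurfacePatch(points=pts, spacing=0.5, potential=phi),
            normalize_magnitude=False,
        )
        assert pos_raw.values.max() == pytest.approx(4.0)

    def test_requires_mapped_potential(self):
        with pytest.raises(ValueError):
            split_by_sign(SurfacePatch(points=np.zeros((2, 3)), spacing=0.5))


def hemisphere_cavity_fixture(spacing=0.4, R=4.0):
    """Slab with a hemispherical dent of radius R, lined by small atoms."""
    ax = np.arange(-8.0, 8.0 + spacing / 2, spacing)
    az = np.arange(-6.0, 1.0 + spacing / 2, spacing)
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    occ = (Z <= 0) & (X**2 + Y**2 + Z**2 > R * R)
    grid = VoxelGrid(origin=np.array([ax[0], ax[0], az[0]]), spacing=spacing, values=occ.astype(float))
    # lining atoms on the dent surface (slightly outside the carved sphere)
    pts = []
    golden = np.pi * (3 - np.sqrt(5))
    for i in range(150):
        z = -(i + 0.5) / 150  # lower hemisphere only
        rho = np.sqrt(1 - z * z)
        th = golden * i
        pts.append(4.15 * np.array([rho * np.cos(th), rho * np.sin(th), z]))
    for k in range(24):  # rim ring at z = 0
        th = 2 * np.pi * k / 24
        pts.append(np.array([4.15 * np.cos(th), 4.15 * np.sin(th), 0.0]))
    st = atom_cloud(pts, radius=0.3, res_numbers=np.ones(len(pts), dtype=int))
    return grid, st, PocketDefinition("dent", (1,))


class TestPocketVolume:
    def test_hemisphere_volume(self):
        grid, st, pocket = hemisphere_cavity_fixture()
        vol = pocket_volume(grid, st, pocket)
        assert vol == pytest.approx(2.0 / 3.0 * np.pi * 4.0**3, rel=0.10)

    def test_refinement_changes_volume_little(self):
        v1 = pocket_volume(*hemisphere_cavity_fixture(spacing=0.5))
        v2 = pocket_volume(*hemisphere_cavity_fixture(spacing=0.25))
        assert abs(v2 - v1) / v2 < 0.05

    def test_convex_surface_has_no_volume(self):
        # atoms on a solid ball's surface: hull interior is occupied
        ax = np.arange(-7.0, 7.0 + 0.4, 0.4)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        occ = X**2 + Y**2 + Z**2 <= 36.0
        grid = VoxelGrid(origin=np.array([ax[0]] * 3), spacing=0.4, values=occ.astype(float))
        golden = np.pi * (3 - np.sqrt(5))
        pts = []
        for i in range(100):
            z = 1 - 2 * (i + 0.5) / 100
            rho = np.sqrt(1 - z * z)
            th = golden * i
            pts.append(5.9 * np.array([rho * np.cos(th), rho * np.sin(th), z]))
        st = atom_cloud(pts, radius=0.3, res_numbers=np.ones(100, dtype=int))
        vol = pocket_volume(grid, st, PocketDefinition("bump", (1,)))
        assert vol < 0.05 * (2.0 / 3.0 * np.pi * 6.0**3)
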