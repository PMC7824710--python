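"""Zernike basis, moments, invariants: index laws, symmetry, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zernmatch.surface import VoxelGrid
from zernmatch.zernike import (
    NormalizedGrid,
    compute_moments,
    descriptor_index_set,
    evaluate_basis,
    invariants_from_moments,
    moment_index_set,
    normalize_to_unit_ball,
    patch_to_grid,
    reconstruct,
)


def ball_grid(radius=6.0, spacing=0.5, value_fn=None, center=(0.0, 0.0, 0.0)):
    """Grid of a solid ball (or a custom scalar field on its support)."""
    half = radius + 2.0
    ax = np.arange(-half, half + spacing / 2, spacing)
    X, Y, Z = np.meshgrid(
        ax + center[0], ax + center[1], ax + center[2], indexing="ij"
    )
    R2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    inside = R2 <= radius * radius
    if value_fn is None:
        vals = inside.astype(float)
    else:
        vals = np.where(inside, value_fn(X - center[0], Y - center[1], Z - center[2]), 0.0)
    origin = np.array([ax[0] + center[0], ax[0] + center[1], ax[0] + center[2]])
    return VoxelGrid(origin=origin, spacing=spacing, values=vals)


class TestIndexSet:
    def test_small_orders_enumerated_by_hand(self):
        assert descriptor_index_set(0) == [(0, 0)]
        assert descriptor_index_set(2) == [(0, 0), (1, 1), (2, 0), (2, 2)]

    def test_count_law(self):
        # |{(n,l): n<=N, l<=n, n-l even}| = ((N+2)^2 - (N mod 2)) / 4
        for N in range(31):
            expected = ((N + 2) ** 2 - (N % 2)) // 4
            assert len(descriptor_index_set(N)) == expected

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            descriptor_index_set(-1)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=24))
    def test_moment_count_matches_descriptor_blocks(self, N):
        pairs = descriptor_index_set(N)
        assert len(moment_index_set(N)) == sum(2 * l + 1 for (_, l) in pairs)


class TestNormalization:
    def test_scaling_contract(self):
        grid = ball_grid(radius=10.0, spacing=0.5)
        norm = normalize_to_unit_ball(grid, scale_margin=0.6)
        pts, _, _ = norm.support()
        assert np.linalg.norm(pts, axis=1).max() == pytest.approx(0.6, abs=0.02)

    def test_translation_invariance(self):
        g0 = normalize_to_unit_ball(ball_grid(radius=5.0, spacing=0.5))
        g1 = normalize_to_unit_ball(
            ball_grid(radius=5.0, spacing=0.5, center=(3.0, -2.0, 7.0))
        )
        assert np.array_equal(g0.grid.values, g1.grid.values)
        assert np.allclose(g0.grid.origin, g1.grid.origin, atol=1e-9)

    def test_already_normalized_identity(self):
        norm = normalize_to_unit_ball(ball_grid(radius=5.0, spacing=0.5))
        again = normalize_to_unit_ball(norm.grid, scale_margin=norm.scale_margin)
        assert np.allclose(again.center, 0.0, atol=1e-12)
        assert again.scale == pytest.approx(1.0, abs=1e-12)

    def test_single_voxel_rejected(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 1.0
        grid = VoxelGrid(origin=np.zeros(3), spacing=0.5, values=vals)
        with pytest.raises(ValueError):
            normalize_to_unit_ball(grid)

    def test_empty_support_rejected(self):
        grid = VoxelGrid(origin=np.zeros(3), spacing=0.5, values=np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            normalize_to_unit_ball(grid)


class TestMoments:
    def test_radially_symmetric_input_has_no_l_gt_0(self):
        fn = lambda x, y, z: np.exp(-(x**2 + y**2 + z**2) / 8.0)
        norm = normalize_to_unit_ball(ball_grid(radius=6.0, spacing=0.4, value_fn=fn))
        mom = compute_moments(norm, N=8)
        by_idx = mom.as_dict()
        l0 = max(abs(v) for (n, l, m), v in by_idx.items() if l == 0)
        lpos = max(abs(v) for (n, l, m), v in by_idx.items() if l > 0)
        assert lpos < 1e-3 * l0

    def test_zero_field_zero_moments(self):
        grid = ball_grid(radius=4.0, spacing=0.5)
        norm = normalize_to_unit_ball(grid)
        norm.grid.values[:] = 0.0
        mom = compute_moments(norm, N=6)
        assert np.all(mom.values == 0)

    def test_basis_function_input_recovers_dominant_coefficient(self):
        # sample Z_220 (real, m=0) on a ball and expand: the (2,2,0)
        # coefficient must dominate all others
        grid = ball_grid(radius=1.0, spacing=0.02)
        norm = NormalizedGrid(grid=grid, center=np.zeros(3), scale=1.0, scale_margin=1.0)
        pts, _, _ = norm.support()
        mask = grid.values != 0
        vals = np.zeros_like(grid.values)
        idx = np.argwhere(mask)
        keep = np.linalg.norm(grid.origin + grid.spacing * idx, axis=1) < 1.0
        target = evaluate_basis(2, 2, 0, grid.origin + grid.spacing * idx[keep]).real
        vals[tuple(idx[keep].T)] = target
        norm = NormalizedGrid(
            grid=VoxelGrid(origin=grid.origin, spacing=grid.spacing, values=vals),
            center=np.zeros(3),
            scale=1.0,
            scale_margin=1.0,
        )
        mom = compute_moments(norm, N=4)
        by_idx = mom.as_dict()
        main = abs(by_idx[(2, 2, 0)])
        cross = max(abs(v) for k, v in by_idx.items() if k != (2, 2, 0))
        assert main == pytest.approx(1.0, rel=0.05)
        assert cross < 0.01 * main

    def test_conjugate_symmetry(self):
        fn = lambda x, y, z: np.maximum(0.0, 1.0 + 0.1 * x - 0.05 * y * z)
        norm = normalize_to_unit_ball(ball_grid(radius=5.0, spacing=0.5, value_fn=fn))
        mom = compute_moments(norm, N=6)
        by_idx = mom.as_dict()
        for (n, l, m), v in by_idx.items():
            if m > 0:
                assert by_idx[(n, l, -m)] == pytest.approx(
                    (-1) ** m * np.conj(v), abs=1e-10
                )

    def test_requires_normalized_grid(self):
        with pytest.raises(TypeError):
            compute_moments(ball_grid(radius=3.0), N=4)


class TestInvariants:
    def test_zero_moments_zero_descriptor(self):
        grid = ball_grid(radius=4.0, spacing=0.5)
        norm = normalize_to_unit_ball(grid)
        norm.grid.values[:] = 0.0
        desc = invariants_from_moments(compute_moments(norm, N=6))
        assert np.all(desc.values == 0)

    def test_order_20_gives_121_descriptors(self):
        norm = normalize_to_unit_ball(ball_grid(radius=4.0, spacing=0.5))
        desc = invariants_from_moments(compute_moments(norm, N=20))
        assert len(desc) == 121

    def test_parseval_identity(self):
        fn = lambda x, y, z: np.abs(x) + 0.2 * np.abs(y * z)
        norm = normalize_to_unit_ball(ball_grid(radius=5.0, spacing=0.5, value_fn=fn))
        mom = compute_moments(norm, N=10)
        desc = invariants_from_moments(mom)
        assert (desc.values**2).sum() == pytest.approx(
            (np.abs(mom.values) ** 2).sum(), abs=1e-12
        )

    def test_rotation_invariance_90_degrees(self):
        # an exact lattice rotation: descriptors must agree to high accuracy
        fn = lambda x, y, z: np.maximum(0.0, 1.0 - (x**2 / 16 + y**2 / 9 + z**2 / 4))
        rot = lambda x, y, z: fn(y, -x, z)  # 90 deg about z
        d0 = invariants_from_moments(
            compute_moments(normalize_to_unit_ball(ball_grid(6.0, 0.5, fn)), N=8)
        )
        d1 = invariants_from_moments(
            compute_moments(normalize_to_unit_ball(ball_grid(6.0, 0.5, rot)), N=8)
        )
        rel = np.linalg.norm(d0.values - d1.values) / np.linalg.norm(d0.values)
        assert rel < 1e-3

    def test_descriptor_tsv_serialization(self, tmp_path):
        norm = normalize_to_unit_ball(ball_grid(radius=4.0, spacing=0.5))
        desc = invariants_from_moments(compute_moments(norm, N=4))
        path = tmp_path / "d.tsv"
        desc.to_tsv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0].split("\t") == ["n", "l", "D_nl"]
        assert len(rows) - 1 == len(desc)


class TestReconstruction:
    def test_ball_reconstruction_correlates(self):
        norm = normalize_to_unit_ball(ball_grid(radius=6.0, spacing=0.4))
        mom = compute_moments(norm, N=20)
        rec = reconstruct(mom, (33, 33, 33))
        # compare against the normalized indicator sampled on the same lattice
        ax = rec.origin[0] + rec.spacing * np.arange(33)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        R = np.sqrt(X**2 + Y**2 + Z**2)
        truth = (R <= 0.6).astype(float)
        inside = R < 1.0
        corr = np.corrcoef(rec.values[inside], truth[inside])[0, 1]
        assert corr > 0.9

    def test_error_decreases_with_order(self):
        norm = normalize_to_unit_ball(ball_grid(radius=6.0, spacing=0.4))
        ax = None
        errs = {}
        for N in (4, 20):
            mom = compute_moments(norm, N=N)
            rec = reconstruct(mom, (29, 29, 29))
            ax = rec.origin[0] + rec.spacing * np.arange(29)
            X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
            R = np.sqrt(X**2 + Y**2 + Z**2)
            truth = (R <= 0.6).astype(float)
            inside = R < 1.0
            errs[N] = np.linalg.norm(rec.values[inside] - truth[inside])
        assert errs[20] <= errs[4]

    def test_zero_moments_zero_field(self):
        norm = normalize_to_unit_ball(ball_grid(radius=4.0, spacing=0.5))
        mom = compute_moments(norm, N=4)
        mom.values[:] = 0
        rec = reconstruct(mom, (17, 17, 17))
        assert np.all(rec.values == 0)


class TestPatchToGrid:
    def test_roundtrip_is_exact_on_lattice(self):
        rng = np.random.default_rng(3)
        idx = rng.integers(0, 12, size=(40, 3))
        idx = np.unique(idx, axis=0)
        pts = np.array([1.0, -2.0, 0.5]) + 0.5 * idx
        from zernmatch.surface import SurfacePatch

        patch = SurfacePatch(points=pts, spacing=0.5)
        grid = patch_to_grid(patch)
        back = grid.voxel_centers()
        assert {tuple(p) for p in np.round(back, 6)} == {
            tuple(p) for p in np.round(pts, 6)
        }
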