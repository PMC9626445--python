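"""DTI tensor construction, reorientation, pullback and anisotropy metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gliomech import tensors as ts
from gliomech.mesh import TetMesh

from conftest import random_deformation


def random_spd(rng, scale=1.0):
    A = rng.standard_normal((3, 3))
    return scale * (A @ A.T + 3.0 * np.eye(3))


class TestAnisotropyIndices:
    def test_isotropic_is_spherical(self):
        al, ap, as_ = ts.anisotropy_indices(2.0, 2.0, 2.0)
        assert (al, ap, as_) == (0.0, 0.0, 1.0)

    def test_prolate_example(self):
        al, ap, as_ = ts.anisotropy_indices(2.0, 1.0, 1.0)
        assert (al, ap, as_) == pytest.approx((0.25, 0.0, 0.75))

    @given(st.lists(st.floats(0.01, 100.0), min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_closure(self, lams):
        l1, l2, l3 = sorted(lams, reverse=True)
        al, ap, as_ = ts.anisotropy_indices(l1, l2, l3)
        assert abs(al + ap + as_ - 1.0) < 1e-12
        assert 0.0 <= min(al, ap, as_) and max(al, ap, as_) <= 1.0

    def test_unordered_rejected(self):
        with pytest.raises(ValueError):
            ts.anisotropy_indices(1.0, 2.0, 0.5)


class TestPreferentialTensor:
    def test_r_one_is_trace_normalized_d0(self, rng):
        D0 = random_spd(rng)
        A0 = ts.build_preferential_tensor(D0, r=1.0)
        assert np.allclose(A0, 3.0 * D0 / np.trace(D0), atol=1e-12)

    def test_isotropic_maps_to_identity(self):
        for r in (1.0, 5.0, 10.0):
            A0 = ts.build_preferential_tensor(2.5 * np.eye(3), r=r)
            assert np.allclose(A0, np.eye(3), atol=1e-12)

    def test_unit_mean_eigenvalue(self, rng):
        for r in (1.0, 5.0, 10.0):
            A0 = ts.build_preferential_tensor(random_spd(rng), r=r)
            assert np.trace(A0) == pytest.approx(3.0, abs=1e-12)

    def test_enhancement_raises_fa(self, rng):
        D0 = np.diag([3.0, 1.5, 1.0])
        fa = []
        for r in (1.0, 3.0, 8.0):
            lam, _ = ts.spectral(ts.build_preferential_tensor(D0, r=r))
            fa.append(ts.fractional_anisotropy(lam[0], lam[1], lam[2]))
        assert fa[0] < fa[1] < fa[2]


class TestReorientation:
    def test_identity_deformation(self, rng):
        D0 = random_spd(rng)
        lams, vecs = ts.spectral(D0)
        assert np.allclose(ts.reorient_tensor(lams, vecs, np.eye(3)), D0, atol=1e-12)

    def test_rotation_rotates_eigenvectors(self):
        D0 = np.diag([3.0, 2.0, 1.0])
        lams, vecs = ts.spectral(D0)
        R = Rotation.from_euler("zyx", [0.3, -0.5, 0.9]).as_matrix()
        D = ts.reorient_tensor(lams, vecs, R)
        assert np.allclose(D, R @ D0 @ R.T, atol=1e-12)

    def test_trace_preserved_under_random_deformations(self, rng):
        D0 = random_spd(rng)
        lams, vecs = ts.spectral(D0)
        for _ in range(50):
            F = random_deformation(rng)
            D = ts.reorient_tensor(lams, vecs, F)
            assert np.trace(D) == pytest.approx(np.trace(D0), rel=1e-12)

    def test_trace_normalization_for_preferential_tensor(self, rng):
        A0 = ts.build_preferential_tensor(random_spd(rng), r=4.0)
        lams, vecs = ts.spectral(A0)
        A = ts.reorient_tensor(lams, vecs, random_deformation(rng),
                               normalize_trace_to=3.0)
        assert np.trace(A) == pytest.approx(3.0, abs=1e-12)

    def test_singular_deformation_rejected(self, rng):
        lams, vecs = ts.spectral(random_spd(rng))
        with pytest.raises(ValueError):
            ts.reorient_tensor(lams, vecs, np.diag([1.0, 1.0, 0.0]))


class TestPullback:
    def test_identity(self, rng):
        T = random_spd(rng)
        assert np.allclose(ts.pullback_tensor(T, np.eye(3)), T)

    def test_reoriented_diffusion_recovers_initial_eigenvectors(self, rng):
        """D* = J F^-1 D F^-T of the reoriented D is diagonal in the D0 frame."""
        D0 = random_spd(rng)
        lams, vecs = ts.spectral(D0)
        for _ in range(10):
            F = random_deformation(rng)
            D = ts.reorient_tensor(lams, vecs, F)
            Dstar = ts.pullback_tensor(D, F)
            off = vecs.T @ Dstar @ vecs
            assert np.abs(off - np.diag(np.diag(off))).max() < 1e-10

    def test_congruence_preserves_spd(self, rng):
        for _ in range(50):
            T = random_spd(rng)
            F = random_deformation(rng)
            lam_min = np.linalg.eigvalsh(ts.pullback_tensor(T, F)).min()
            assert lam_min > 0.0


class TestFractionalAnisotropy:
    def test_limits_and_example(self):
        assert ts.fractional_anisotropy(2.0, 2.0, 2.0) == pytest.approx(0.0)
        assert ts.fractional_anisotropy(1.0, 0.0, 0.0) == pytest.approx(1.0)
        assert ts.fractional_anisotropy(2.0, 1.0, 1.0) == pytest.approx(
            np.sqrt(1.0 / 6.0))

    def test_bounded_and_monotone(self, rng):
        lam = np.sort(rng.uniform(0.1, 10.0, (200, 3)), axis=1)[:, ::-1]
        fa = ts.fractional_anisotropy(lam[:, 0], lam[:, 1], lam[:, 2])
        assert np.all((fa >= 0.0) & (fa <= 1.0))
        # FA grows with lambda1/lambda3 at fixed geometric-mean lambda2
        ratios = np.linspace(1.0, 30.0, 50)
        fas = [ts.fractional_anisotropy(r, np.sqrt(r), 1.0) for r in ratios]
        assert np.all(np.diff(fas) > 0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ts.fractional_anisotropy(0.0, 0.0, 0.0)


class TestEigenvectorChange:
    def test_same_axis(self):
        e = np.array([0.0, 0.0, 1.0])
        s, dth, dph = ts.eigenvector_change(e, e)
        assert (s, dth, dph) == pytest.approx((0.0, 0.0, 0.0))

    def test_opposite_orientation_is_same_axis(self, rng):
        e = rng.standard_normal(3)
        s, dth, dph = ts.eigenvector_change(e, -e)
        assert s == pytest.approx(0.0, abs=1e-12)
        assert dth == pytest.approx(0.0, abs=1e-9)
        assert dph == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular(self):
        s, _, _ = ts.eigenvector_change([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        assert s == pytest.approx(1.0)

    def test_angle_folding_into_quarter_circle(self):
        e0 = np.array([1.0, 0.0, 0.0])
        ef = np.array([np.cos(2.0), np.sin(2.0), 0.0])  # azimuth 2 rad > pi/2
        _, dth, _ = ts.eigenvector_change(e0, ef)
        assert 0.0 <= dth <= np.pi / 2.0
        assert dth == pytest.approx(np.pi - 2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            ts.eigenvector_change([0.0, 0.0, 0.0], [1.0, 0.0, 0.0])


def _unit_cube_mesh(n=3):
    """Structured tetrahedralization of [0, 10]^3 for sampling tests."""
    from scipy.spatial import Delaunay

    ax = np.linspace(0.0, 10.0, n)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(0)
    pts = pts + 1e-3 * rng.standard_normal(pts.shape)
    tri = Delaunay(pts)
    return TetMesh(points=pts, cells=tri.simplices).orient()


class TestVoxelToCell:
    def test_constant_grid(self):
        mesh = _unit_cube_mesh()
        T = np.diag([3.0, 2.0, 1.0])
        data = np.broadcast_to(ts.mat_to_sym6(T), (8, 8, 8, 6)).copy()
        grid = ts.VoxelTensorGrid(data=data, origin=-np.ones(3) * 2, spacing=np.full(3, 2.0))
        out = ts.voxel_to_cell(grid, mesh)
        assert np.allclose(out, T)

    def test_two_valued_plane_split(self):
        mesh = _unit_cube_mesh(4)
        n = 10
        data = np.zeros((n, n, n, 6))
        data[:, :, :, 0] = data[:, :, :, 3] = data[:, :, :, 5] = 1.0
        split = 5  # voxels with x-index >= 5 carry the doubled tensor
        data[split:, :, :, 0] = 2.0
        grid = ts.VoxelTensorGrid(data=data, origin=-2.0 * np.ones(3),
                                  spacing=np.full(3, 1.5))
        out = ts.voxel_to_cell(grid, mesh)
        bx = mesh.barycenters[:, 0]
        right = bx >= grid.origin[0] + split * grid.spacing[0]
        assert np.allclose(out[right, 0, 0], 2.0)
        assert np.allclose(out[~right, 0, 0], 1.0)

    def test_refinement_consistency_on_smooth_field(self):
        """Coarse and fine samplings of a smooth field differ by its continuity."""
        mesh = _unit_cube_mesh(4)

        def smooth(x):
            # eigenvalue field varying on a 10 mm scale; Lipschitz const ~0.1/mm
            out = np.zeros(x.shape[:-1] + (6,))
            out[..., 0] = 2.0 + np.sin(x[..., 0] / 10.0)
            out[..., 3] = 2.0 + np.cos(x[..., 1] / 10.0)
            out[..., 5] = 2.0
            return out

        fields = {}
        for spacing in (1.0, 2.0):
            n = int(np.ceil(16.0 / spacing))
            origin = -2.0 * np.ones(3)
            ax = origin[0] + (np.arange(n) + 0.5) * spacing
            centres = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
            grid = ts.VoxelTensorGrid(data=smooth(centres), origin=origin,
                                      spacing=np.full(3, spacing))
            fields[spacing] = ts.voxel_to_cell(grid, mesh)
        # voxel-centre offsets are at most (sqrt(3)/2)(s1+s2); modulus ~0.1/mm
        bound = 0.1 * np.sqrt(3.0) / 2.0 * (1.0 + 2.0) + 1e-12
        assert np.abs(fields[1.0] - fields[2.0]).max() <= bound

    def test_out_of_grid_names_cell(self):
        mesh = _unit_cube_mesh()
        grid = ts.VoxelTensorGrid(data=np.ones((2, 2, 2, 6)),
                                  origin=np.zeros(3), spacing=np.ones(3))
        with pytest.raises(ValueError, match="cell"):
            ts.voxel_to_cell(grid, mesh)


class TestSym6Roundtrip:
    def test_roundtrip(self, rng):
        T = random_spd(rng)
        assert np.allclose(ts.sym6_to_mat(ts.mat_to_sym6(T)), T)
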