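import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacisolate import (
    FourierFit,
    FusiformSpec,
    MeshValidationError,
    NoSacDetectedError,
    ProjectionCurve,
    RotationConfig,
    SurfaceMesh,
    detect_sac_bounds,
    fit_fourier,
    fit_fourier_sweep,
    fourier_derivatives,
    fourier_eval,
    isolate_sac,
    make_cylinder,
    make_fusiform,
    project_silhouette,
    rotate_about_z,
)


class TestRotation:
    def test_quarter_turn(self):
        out = rotate_about_z([[1.0, 0.0, 0.0]], 90.0)
        np.testing.assert_allclose(out, [[0.0, 1.0, 0.0]], atol=1e-12)

    def test_full_turn_identity(self):
        pts = np.random.default_rng(0).normal(size=(50, 3))
        np.testing.assert_allclose(rotate_about_z(pts, 360.0), pts, atol=1e-9)

    def test_composition_of_48_increments(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        out = pts
        for _ in range(48):
            out = rotate_about_z(out, 7.5)
        np.testing.assert_allclose(out, pts, atol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(theta=st.floats(-720, 720), x=st.floats(-50, 50), y=st.floats(-50, 50),
           z=st.floats(-50, 50))
    def test_preserves_norm_and_z(self, theta, x, y, z):
        out = rotate_about_z([[x, y, z]], theta)[0]
        assert out[2] == pytest.approx(z, abs=1e-9)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm([x, y, z]), abs=1e-8)


class TestRotationConfig:
    @pytest.mark.parametrize("inc,expected", [(0.5, 720), (1.0, 360), (7.5, 48),
                                              (15.0, 24), (22.5, 16), (45.0, 8),
                                              (90.0, 4)])
    def test_projection_counts(self, inc, expected):
        cfg = RotationConfig(inc)
        assert cfg.n_projections == expected
        assert len(cfg.angles()) == expected

    @pytest.mark.parametrize("inc", [0.0, -1.0, 91.0, 7.0])
    def test_invalid_increments(self, inc):
        with pytest.raises(MeshValidationError):
            RotationConfig(inc)


class TestSilhouette:
    def test_cylinder_constant_branches(self, cylinder_mesh):
        left, right = project_silhouette(cylinder_mesh, 0.0, z_bins=40)
        # Discretized ring: silhouette lies within one chord sagitta of r.
        sagitta = 10.0 * (1 - np.cos(np.pi / 48))
        assert np.all(np.abs(right.x - 10.0) <= sagitta + 1e-9)
        assert np.all(np.abs(left.x + 10.0) <= sagitta + 1e-9)

    def test_sphere_closed_form(self, icosphere_mesh):
        z_bins = 50
        left, right = project_silhouette(icosphere_mesh, 0.0, z_bins=z_bins)
        keep = np.abs(right.z) < 0.8
        expected = np.sqrt(1.0 - right.z[keep] ** 2)
        bin_width = 2.0 / z_bins
        # Geometric error is at most one bin width times the local slope.
        tol = bin_width * np.abs(right.z[keep]) / expected + 0.01
        assert np.all(np.abs(right.x[keep] - expected) <= tol)

    def test_surface_of_revolution_rotation_invariant(self):
        mesh, _ = make_fusiform(FusiformSpec(asymmetry=0.0))
        grid_step = 360.0 / 64  # one circumferential node spacing
        l0, r0 = project_silhouette(mesh, 0.0, 80)
        l1, r1 = project_silhouette(mesh, 3 * grid_step, 80)
        np.testing.assert_allclose(r1.x, r0.x, atol=1e-9)
        np.testing.assert_allclose(l1.x, l0.x, atol=1e-9)

    def test_insufficient_bins_error(self, cylinder_mesh):
        # Collapse nodes onto two z levels: only 2 of 100 bins are occupied.
        nodes = cylinder_mesh.nodes.copy()
        nodes[:, 2] = np.where(nodes[:, 2] > 0, 1.0, 0.0)
        flat = SurfaceMesh(nodes, cylinder_mesh.triangles)
        with pytest.raises(MeshValidationError, match="insufficient silhouette"):
            project_silhouette(flat, 0.0, z_bins=100)

    def test_branch_sign_invariants(self, fusiform_case):
        _, mesh, _ = fusiform_case
        left, right = project_silhouette(mesh, 30.0, 100)
        assert np.all(right.x >= 0)
        assert np.all(left.x <= 0)
        assert np.all(np.diff(right.z) > 0)


def _curve(z, x, side="right"):
    return ProjectionCurve(0.0, side, z, x)


class TestFourierFit:
    def test_constant_curve(self):
        z = np.linspace(-30, 30, 40)
        fit = fit_fourier(_curve(z, np.full_like(z, 5.0)), n_harmonics=7)
        assert fit.a0 == pytest.approx(5.0, abs=1e-6)
        assert np.all(np.abs(fit.a) < 1e-6)
        assert np.all(np.abs(fit.b) < 1e-6)
        assert fit.rmse < 1e-8

    def test_recovers_known_three_harmonic_series(self):
        z = np.linspace(0, 40, 120)
        w_true = 2 * np.pi / 40 * 0.8
        truth = FourierFit(a0=12.0, a=[1.5, -0.7, 0.3], b=[0.4, 0.8, -0.2],
                           w=w_true, n=3, rmse=0.0)
        y = fourier_eval(truth, z)
        assert np.all(y > 0)
        fit = fit_fourier(_curve(z, y), n_harmonics=3)
        assert fit.rmse < 1e-6
        assert fit.w == pytest.approx(w_true, abs=1e-4)

    def test_rmse_non_increasing_in_harmonics(self, fusiform_case):
        _, mesh, _ = fusiform_case
        _, right = project_silhouette(mesh, 0.0, 100)
        fits = fit_fourier_sweep(right, 1, 8)
        rmses = [f.rmse for f in fits]
        assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))

    def test_too_few_samples_rejected(self):
        z = np.linspace(0, 10, 10)
        with pytest.raises(MeshValidationError, match="samples"):
            fit_fourier(_curve(z, np.abs(np.sin(z)) + 1), n_harmonics=7)

    def test_deterministic(self, fusiform_case):
        _, mesh, _ = fusiform_case
        _, right = project_silhouette(mesh, 15.0, 100)
        f1 = fit_fourier(right)
        f2 = fit_fourier(right)
        assert f1.a0 == f2.a0 and f1.w == f2.w
        np.testing.assert_array_equal(f1.a, f2.a)


class TestDerivatives:
    def test_constant_fit_zero_derivatives(self):
        fit = FourierFit(a0=4.0, a=[0.0], b=[0.0], w=0.3, n=1, rmse=0.0)
        _, d1, d2 = fourier_derivatives(fit, np.linspace(-5, 5, 11))
        np.testing.assert_allclose(d1, 0.0, atol=1e-15)
        np.testing.assert_allclose(d2, 0.0, atol=1e-15)

    def test_pure_sine_closed_form(self):
        w = 0.7
        fit = FourierFit(a0=0.0, a=[0.0], b=[1.0], w=w, n=1, rmse=0.0)
        z = np.linspace(-4, 4, 200)
        _, _, d2 = fourier_derivatives(fit, z)
        np.testing.assert_allclose(d2, -(w**2) * np.sin(w * z), atol=1e-9)

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        z_range = 60.0
        for _ in range(10):
            n = int(rng.integers(1, 9))
            fit = FourierFit(a0=rng.normal(), a=rng.normal(size=n),
                             b=rng.normal(size=n),
                             w=2 * np.pi / z_range * rng.uniform(0.5, 2.0),
                             n=n, rmse=0.0)
            z = rng.uniform(-25, 25, size=20)
            h = 1e-5 * z_range
            _, d1, d2 = fourier_derivatives(fit, z)
            vp = fourier_eval(fit, z + h)
            vm = fourier_eval(fit, z - h)
            v0 = fourier_eval(fit, z)
            fd1 = (vp - vm) / (2 * h)
            fd2 = (vp - 2 * v0 + vm) / h**2
            scale1 = np.max(np.abs(d1)) + 1e-9
            scale2 = np.max(np.abs(d2)) + 1e-9
            assert np.max(np.abs(d1 - fd1)) / scale1 < 1e-4
            assert np.max(np.abs(d2 - fd2)) / scale2 < 1e-4


class TestDetectBounds:
    def test_cylinder_raises_no_sac(self):
        z = np.linspace(-50, 50, 80)
        fit = fit_fourier(_curve(z, np.full_like(z, 10.0)), n_harmonics=7)
        with pytest.raises(NoSacDetectedError):
            detect_sac_bounds(fit, (-50.0, 50.0))

    def test_gaussian_bulge_brackets_center(self):
        sigma = 12.0
        z = np.linspace(-55, 55, 160)
        y = 10.0 + 15.0 * np.exp(-((z / sigma) ** 2))
        fit = fit_fourier(_curve(z, y), n_harmonics=7)
        b = detect_sac_bounds(fit, (-55.0, 55.0))
        assert b.z_inf < 0 < b.z_sup
        assert not b.fallback_inf and not b.fallback_sup
        # Oracle: brute-force the flank extrema of the *fitted* series.
        zs = np.linspace(-55, 55, 20001)
        _, _, d2 = fourier_derivatives(fit, zs)
        pos = (d2 > 0) & (np.r_[False, d2[1:] > d2[:-1]] & np.r_[d2[:-1] > d2[1:], False])
        flanks = zs[pos]
        assert min(abs(flanks - b.z_inf)) <= 0.15 * sigma
        assert min(abs(flanks - b.z_sup)) <= 0.15 * sigma

    def test_symmetric_bulge_gives_symmetric_bounds(self, fusiform_case):
        spec, mesh, _ = fusiform_case
        _, right = project_silhouette(mesh, 0.0, 100)
        fit = fit_fourier(right, 7)
        z = mesh.nodes[:, 2]
        b = detect_sac_bounds(fit, (z.min(), z.max()))
        half = spec.sac_length / 2
        assert abs(abs(b.z_inf) - abs(b.z_sup)) <= 0.05 * half

    def test_left_branch_agrees_with_right(self, fusiform_case):
        spec, mesh, _ = fusiform_case
        left, right = project_silhouette(mesh, 0.0, 100)
        z = mesh.nodes[:, 2]
        br = detect_sac_bounds(fit_fourier(right, 7), (z.min(), z.max()))
        bl = detect_sac_bounds(fit_fourier(left, 7), (z.min(), z.max()))
        assert bl.z_inf == pytest.approx(br.z_inf, abs=2.0)
        assert bl.z_sup == pytest.approx(br.z_sup, abs=2.0)


class TestIsolateSac:
    def test_projection_bookkeeping(self, fusiform_case):
        _, mesh, _ = fusiform_case
        region = isolate_sac(mesh, RotationConfig(45.0))
        angles = {a for a, _, _, _ in region.per_projection_bounds}
        assert angles == set(np.arange(8) * 45.0)
        assert len(region.per_projection_bounds) == 16  # 8 rotations x 2 sides

    def test_recovers_ground_truth(self, fusiform_case):
        spec, mesh, truth = fusiform_case
        region = isolate_sac(mesh, RotationConfig(22.5))
        L = spec.sac_length
        assert abs(region.z_inferior - truth[0]) <= 0.1 * L
        assert abs(region.z_superior - truth[1]) <= 0.1 * L
        assert 0 < region.node_mask.sum() < mesh.n_nodes

    def test_cylinder_has_no_sac(self, cylinder_mesh):
        from sacisolate import SacIsolationError

        with pytest.raises(SacIsolationError):
            isolate_sac(cylinder_mesh, RotationConfig(45.0))

    def test_translation_invariant_mask(self, fusiform_case):
        _, mesh, _ = fusiform_case
        base = isolate_sac(mesh, RotationConfig(45.0))
        shifted = mesh.translated([17.0, -4.0, 33.0])
        moved = isolate_sac(shifted, RotationConfig(45.0))
        np.testing.assert_array_equal(moved.node_mask, base.node_mask)

    def test_pre_rotation_by_one_increment(self, fusiform_case):
        _, mesh, _ = fusiform_case
        inc = 45.0
        base = isolate_sac(mesh, RotationConfig(inc))
        rotated = SurfaceMesh(rotate_about_z(mesh.nodes, inc), mesh.triangles)
        other = isolate_sac(rotated, RotationConfig(inc))
        z = mesh.nodes[:, 2]
        bin_width = (z.max() - z.min()) / 100
        assert abs(other.z_inferior - base.z_inferior) <= bin_width
        assert abs(other.z_superior - base.z_superior) <= bin_width

    def test_node_permutation_permutes_mask(self, fusiform_case):
        _, mesh, _ = fusiform_case
        rng = np.random.default_rng(5)
        perm = rng.permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        permuted = SurfaceMesh(mesh.nodes[perm], inv[mesh.triangles])
        base = isolate_sac(mesh, RotationConfig(45.0))
        other = isolate_sac(permuted, RotationConfig(45.0))
        np.testing.assert_array_equal(other.node_mask, base.node_mask[perm])

    def test_bit_identical_determinism(self, fusiform_case):
        _, mesh, _ = fusiform_case
        r1 = isolate_sac(mesh, RotationConfig(45.0))
        r2 = isolate_sac(mesh, RotationConfig(45.0))
        assert r1.z_inferior == r2.z_inferior
        assert r1.z_superior == r2.z_superior
        np.testing.assert_array_equal(r1.node_mask, r2.node_mask)
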