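"""Field offsets: closed forms, superposition, and the Fourier route."""

import numpy as np
import pytest

import boldsim as bs

B0 = 3.0
DCHI = 1e-6
MAGIC = np.arccos(np.sqrt(1.0 / 3.0))


class TestCylinderField3D:
    def test_inside_parallel(self):
        cyl = bs.Cylinder3D(1e-3, [0, 0, 0], [0, 0, 1], DCHI)
        val = bs.cylinder_field_3d([[1e-4, 0, 0.3]], cyl, B0, (0, 0, 1))[0]
        assert np.isclose(val, 1.0e-6, rtol=1e-12)  # B0*dchi/6 * 2

    def test_inside_magic_angle_is_zero(self):
        cyl = bs.Cylinder3D(1e-3, [0, 0, 0], [np.sin(MAGIC), 0, np.cos(MAGIC)], DCHI)
        val = bs.cylinder_field_3d([[0, 1e-4, 0]], cyl, B0, (0, 0, 1))[0]
        assert abs(val) < 1e-18

    def test_outside_at_2r(self):
        # axis x, B0 z: theta = pi/2; point along z => phi = 0
        cyl = bs.Cylinder3D(1e-3, [0, 0, 0], [1, 0, 0], DCHI)
        val = bs.cylinder_field_3d([[0, 0, 2e-3]], cyl, B0, (0, 0, 1))[0]
        assert np.isclose(val, 3.75e-7, rtol=1e-12)  # B0*dchi/2 * 1/4

    def test_axis_parallel_b0_no_outside_field(self):
        cyl = bs.Cylinder3D(1e-3, [0, 0, 0], [0, 0, 1], DCHI)
        pts = np.random.default_rng(0).normal(size=(20, 3)) * 0.01
        vals = bs.cylinder_field_3d(pts, cyl, B0, (0, 0, 1))
        outside = np.hypot(pts[:, 0], pts[:, 1]) > cyl.radius
        assert np.all(vals[outside] == 0.0)

    def test_far_field_inverse_square(self):
        cyl = bs.Cylinder3D(1e-3, [0, 0, 0], [1, 0, 0], DCHI)
        v1 = bs.cylinder_field_3d([[0, 0, 4e-3]], cyl, B0, (0, 0, 1))[0]
        v2 = bs.cylinder_field_3d([[0, 0, 8e-3]], cyl, B0, (0, 0, 1))[0]
        assert np.isclose(v1 / v2, 4.0, rtol=1e-12)


class TestCylinderField2D:
    def test_theta_zero_outside_is_zero(self):
        cyl = bs.Cylinder2D(1e-3, [0, 0], 0.0, 0.3, DCHI)
        assert bs.cylinder_field_2d([[5e-3, 2e-3]], cyl, B0)[0] == 0.0

    def test_perpendicular_at_2r(self):
        cyl = bs.Cylinder2D(1e-3, [0, 0], np.pi / 2, 0.0, DCHI)
        val = bs.cylinder_field_2d([[2e-3, 0]], cyl, B0)[0]
        assert np.isclose(val, B0 * DCHI / 8, rtol=1e-12)

    def test_matches_3d_at_matched_geometry(self, rng):
        # a 2D cylinder with (theta, phi0) equals a 3D cylinder whose axis
        # makes angle theta with B0, evaluated in the perpendicular plane
        for _ in range(10):
            theta = rng.uniform(0.05, np.pi - 0.05)
            phi0 = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(1.5e-3, 1e-2)
            phi = rng.uniform(0, 2 * np.pi)
            c2 = bs.Cylinder2D(1e-3, [0, 0], theta, phi0, DCHI)
            p2 = [r * np.cos(phi), r * np.sin(phi)]
            v2 = bs.cylinder_field_2d([p2], c2, B0)[0]
            # 3D: axis along x rotated so that angle(axis, B0) = theta, with
            # B0 projection onto the yz-plane along +y; measure phi from +y.
            axis = [np.sin(theta), 0.0, np.cos(theta)]
            c3 = bs.Cylinder3D(1e-3, [0, 0, 0], axis, DCHI)
            b3 = (0.0, 0.0, 1.0)
            # perpendicular plane basis: e1 = projection dir of B0, e2 = axis x e1
            b = np.array(b3)
            u = np.array(axis)
            e1 = b - (b @ u) * u
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            p3 = r * (np.cos(phi - phi0) * e1 + np.sin(phi - phi0) * e2)
            v3 = bs.cylinder_field_3d([p3], c3, B0, b3)[0]
            assert np.isclose(v2, v3, rtol=1e-10, atol=1e-20)


class TestSphereField:
    def test_inside_is_zero(self):
        sph = bs.Sphere3D(1e-3, [0, 0, 0], DCHI)
        assert bs.sphere_field([[0, 0, 0.5e-3]], sph, B0, (0, 0, 1))[0] == 0.0

    def test_surface_polar_value(self):
        sph = bs.Sphere3D(1e-3, [0, 0, 0], DCHI)
        val = bs.sphere_field([[0, 0, 1e-3]], sph, B0, (0, 0, 1))[0]
        assert np.isclose(val, 2.0e-6, rtol=1e-12)

    def test_magic_angle_zero(self):
        sph = bs.Sphere3D(1e-3, [0, 0, 0], DCHI)
        p = 2e-3 * np.array([np.sin(MAGIC), 0, np.cos(MAGIC)])
        assert abs(bs.sphere_field([p], sph, B0, (0, 0, 1))[0]) < 1e-18

    def test_far_field_inverse_cube(self):
        sph = bs.Sphere3D(1e-3, [0, 0, 0], DCHI)
        v1 = bs.sphere_field([[0, 0, 4e-3]], sph, B0, (0, 0, 1))[0]
        v2 = bs.sphere_field([[0, 0, 8e-3]], sph, B0, (0, 0, 1))[0]
        assert np.isclose(v1 / v2, 8.0, rtol=1e-12)

    def test_zero_mean_over_shell(self, rng):
        # the exterior dipole field averages to zero over a sphere shell
        sph = bs.Sphere3D(1e-3, [0, 0, 0], DCHI)
        v = rng.normal(size=(200_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        vals = bs.sphere_field(5e-3 * v, sph, B0, (0, 0, 1))
        assert abs(vals.mean()) < 5 * vals.std() / np.sqrt(vals.size)


class TestSuperposition:
    def test_single_perturber_equals_single_op(self):
        cyl = bs.Cylinder3D(1e-3, [0, 0, 0], [1, 0, 0], DCHI)
        pts = np.random.default_rng(0).normal(size=(50, 3)) * 0.01
        assert np.allclose(
            bs.analytic_field(pts, [cyl], B0, (0, 0, 1)),
            bs.cylinder_field_3d(pts, cyl, B0, (0, 0, 1)),
            rtol=1e-12, atol=1e-24)

    def test_linearity_two_cylinders(self):
        a = bs.Cylinder3D(1e-3, [0, 0, -5e-3], [1, 0, 0], DCHI)
        b = bs.Cylinder3D(1e-3, [0, 0, 5e-3], [1, 0, 0], DCHI)
        mid = np.array([[0.0, 0.0, 0.0]])
        total = bs.analytic_field(mid, [a, b], B0, (0, 0, 1))[0]
        assert np.isclose(total,
                          bs.cylinder_field_3d(mid, a, B0, (0, 0, 1))[0]
                          + bs.cylinder_field_3d(mid, b, B0, (0, 0, 1))[0],
                          rtol=1e-14)

    def test_inside_one_outside_other(self):
        a = bs.Cylinder2D(1e-3, [0, 0], np.pi / 2, 0.0, DCHI)
        b = bs.Cylinder2D(1e-3, [4e-3, 0], np.pi / 2, 0.0, DCHI)
        p = np.array([[1e-4, 0.0]])  # inside a, outside b
        total = bs.analytic_field(p, [a, b], B0)[0]
        expect = (bs.cylinder_field_2d(p, a, B0)[0]
                  + bs.cylinder_field_2d(p, b, B0)[0])
        assert np.isclose(total, expect, rtol=1e-14)

    def test_b0_direction_invariance(self, rng):
        # rotating B0 and all perturbers together leaves offsets unchanged
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=7)
        cyl = bs.Cylinder3D(1e-3, [1e-3, 0, 0], [0, 1, 0], DCHI)
        sph = bs.Sphere3D(1e-3, [0, 5e-3, 0], DCHI)
        pts = rng.normal(size=(30, 3)) * 0.01
        before = bs.analytic_field(pts, [cyl, sph], B0, (0, 0, 1))
        cyl_r = bs.Cylinder3D(1e-3, rot.apply(cyl.axis_point),
                              rot.apply(cyl.axis_dir), DCHI)
        sph_r = bs.Sphere3D(1e-3, rot.apply(sph.center), DCHI)
        after = bs.analytic_field(rot.apply(pts), [cyl_r, sph_r], B0,
                                  rot.apply([0, 0, 1]))
        assert np.allclose(before, after, rtol=1e-10, atol=1e-22)


class TestDipoleKernel:
    def test_zero_at_origin(self):
        g = bs.dipole_kernel_3d((9, 9, 9), 1.0)
        assert g[4, 4, 4] == 0.0

    def test_on_axis_value(self):
        g = bs.dipole_kernel_3d((9, 9, 9), 1.0)
        d = 3.0
        assert np.isclose(g[4, 4, 7], 2.0 / (4 * np.pi * d**3), rtol=1e-12)

    def test_equatorial_value(self):
        g = bs.dipole_kernel_3d((9, 9, 9), 1.0)
        d = 3.0
        assert np.isclose(g[7, 4, 4], -1.0 / (4 * np.pi * d**3), rtol=1e-12)


class TestFFTField:
    def test_uniform_chi_gives_constant_field(self):
        chi = np.full((24, 24, 24), 1e-6)
        out = bs.fft_field(chi, 1e-3, B0, pad_elements=0)
        assert np.ptp(out) < 1e-18

    def test_sphere_matches_analytic(self):
        w, n = 0.1, 64
        spec = bs.VoxelSpec(3, w, "gridded", n=n, b0=B0)
        sph = bs.Sphere3D(w / 8, np.full(3, w / 2), DCHI)
        gv = bs.discretize_voxel([sph], spec)
        f = bs.fft_field(gv.dchi_map, spec.dx, B0)
        ana = bs.analytic_field_grid([sph], spec).values
        c1 = spec.element_centers_1d()
        x, y, z = np.meshgrid(c1, c1, c1, indexing="ij")
        r = np.sqrt((x - w / 2) ** 2 + (y - w / 2) ** 2 + (z - w / 2) ** 2)
        face = np.minimum.reduce([x, w - x, y, w - y, z, w - z])
        m = (np.abs(r - sph.radius) >= 2 * spec.dx) & (face >= 4 * spec.dx)
        rel = np.sqrt(np.mean((f - ana)[m] ** 2) / np.mean(ana[m] ** 2))
        assert rel <= 0.05

    def test_extra_padding_changes_nothing(self):
        chi = np.zeros((16, 16, 16))
        chi[6:10, 6:10, 6:10] = 1e-6
        full = bs.fft_field(chi, 1e-3, B0, pad_elements=15)   # M - 1 = 15
        more = bs.fft_field(chi, 1e-3, B0, pad_elements=40)
        # atol: FFT round-off, ~1e-12 of the peak field
        assert np.allclose(full, more, rtol=1e-10, atol=1e-18)

    def test_periodic_mode_differs_from_padded(self):
        chi = np.zeros((16, 16, 16))
        chi[2:6, 2:6, 2:6] = 1e-6  # off-center: wrap-around matters
        periodic = bs.fft_field(chi, 1e-3, B0, pad_elements=0)
        padded = bs.fft_field(chi, 1e-3, B0)
        assert not np.allclose(periodic, padded, rtol=1e-3)

    def test_2d_grid_rejected(self):
        with pytest.raises(ValueError, match="3D"):
            bs.fft_field(np.zeros((8, 8)), 1e-3, B0)
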