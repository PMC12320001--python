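"""Geometry: perturber generation, CBV estimation, discretization, masks."""

import numpy as np
import pytest
from scipy import stats

import boldsim as bs
from boldsim.geometry import (label_points, random_unit_vectors,
                              sample_polar_angles)


class TestComputeCBV:
    def test_empty_list_is_zero(self, spec2d):
        assert bs.compute_cbv([], spec2d).value == 0.0

    def test_centered_circle_closed_form(self, spec2d):
        # circle of radius W/2 covers pi/4 of the square
        w = spec2d.width
        circ = bs.Cylinder2D(w / 2, [w / 2, w / 2], 0.0, 0.0, 1e-6)
        est = bs.compute_cbv([circ], spec2d, n_samples=200_000, rng_seed=3)
        assert abs(est.value - np.pi / 4) < 3 * est.stderr

    def test_centered_sphere_closed_form(self, spec3d):
        w = spec3d.width
        sph = bs.Sphere3D(w / 4, np.full(3, w / 2), 1e-6)
        est = bs.compute_cbv([sph], spec3d, n_samples=200_000, rng_seed=3)
        expected = 4.0 / 3.0 * np.pi * 0.25**3
        assert abs(est.value - expected) < 3 * est.stderr

    def test_union_semantics_for_overlapping_spheres(self, spec3d):
        w = spec3d.width
        sph = bs.Sphere3D(w / 4, np.full(3, w / 2), 1e-6)
        one = bs.compute_cbv([sph], spec3d, rng_seed=5)
        two = bs.compute_cbv([sph, sph], spec3d, rng_seed=5)
        assert one.value == two.value

    def test_convergence_rate(self, spec2d):
        # the MC estimator error shrinks roughly as 1/sqrt(n)
        w = spec2d.width
        circ = bs.Cylinder2D(w / 2, [w / 2, w / 2], 0.0, 0.0, 1e-6)
        errs = []
        for n in (10_000, 1_000_000):
            vals = [bs.compute_cbv([circ], spec2d, n_samples=n, rng_seed=s).value
                    for s in range(5)]
            errs.append(np.sqrt(np.mean((np.array(vals) - np.pi / 4) ** 2)))
        assert errs[1] < errs[0] / 3.0  # expect ~x10 reduction, allow slack


class TestGenerators:
    @pytest.mark.parametrize("maker,nd", [
        (bs.make_random_cylinders_3d, 3),
        (bs.make_random_cylinders_2d, 2),
        (bs.make_random_spheres_3d, 3),
    ])
    def test_target_cbv_reached(self, maker, nd):
        spec = bs.VoxelSpec(nd, 0.1)
        perts = maker(spec, 1e-3 if nd == 2 else 2e-3, 0.02, 1e-6, rng_seed=0)
        est = bs.compute_cbv(perts, spec, n_samples=200_000, rng_seed=99)
        assert 0.018 <= est.value <= 0.022

    @pytest.mark.parametrize("maker,nd,radius", [
        (bs.make_random_cylinders_3d, 3, 1e-3),
        (bs.make_random_cylinders_2d, 2, 1e-3),
        (bs.make_random_spheres_3d, 3, 4e-3),
    ])
    def test_seed_determinism(self, maker, nd, radius):
        spec = bs.VoxelSpec(nd, 0.1)
        a = maker(spec, radius, 0.01, 1e-6, rng_seed=42)
        b = maker(spec, radius, 0.01, 1e-6, rng_seed=42)
        assert a == b

    def test_zero_cbv_gives_empty_list(self, spec3d):
        assert bs.make_random_spheres_3d(spec3d, 1e-3, 0.0, 1e-6) == []

    def test_cap_failure_names_cap(self, spec3d):
        with pytest.raises(RuntimeError, match="cap of 3"):
            bs.make_random_cylinders_3d(spec3d, 1e-4, 0.05, 1e-6,
                                        max_perturbers=3)

    def test_overshoot_failure_for_oversized_perturber(self):
        spec = bs.VoxelSpec(2, 0.01)
        with pytest.raises(ValueError, match="overshoot"):
            bs.make_random_cylinders_2d(spec, 4e-3, 0.01, 1e-6)

    def test_orientation_uniformity_3d(self, rng):
        # cos(angle to B0) of isotropic axes is uniform on [-1, 1]
        v = random_unit_vectors(rng, 100_000)
        cos_t = v @ np.array([0.0, 0.0, 1.0])
        assert stats.kstest(cos_t, stats.uniform(-1, 2).cdf).pvalue > 0.01

    def test_2d_effective_orientation_uniformity(self, rng):
        cos_t = np.cos(sample_polar_angles(rng, 100_000))
        assert stats.kstest(cos_t, stats.uniform(-1, 2).cdf).pvalue > 0.01

    def test_2d_cylinder_list_theta_distribution(self):
        # end-to-end: theta of generated cylinders matches the law
        spec = bs.VoxelSpec(2, 0.1)
        perts = bs.make_random_cylinders_2d(spec, 2e-4, 0.02, 1e-6,
                                            rng_seed=1, n_probe=50_000)
        assert len(perts) > 500
        cos_t = np.cos([p.theta for p in perts])
        assert stats.kstest(cos_t, stats.uniform(-1, 2).cdf).pvalue > 0.001

    def test_no_overlap_mode(self):
        spec = bs.VoxelSpec(2, 0.05)
        perts = bs.make_random_cylinders_2d(spec, 2e-3, 0.05, 1e-6,
                                            rng_seed=0, overlap="forbid")
        for i, p in enumerate(perts):
            for q in perts[i + 1:]:
                assert np.linalg.norm(p.center - q.center) >= p.radius + q.radius


class TestDiscretization:
    def test_centered_circle_area_fraction(self):
        spec = bs.VoxelSpec(2, 0.1, "gridded", n=500)
        w = spec.width
        circ = bs.Cylinder2D(w / 4, [w / 2, w / 2], 0.0, 0.0, 1e-6)
        gv = bs.discretize_voxel([circ], spec)
        frac = (gv.label > 0).mean()
        assert abs(frac - np.pi / 16) / (np.pi / 16) < 0.01

    def test_labelled_fraction_converges_with_n(self):
        w = 0.1
        circ = bs.Cylinder2D(w / 4, [w / 2, w / 2], 0.0, 0.0, 1e-6)
        errs = []
        for n in (64, 256):
            gv = bs.discretize_voxel([circ], bs.VoxelSpec(2, w, "gridded", n=n))
            errs.append(abs((gv.label > 0).mean() - np.pi / 16))
        assert errs[1] < errs[0]

    def test_no_perturbers_all_zero(self):
        spec = bs.VoxelSpec(2, 0.1, "gridded", n=16)
        gv = bs.discretize_voxel([], spec)
        assert not gv.label.any()
        assert not gv.dchi_map.any()

    def test_subelement_perturber_warns_and_may_vanish(self):
        spec = bs.VoxelSpec(2, 0.1, "gridded", n=10)  # dx = 10 um
        tiny = bs.Cylinder2D(1e-3, [0.0199, 0.0199], 0.0, 0.0, 1e-6)
        with pytest.warns(UserWarning, match="at least 6"):
            gv = bs.discretize_voxel([tiny], spec)
        assert (gv.label > 0).sum() == 0

    def test_element_centers_convention(self):
        spec = bs.VoxelSpec(2, 1.0, "gridded", n=4)
        assert np.allclose(spec.element_centers_1d(), [0.125, 0.375, 0.625, 0.875])

    def test_3d_discretization_matches_mc_estimate(self):
        spec = bs.VoxelSpec(3, 0.1, "gridded", n=48)
        sph = bs.Sphere3D(0.025, np.full(3, 0.05), 1e-6)
        gv = bs.discretize_voxel([sph], spec)
        est = bs.compute_cbv([sph], spec, n_samples=200_000, rng_seed=0)
        assert abs((gv.label > 0).mean() - est.value) < 0.002


class TestCheckSampling:
    def test_warning_below_six_elements(self):
        spec = bs.VoxelSpec(2, 0.1, "gridded", n=100)  # dx = 1 um
        small = bs.Cylinder2D(1e-3, [0.05, 0.05], 0.0, 0.0, 1e-6)  # 2 across
        with pytest.warns(UserWarning):
            msgs = bs.check_sampling(spec, [small])
        assert len(msgs) == 1

    def test_no_warning_at_six_elements(self):
        spec = bs.VoxelSpec(2, 0.1, "gridded", n=100)
        ok = bs.Cylinder2D(3e-3, [0.05, 0.05], 0.0, 0.0, 1e-6)  # 6 across
        assert bs.check_sampling(spec, [ok]) == []

    def test_continuous_spec_is_silent(self, spec2d):
        small = bs.Cylinder2D(1e-6, [0.05, 0.05], 0.0, 0.0, 1e-6)
        assert bs.check_sampling(spec2d, [small]) == []


class TestMaskContainer:
    def _gv(self):
        spec = bs.VoxelSpec(3, 0.05, "gridded", n=16)
        sph = bs.Sphere3D(0.01, np.full(3, 0.025), 2e-6, perm=0.5)
        return bs.discretize_voxel([sph], spec)

    def test_round_trip_bit_exact(self, tmp_path):
        gv = self._gv()
        path = tmp_path / "mask.h5"
        gv.save(path)
        back = bs.load_perturber_mask(path)
        assert np.array_equal(back.label, gv.label)
        assert np.array_equal(back.dchi_map, gv.dchi_map)
        assert np.array_equal(back.perm_by_label, gv.perm_by_label)
        assert back.spec == gv.spec

    def test_missing_dchi_for_label_fails(self, tmp_path):
        import h5py
        path = tmp_path / "bad.h5"
        label = np.zeros((4, 4, 4), dtype=np.int32)
        label[0, 0, 0] = 1
        label[1, 1, 1] = 2
        with h5py.File(path, "w") as f:
            f.attrs.update(width=0.01, n=4, ndim=3, b0=3.0)
            f.attrs["b0_dir"] = [0.0, 0.0, 1.0]
            f.create_dataset("label", data=label)
            f.create_dataset("dchi_by_label", data=[0.0, 1e-6])  # label 2 missing
        with pytest.raises(ValueError, match="every label"):
            bs.load_perturber_mask(path)

    def test_shape_mismatch_fails(self, tmp_path):
        import h5py
        path = tmp_path / "bad2.h5"
        with h5py.File(path, "w") as f:
            f.attrs.update(width=0.01, n=4, ndim=3, b0=3.0)
            f.attrs["b0_dir"] = [0.0, 0.0, 1.0]
            f.create_dataset("label", data=np.zeros((4, 4, 4), dtype=np.int32))
            f.create_dataset("dchi", data=np.zeros((3, 4, 4)))
        with pytest.raises(ValueError, match="does not match"):
            bs.load_perturber_mask(path)

    def test_all_zero_mask_is_valid(self, tmp_path):
        spec = bs.VoxelSpec(3, 0.05, "gridded", n=8)
        gv = bs.GriddedVoxel(spec, np.zeros((8, 8, 8), dtype=np.int32),
                             np.zeros((8, 8, 8)))
        path = tmp_path / "empty.h5"
        gv.save(path)
        back = bs.load_perturber_mask(path)
        assert not back.label.any()


def test_label_points_first_wins():
    a = bs.Cylinder2D(0.01, [0.0, 0.0], 0.0, 0.0, 1e-6)
    b = bs.Cylinder2D(0.01, [0.005, 0.0], 0.0, 0.0, 2e-6)
    lab = label_points(np.array([[0.004, 0.0]]), [a, b])
    assert lab[0] == 1  # inside both, first perturber claims it


def test_ppm_cgs_conversion():
    assert np.isclose(bs.ppm_cgs_to_si(0.3), 4 * np.pi * 0.3e-6)


def test_voxelspec_validation():
    with pytest.raises(ValueError):
        bs.VoxelSpec(4, 0.1)
    with pytest.raises(ValueError):
        bs.VoxelSpec(2, 0.1, "gridded", n=1)
    with pytest.raises(ValueError):
        bs.VoxelSpec(3, 0.1, b0_dir=(0, 0, 0))
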