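"""Crofton LUT properties, area accuracy against analytic solids, rectangle
placement, and replicate statistics."""

import numpy as np
import pytest

from mucoct import (
    BinaryVolume,
    ConfigurationError,
    MeasurementRectangle,
    analytic_surface_area,
    build_lut,
    crofton_area,
    effective_surface_area,
    place_rectangle,
    replicate_analysis,
)
from mucoct.phantom import PhantomSpec, generate_phantom


def _sphere(radius_um, spacing, margin=6.0, center_frac=(0.3, 0.37, 0.41)):
    n = int(np.ceil(2 * (radius_um + margin) / spacing))
    g = np.arange(n) * spacing
    c = [g[n // 2] + f * spacing for f in center_frac]
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij", sparse=True)
    occ = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius_um**2
    return BinaryVolume(occ, (spacing,) * 3)


class TestLUT:
    def test_empty_and_full_patterns_contribute_nothing(self):
        lut = build_lut(13, (1.0, 1.0, 1.0))
        assert lut.table[0] == 0.0
        assert lut.table[255] == 0.0

    def test_all_contributions_nonnegative(self):
        for spacing in [(1.0, 1.0, 1.0), (2.0, 2.0, 4.0)]:
            lut = build_lut(13, spacing)
            assert (lut.table >= 0).all()

    def test_complement_symmetry_all_128_pairs(self):
        lut = build_lut(13, (2.0, 2.0, 2.0))
        c = np.arange(256)
        assert np.allclose(lut.table[c], lut.table[255 - c])

    def test_axis_plane_response_is_exact(self):
        lut = build_lut(13, (1.0, 1.0, 1.0))
        for axis in np.eye(3):
            assert lut.plane_response(axis) == pytest.approx(1.0, abs=1e-6)

    def test_rejects_unsupported_direction_counts(self):
        with pytest.raises(ConfigurationError):
            build_lut(7, (1.0, 1.0, 1.0))

    def test_flat_interface_area_within_one_percent(self):
        # 200x200-cell axis-aligned interface, measured inside a prism that
        # keeps clear of the lattice border
        occ = np.zeros((8, 222, 222), dtype=bool)
        occ[:4] = True
        bv = BinaryVolume(occ, (1.0, 1.0, 1.0))
        lut = build_lut(13, bv.spacing)
        rect = MeasurementRectangle(
            center=np.array([3.5, 110.5, 110.5]), u=np.array([0.0, 0.0, 1.0]),
            v=np.array([0.0, 1.0, 0.0]), n=np.array([1.0, 0.0, 0.0]),
            side_u_um=200.0, side_v_um=200.0, depth_above_um=2.0, depth_below_um=2.0,
        )
        area = crofton_area(bv, lut, region=rect) * 1e6
        assert area == pytest.approx(200.0**2, rel=0.01)


class TestCroftonArea:
    def test_empty_volume_is_zero(self):
        bv = BinaryVolume(np.zeros((8, 8, 8), dtype=bool), (1.0, 1.0, 1.0))
        lut = build_lut(13, bv.spacing)
        assert crofton_area(bv, lut) == 0.0

    def test_sphere_within_two_percent(self):
        bv = _sphere(30.0, 1.0)
        lut = build_lut(13, bv.spacing)
        est = crofton_area(bv, lut) * 1e6
        assert est == pytest.approx(4 * np.pi * 30.0**2, rel=0.02)

    def test_sphere_error_decreases_with_refinement(self):
        truth = 4 * np.pi * 30.0**2
        errs = []
        for spacing in (1.0, 0.5):
            bv = _sphere(30.0, spacing)
            lut = build_lut(13, bv.spacing)
            errs.append(abs(crofton_area(bv, lut) * 1e6 / truth - 1.0))
        assert errs[1] < errs[0]

    def test_axis_aligned_box_faces(self):
        occ = np.zeros((40, 120, 120), dtype=bool)
        occ[10:30, 10:110, 10:110] = True  # 20 x 100 x 100 voxel box
        bv = BinaryVolume(occ, (1.0, 1.0, 1.0))
        lut = build_lut(13, bv.spacing)
        est = crofton_area(bv, lut) * 1e6
        truth = 2 * (100 * 100) + 4 * (100 * 20)
        assert est == pytest.approx(truth, rel=0.05)

    def test_three_direction_variant_on_axis_box(self):
        # the 3-direction estimator with isotropic weights under-counts
        # axis-aligned faces by exactly 1/3 — a sharp cross-check of the
        # transition bookkeeping independent of the 13-direction weights
        occ = np.zeros((24, 64, 64), dtype=bool)
        occ[8:16, 8:56, 8:56] = True
        bv = BinaryVolume(occ, (1.0, 1.0, 1.0))
        lut3 = build_lut(3, bv.spacing)
        truth = 2 * (48 * 48) + 4 * (48 * 8)
        assert crofton_area(bv, lut3) * 1e6 == pytest.approx(truth * 2.0 / 3.0, rel=0.02)

    def test_rotation_robustness_on_ellipsoid(self):
        # voxelize a rotated ellipsoid analytically; the area estimate must be
        # stable (< 3% spread) across random rigid orientations
        from scipy.spatial.transform import Rotation

        semi = np.array([30.0, 24.0, 18.0])
        n = 96
        g = np.arange(n) * 1.0 - n / 2 + 0.23
        zz, yy, xx = np.meshgrid(g, g, g, indexing="ij", sparse=True)
        lut = build_lut(13, (1.0, 1.0, 1.0))
        estimates = []
        for rot in Rotation.random(10, random_state=7):
            m = rot.as_matrix()
            a = m[0, 0] * zz + m[0, 1] * yy + m[0, 2] * xx
            b = m[1, 0] * zz + m[1, 1] * yy + m[1, 2] * xx
            c = m[2, 0] * zz + m[2, 1] * yy + m[2, 2] * xx
            occ = (a / semi[0]) ** 2 + (b / semi[1]) ** 2 + (c / semi[2]) ** 2 <= 1.0
            estimates.append(crofton_area(BinaryVolume(occ, (1.0, 1.0, 1.0)), lut))
        estimates = np.array(estimates)
        assert estimates.max() / estimates.min() - 1.0 < 0.03

    def test_against_marching_cubes_oracle_on_sinusoids(self):
        from skimage import measure

        for h in (100.0, 300.0):
            spec = PhantomSpec(kind="sinusoid", volume_dims=(220, 150, 150),
                               voxel_spacing=(2.0, 2.0, 2.0), slab_thickness=80.0,
                               villus_height=h, wavelength=250.0)
            binary = generate_phantom(spec)
            lut = build_lut(13, binary.spacing)
            # close the surface by padding with background so both estimators
            # measure the identical closed boundary; mild smoothing gives the
            # mesh oracle subvoxel accuracy instead of a staircase
            from scipy import ndimage

            occ = np.pad(binary.occupancy, 4)
            bv = BinaryVolume(occ, binary.spacing)
            crofton = crofton_area(bv, lut)
            smooth = ndimage.gaussian_filter(occ.astype(np.float32), 1.2)
            verts, faces, *_ = measure.marching_cubes(
                smooth, level=0.5, spacing=binary.spacing)
            mesh = measure.mesh_surface_area(verts, faces) / 1e6
            assert crofton == pytest.approx(mesh, rel=0.05)

    def test_spacing_mismatch_rejected(self, flat_slab):
        _, binary = flat_slab
        lut = build_lut(13, (1.0, 1.0, 1.0))
        with pytest.raises(Exception, match="spacing"):
            crofton_area(binary, lut)


class TestPlaceRectangle:
    def test_flat_slab_normal_is_axial(self, flat_slab):
        _, binary = flat_slab
        rect = place_rectangle(binary, 500.0, 500.0)
        angle = np.degrees(np.arccos(np.clip(rect.n @ np.array([1.0, 0, 0]), -1, 1)))
        assert angle < 1.0

    def test_tilted_slab_normal_recovered(self):
        # slab tilted 10 degrees about y: occupancy z < tan(10°)·x + 60
        tilt = np.radians(10.0)
        z = np.arange(120)[:, None, None] * 1.0
        x = np.arange(200)[None, None, :] * 1.0
        occ = np.broadcast_to(z < np.tan(tilt) * x + 30.0, (120, 200, 200)).copy()
        binary = BinaryVolume(occ, (1.0, 1.0, 1.0))
        rect = place_rectangle(binary, 100.0, 100.0)
        true_n = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
        angle = np.degrees(np.arccos(np.clip(rect.n @ true_n, -1, 1)))
        assert angle < 1.0

    def test_oversized_rectangle_reports_feasible_maximum(self, flat_slab):
        _, binary = flat_slab
        with pytest.raises(ConfigurationError, match="maximum feasible"):
            place_rectangle(binary, 10_000.0, 10_000.0)


class TestEffectiveSurfaceArea:
    def test_flat_slab_coefficient_is_one(self, flat_slab, lut2um):
        _, binary = flat_slab
        est = effective_surface_area(binary, place_rectangle(binary, 500.0, 500.0), lut2um)
        assert est.effective_coefficient == pytest.approx(1.0, abs=0.03)
        assert est.effective_coefficient == pytest.approx(
            est.measured_area_mm2 / est.rectangle_area_mm2)

    def test_degenerate_sinusoid_coefficient_is_one(self, lut2um):
        spec = PhantomSpec(kind="sinusoid", volume_dims=(64, 300, 300),
                           voxel_spacing=(2.0, 2.0, 2.0), slab_thickness=100.0,
                           villus_height=0.0, wavelength=250.0)
        binary = generate_phantom(spec)
        est = effective_surface_area(binary, place_rectangle(binary, 500.0, 500.0), lut2um)
        assert est.effective_coefficient == pytest.approx(1.0, abs=0.03)

    def test_sinusoid_matches_quadrature_oracle(self, sinusoid_300, lut2um):
        spec, binary = sinusoid_300
        truth = analytic_surface_area(spec, 500.0).expected_effective_coefficient
        est = effective_surface_area(binary, place_rectangle(binary, 500.0, 500.0), lut2um)
        assert est.effective_coefficient == pytest.approx(truth, rel=0.05)

    def test_coefficient_increases_with_amplitude(self, lut2um):
        coeffs = []
        for h in (0.0, 150.0, 300.0):
            spec = PhantomSpec(kind="sinusoid", volume_dims=(240, 200, 200),
                               voxel_spacing=(2.0, 2.0, 2.0), slab_thickness=100.0,
                               villus_height=h, wavelength=200.0)
            binary = generate_phantom(spec)
            est = effective_surface_area(binary, place_rectangle(binary, 300.0, 300.0), lut2um)
            coeffs.append(est.effective_coefficient)
        assert coeffs[0] < coeffs[1] < coeffs[2]

    def test_prism_extension_into_solid_tissue_is_inert(self, sinusoid_300, lut2um):
        _, binary = sinusoid_300
        rect = place_rectangle(binary, 400.0, 400.0)
        deeper = MeasurementRectangle(
            rect.center, rect.u, rect.v, rect.n, rect.side_u_um, rect.side_v_um,
            rect.depth_above_um, rect.depth_below_um + 60.0,
        )
        a = effective_surface_area(binary, rect, lut2um).measured_area_mm2
        b = effective_surface_area(binary, deeper, lut2um).measured_area_mm2
        assert b == pytest.approx(a, rel=0.005)

    def test_empty_prism_warns_and_returns_zero(self, flat_slab, lut2um):
        _, binary = flat_slab
        rect = MeasurementRectangle(
            center=np.array([180.0, 300.0, 300.0]), u=np.array([0.0, 0.0, 1.0]),
            v=np.array([0.0, 1.0, 0.0]), n=np.array([1.0, 0.0, 0.0]),
            side_u_um=100.0, side_v_um=100.0, depth_above_um=10.0, depth_below_um=10.0,
        )
        with pytest.warns(UserWarning, match="interface"):
            est = effective_surface_area(binary, rect, lut2um)
        assert est.measured_area_mm2 == 0.0


class TestReplicates:
    @pytest.fixture(scope="class")
    def periodic_sinusoid(self):
        spec = PhantomSpec(kind="sinusoid", volume_dims=(112, 320, 320),
                           voxel_spacing=(4.0, 4.0, 4.0), slab_thickness=60.0,
                           villus_height=300.0, wavelength=250.0)
        return generate_phantom(spec)

    def test_flat_slab_translation_invariance(self):
        spec = PhantomSpec(kind="flat_slab", volume_dims=(40, 320, 320),
                           voxel_spacing=(4.0, 4.0, 4.0), slab_thickness=60.0)
        binary = generate_phantom(spec)
        summary = replicate_analysis(binary, [0.5], n=20, seed=3)[0]
        assert summary.mean_coefficient == pytest.approx(1.0, abs=0.01)
        assert summary.ci_width < 0.01

    def test_large_squares_consistent_small_squares_noisier(self, periodic_sinusoid):
        sides = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        res = replicate_analysis(periodic_sinusoid, sides, n=20, seed=11)
        big = [s for s in res if s.side_length_mm >= 0.5]
        small = [s for s in res if s.side_length_mm < 0.5]
        means = [s.mean_coefficient for s in big]
        assert max(means) / min(means) - 1.0 < 0.05
        assert np.mean([s.ci_width for s in small]) > np.mean([s.ci_width for s in big])
        for s in res:
            assert s.ci95_low <= s.mean_coefficient <= s.ci95_high

    def test_fixed_seed_reproducible(self, periodic_sinusoid):
        a = replicate_analysis(periodic_sinusoid, [0.3], n=5, seed=21)[0]
        b = replicate_analysis(periodic_sinusoid, [0.3], n=5, seed=21)[0]
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_single_replicate_has_undefined_ci(self, periodic_sinusoid):
        with pytest.warns(UserWarning, match="confidence"):
            s = replicate_analysis(periodic_sinusoid, [0.3], n=1, seed=2)[0]
        assert np.isnan(s.ci95_low) and np.isnan(s.ci95_high)

    def test_fast_and_general_paths_agree(self, periodic_sinusoid):
        # the axis-aligned prefix-sum shortcut must match the generic
        # per-replicate prism evaluation
        import mucoct.surface as surf

        lut = build_lut(13, periodic_sinusoid.spacing)
        a = replicate_analysis(periodic_sinusoid, [0.4], n=4, seed=5, lut=lut)[0]
        orig = surf._axis_aligned
        surf._axis_aligned = lambda rect: False
        try:
            b = replicate_analysis(periodic_sinusoid, [0.4], n=4, seed=5, lut=lut)[0]
        finally:
            surf._axis_aligned = orig
        assert np.allclose(a.coefficients, b.coefficients, rtol=1e-3)
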