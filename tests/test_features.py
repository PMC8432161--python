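import numpy as np
import pytest

from lesionplan.features import (CHANNELS, MATRIX_COLUMNS, ControlStats,
                                 FeatureSet, SmoothingSpec, angle_deficits,
                                 add_asymmetry, build_control_stats,
                                 build_feature_matrix,
                                 interhemispheric_asymmetry,
                                 intrinsic_curvature,
                                 normalize_between_subjects,
                                 normalize_within_subject, sample_at_depth,
                                 smooth_overlay, triangle_areas, vertex_areas)
from lesionplan.surface_io import (AffineTransform, HemisphereSurface, Overlay,
                                   ShapeError, ValidationError)

from conftest import build_planar_grid


class TestVertexAreas:
    def test_icosahedron_symmetry(self, icosahedron):
        # unit-circumradius icosahedron: edge a = 4/sqrt(10+2*sqrt(5))
        a = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))
        total = 20.0 * (np.sqrt(3.0) / 4.0) * a ** 2
        areas = vertex_areas(icosahedron).values
        np.testing.assert_allclose(areas, total / 12.0, rtol=1e-9)

    def test_single_right_triangle(self):
        surf = HemisphereSurface([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        np.testing.assert_allclose(vertex_areas(surf).values, 1 / 6, rtol=1e-12)

    def test_conservation_random_mesh(self, sphere_mesh):
        assert abs(vertex_areas(sphere_mesh).values.sum()
                   - triangle_areas(sphere_mesh).sum()) < 1e-9

    def test_degenerate_triangle_warns(self):
        surf = HemisphereSurface([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]],
                                 [[0, 1, 2], [0, 1, 3]])
        with pytest.warns(UserWarning, match="degenerate"):
            vertex_areas(surf)


class TestIntrinsicCurvature:
    def test_sphere_closed_form(self, fine_sphere_mesh):
        k = intrinsic_curvature(fine_sphere_mesh).values
        assert abs(np.nanmean(k) * 25.0 ** 2 - 1.0) < 0.05

    def test_planar_interior_zero(self, planar_grid):
        k = intrinsic_curvature(planar_grid).values
        n = 15
        interior = np.array([i * n + j for i in range(1, n - 1)
                             for j in range(1, n - 1)])
        np.testing.assert_allclose(k[interior], 0.0, atol=1e-9)

    def test_gauss_bonnet(self, sphere_mesh):
        assert abs(angle_deficits(sphere_mesh).sum() - 4.0 * np.pi) < 1e-6

    def test_isolated_vertex_nan(self):
        surf = HemisphereSurface([[0, 0, 0], [1, 0, 0], [0, 1, 0], [9, 9, 9]],
                                 [[0, 1, 2]])
        assert np.isnan(intrinsic_curvature(surf).values[3])


class TestSampleAtDepth:
    @staticmethod
    def _vertical_cortex():
        # vertex-paired flat patch: white at z=0, gray at z=2
        white = build_planar_grid(4)
        gray = HemisphereSurface(white.vertex_coords + [0, 0, 2.0],
                                 white.triangles)
        return white, gray

    def test_constant_volume(self):
        white, gray = self._vertical_cortex()
        vol = np.full((10, 10, 10), 100.0)
        aff = AffineTransform(np.eye(4))
        got = sample_at_depth(vol, aff, white, gray, depth_fraction=0.5)
        np.testing.assert_allclose(got.values, 100.0)

    def test_linear_ramp(self):
        white, gray = self._vertical_cortex()
        zs = np.arange(10, dtype=float)
        vol = np.broadcast_to(zs, (10, 10, 10)).copy()
        aff = AffineTransform(np.eye(4))
        got = sample_at_depth(vol, aff, white, gray, depth_fraction=0.5)
        np.testing.assert_allclose(got.values, 1.0, atol=1e-9)

    def test_depth_zero_is_white_surface(self):
        white, gray = self._vertical_cortex()
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(10, 10, 10))
        aff = AffineTransform(np.eye(4))
        got = sample_at_depth(vol, aff, white, gray, depth_fraction=0.0)
        from scipy.ndimage import map_coordinates
        expected = map_coordinates(vol, white.vertex_coords.T, order=1)
        np.testing.assert_allclose(got.values, expected, atol=1e-12)

    def test_subcortical_direction(self):
        white, gray = self._vertical_cortex()
        zs = np.arange(10, dtype=float)
        vol = np.broadcast_to(zs, (10, 10, 10)).copy() + 5.0
        aff = AffineTransform(np.eye(4))
        # shift the cortex up so the 1 mm subcortical sample stays in-volume
        white2 = HemisphereSurface(white.vertex_coords + [0, 0, 3.0],
                                   white.triangles)
        gray2 = HemisphereSurface(gray.vertex_coords + [0, 0, 3.0],
                                  gray.triangles)
        got2 = sample_at_depth(vol, aff, white2, gray2, subcortical_mm=1.0)
        np.testing.assert_allclose(got2.values, 7.0, atol=1e-9)

    def test_outside_volume_masked(self):
        white, gray = self._vertical_cortex()
        vol = np.full((2, 2, 2), 1.0)
        aff = AffineTransform(np.eye(4))
        with pytest.warns(UserWarning, match="outside"):
            got = sample_at_depth(vol, aff, white, gray, depth_fraction=1.0)
        assert np.isnan(got.values).any()


class TestSmoothing:
    def test_constant_unchanged(self, sphere_mesh):
        const = Overlay(np.full(sphere_mesh.n_vertices, 3.7))
        got = smooth_overlay(sphere_mesh, const, 10.0)
        np.testing.assert_allclose(got.values, 3.7, atol=1e-9)

    def test_fwhm_zero_identity(self, sphere_mesh):
        rng = np.random.default_rng(0)
        overlay = Overlay(rng.normal(size=sphere_mesh.n_vertices))
        got = smooth_overlay(sphere_mesh, overlay, 0.0)
        np.testing.assert_array_equal(got.values, overlay.values)

    def test_mass_conservation(self, sphere_mesh):
        rng = np.random.default_rng(1)
        overlay = Overlay(rng.normal(size=sphere_mesh.n_vertices))
        areas = vertex_areas(sphere_mesh).values
        before = float(areas @ overlay.values)
        after = float(areas @ smooth_overlay(sphere_mesh, overlay, 10.0).values)
        assert abs(after - before) <= 1e-6 * max(abs(before), 1.0)

    def test_impulse_matches_bruteforce_gaussian(self):
        grid = build_planar_grid(n=25)
        n = 25
        center = (n // 2) * n + n // 2
        fwhm = 6.0
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        impulse = np.zeros(n * n)
        impulse[center] = 1.0
        got = smooth_overlay(grid, Overlay(impulse), fwhm).values
        # brute-force oracle: exact (Euclidean) geodesic Gaussian weights
        verts = grid.vertex_coords
        areas = vertex_areas(grid).values
        dist = np.linalg.norm(verts[:, None, :] - verts[None, :, :], axis=2)
        kernel = np.exp(-0.5 * (dist / sigma) ** 2)
        weights = (kernel * areas[None, :]) / (kernel @ areas)[:, None]
        oracle = weights[:, center]
        rms = np.sqrt(np.mean((got - oracle) ** 2)) / oracle.max()
        assert rms < 0.05

    def test_negative_fwhm_rejected(self, sphere_mesh):
        with pytest.raises(ValueError):
            smooth_overlay(sphere_mesh, Overlay(np.zeros(sphere_mesh.n_vertices)), -1.0)


class TestSmoothingSpec:
    def test_defaults(self):
        spec = SmoothingSpec()
        assert spec.fwhm("thickness") == 10.0
        assert spec.fwhm("intrinsic_curvature") == 20.0
        assert spec.fwhm("mean_curvature") == 0.0
        assert spec.fwhm("sulcal_depth") == 0.0
        assert all(spec.fwhm(c) == 10.0 for c in CHANNELS
                   if c.startswith("intensity"))

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            SmoothingSpec({"thickness": -1.0})


class TestNormalization:
    def test_closed_form_z(self):
        got = normalize_within_subject(Overlay(np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(got.values, [-1.2247448, 0.0, 1.2247448],
                                   atol=1e-6)

    def test_constant_overlay_zeros(self):
        with pytest.warns(UserWarning, match="near-constant"):
            got = normalize_within_subject(Overlay(np.full(10, 4.0)))
        np.testing.assert_array_equal(got.values, 0.0)

    def test_output_mean_zero(self):
        rng = np.random.default_rng(3)
        got = normalize_within_subject(Overlay(rng.normal(2, 5, size=100)))
        assert abs(got.values.mean()) < 1e-9
        assert abs(got.values.std() - 1.0) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        once = normalize_within_subject(Overlay(rng.normal(size=50)))
        twice = normalize_within_subject(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_too_few_vertices(self):
        with pytest.raises(ValidationError):
            normalize_within_subject(Overlay(np.array([1.0])))

    def test_between_subject_arithmetic(self):
        stats = ControlStats(
            mean={"left": {"thickness": np.array([2.5])}},
            sd={"left": {"thickness": np.array([0.25])}}, n_controls=5)
        got = normalize_between_subjects(Overlay(np.array([3.0])), stats,
                                         "thickness", "left")
        np.testing.assert_allclose(got.values, [2.0])

    def test_between_subject_missing_channel(self):
        stats = ControlStats(mean={"left": {}}, sd={"left": {}}, n_controls=5)
        with pytest.raises(ValidationError, match="thickness"):
            normalize_between_subjects(Overlay(np.zeros(3)), stats,
                                       "thickness", "left")

    def test_between_subject_sd_floor(self):
        stats = ControlStats(
            mean={"left": {"thickness": np.array([1.0, 1.0])}},
            sd={"left": {"thickness": np.array([0.0, 1.0])}}, n_controls=5)
        got = normalize_between_subjects(Overlay(np.array([1.1, 2.0])), stats,
                                        "thickness", "left")
        assert np.isfinite(got.values).all()

    def test_control_self_normalization(self):
        rng = np.random.default_rng(5)
        controls = []
        for _ in range(20):
            controls.append({
                "left": FeatureSet({"thickness": rng.normal(2.5, 0.3, 50)},
                                   "left"),
                "right": FeatureSet({"thickness": rng.normal(2.5, 0.3, 50)},
                                    "right")})
        stats = build_control_stats(controls)
        zs = [normalize_between_subjects(
            Overlay(c["left"].channels["thickness"]), stats, "thickness",
            "left").values for c in controls]
        assert abs(np.mean(zs)) < 0.1


class TestAsymmetry:
    def test_identical_hemispheres_zero(self):
        v = Overlay(np.arange(5, dtype=float))
        la, ra = interhemispheric_asymmetry(v, Overlay(v.values.copy()))
        np.testing.assert_array_equal(la.values, 0.0)
        np.testing.assert_array_equal(ra.values, 0.0)

    def test_arithmetic(self):
        la, ra = interhemispheric_asymmetry(Overlay([1.0, 2.0]),
                                            Overlay([0.0, 2.0]))
        np.testing.assert_array_equal(la.values, [1.0, 0.0])
        np.testing.assert_array_equal(ra.values, [-1.0, 0.0])

    def test_antisymmetry_random(self):
        rng = np.random.default_rng(6)
        l = Overlay(rng.normal(size=30))
        r = Overlay(rng.normal(size=30))
        la, ra = interhemispheric_asymmetry(l, r)
        np.testing.assert_array_equal(la.values + ra.values, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            interhemispheric_asymmetry(Overlay(np.zeros(3)), Overlay(np.zeros(4)))


class TestFeatureMatrix:
    @staticmethod
    def _complete_featureset(n=10, seed=0):
        rng = np.random.default_rng(seed)
        subj = {h: FeatureSet({c: rng.normal(size=n) for c in CHANNELS}, h,
                              stage="raw")
                for h in ("left", "right")}
        for fs in subj.values():
            fs.advance_stage("normalized")
        return add_asymmetry(subj)

    def test_column_count(self):
        subj = self._complete_featureset()
        matrix = build_feature_matrix(subj["left"])
        # 11 quoted feature channels plus their asymmetry counterparts
        assert matrix.shape == (10, 22)
        assert len(MATRIX_COLUMNS) == 22

    def test_zero_row(self):
        subj = {h: FeatureSet({c: np.zeros(4) for c in CHANNELS}, h,
                              stage="normalized") for h in ("left", "right")}
        aug = add_asymmetry(subj)
        matrix = build_feature_matrix(aug["left"])
        np.testing.assert_array_equal(matrix[0], 0.0)

    def test_deterministic_column_order(self):
        subj = self._complete_featureset(seed=2)
        m1 = build_feature_matrix(subj["left"])
        m2 = build_feature_matrix(subj["left"])
        assert m1.tobytes() == m2.tobytes()

    def test_missing_channel_named(self):
        subj = self._complete_featureset()
        del subj["left"].channels["sulcal_depth"]
        with pytest.raises(ValidationError, match="sulcal_depth"):
            build_feature_matrix(subj["left"])

    def test_requires_asymmetry_stage(self):
        fs = FeatureSet({c: np.zeros(4) for c in CHANNELS}, "left", stage="raw")
        with pytest.raises(ValidationError):
            build_feature_matrix(fs)


class TestStageTransitions:
    def test_forward_only(self):
        fs = FeatureSet({"thickness": np.zeros(3)}, "left", stage="smoothed")
        with pytest.raises(ValidationError):
            fs.advance_stage("raw")
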