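"""The five-term convex fusion objective and its solvers."""

import numpy as np
import pytest

import spadfuse as sf
from spadfuse.forward_model import build_forward_matrix
from spadfuse.reconstruction import (
    Tv2dOperator,
    grad2d,
    rescale_ccd,
    temporal_histogram,
    temporal_integrate,
    tv2d,
)


class TestTemporalOperators:
    def test_integrate_cube_of_ones(self):
        cube = sf.TransientCube(np.ones((5, 3, 4)))
        np.testing.assert_array_equal(temporal_integrate(cube).values, np.full((3, 4), 5.0))

    def test_integrate_single_bin_is_identity(self, rng):
        frame = rng.random((6, 6))
        cube = sf.TransientCube(frame[None])
        np.testing.assert_array_equal(temporal_integrate(cube).values, frame)

    def test_integrate_conserves_total(self, rng):
        cube = sf.TransientCube(rng.random((7, 5, 5)))
        assert temporal_integrate(cube).total() == pytest.approx(cube.total(), rel=1e-12)

    def test_histogram_impulse_normalizes_to_unit_mass(self):
        vals = np.zeros((6, 4, 4))
        vals[3] = 2.0
        h = temporal_histogram(sf.TransientCube(vals), normalize=True)
        expect = np.zeros(6)
        expect[3] = 1.0
        np.testing.assert_allclose(h, expect)

    def test_histogram_uniform_cube(self):
        h = temporal_histogram(sf.TransientCube(np.ones((4, 3, 3))), normalize=True)
        np.testing.assert_allclose(h, 0.25)

    def test_zero_cube_normalizes_to_zero_vector(self):
        h = temporal_histogram(sf.TransientCube(np.zeros((4, 3, 3))), normalize=True)
        np.testing.assert_array_equal(h, 0.0)

    def test_histogram_shape_preserved_by_mass_conserving_forward(self, rng):
        # with every sub-pixel active and no dead pixels, A conserves each
        # bin's mass, so the low-res histogram equals the high-res one
        geom = sf.FusionGeometry(
            M=12, N=12, m=4, n=4, blur_sigma=2.0,
            active_offsets=frozenset((i, j) for i in range(3) for j in range(3)),
        )
        cube = sf.TransientCube(rng.random((5, 12, 12)))
        h_high = temporal_histogram(cube, normalize=True)
        h_low = temporal_histogram(sf.forward_project_cube(cube, geom), normalize=True)
        np.testing.assert_allclose(h_low, h_high, rtol=1e-10)


class TestTotalVariation:
    def test_constant_frame_has_zero_tv(self):
        assert tv2d(np.full((1, 5, 7), 4.2)) == 0.0

    def test_step_edge_tv_equals_rows(self):
        frame = np.zeros((6, 8))
        frame[:, 4:] = 1.0
        assert tv2d(frame[None]) == 6.0

    def test_matches_double_loop_oracle(self, rng):
        frames = rng.random((3, 6, 7))
        total = 0.0
        for f in frames:
            for i in range(6):
                for j in range(7):
                    if i + 1 < 6:
                        total += abs(f[i + 1, j] - f[i, j])
                    if j + 1 < 7:
                        total += abs(f[i, j + 1] - f[i, j])
        assert tv2d(frames) == pytest.approx(total, rel=1e-12)

    def test_operator_adjoint_consistency(self, rng):
        op = Tv2dOperator(5, 6)
        x = rng.standard_normal(30)
        y = rng.standard_normal(op.shape[0])
        assert np.dot(op.matvec(x), y) == pytest.approx(np.dot(x, op.rmatvec(y)), rel=1e-12)

    def test_operator_matvec_matches_grad2d(self, rng):
        op = Tv2dOperator(4, 5)
        frame = rng.random((4, 5))
        gr, gc = grad2d(frame)
        np.testing.assert_allclose(
            op.matvec(frame.ravel()), np.concatenate([gr.ravel(), gc.ravel()])
        )


class TestRescaleCcd:
    def test_round_trip_total(self, rng, small_geometry):
        c = sf.IntensityImage(rng.random((12, 12)) + 0.1)
        d = sf.TransientCube(rng.random((3, 4, 4)), grid=sf.LOW)
        c_s = rescale_ccd(c, d, small_geometry)
        fwd = sf.forward_project_frame(c_s, small_geometry)
        assert fwd.total() == pytest.approx(d.total(), rel=1e-12)

    def test_homogeneity(self, rng, small_geometry):
        c = sf.IntensityImage(rng.random((12, 12)) + 0.1)
        d = sf.TransientCube(rng.random((3, 4, 4)), grid=sf.LOW)
        s1 = rescale_ccd(c, d, small_geometry).total() / c.total()
        s2 = rescale_ccd(c.with_values(2 * c.values), d, small_geometry).total() / (2 * c.total())
        assert s2 == pytest.approx(s1 / 2, rel=1e-12)

    def test_consistent_image_unchanged(self, rng, small_geometry):
        c = sf.IntensityImage(rng.random((12, 12)) + 0.1)
        total = sf.forward_project_frame(c, small_geometry).total()
        d_vals = np.full((1, 4, 4), total / 16)
        c_s = rescale_ccd(c, sf.TransientCube(d_vals, grid=sf.LOW), small_geometry)
        np.testing.assert_allclose(c_s.values, c.values, rtol=1e-12)

    def test_zero_image_rejected(self, small_geometry):
        c = sf.IntensityImage(np.zeros((12, 12)))
        d = sf.TransientCube(np.ones((1, 4, 4)), grid=sf.LOW)
        with pytest.raises(ValueError, match="zero"):
            rescale_ccd(c, d, small_geometry)


class TestObjectiveValue:
    def test_all_zero_inputs_give_zero(self, small_geometry):
        i = sf.TransientCube(np.zeros((2, 12, 12)))
        d = sf.TransientCube(np.zeros((2, 4, 4)), grid=sf.LOW)
        c = sf.IntensityImage(np.zeros((12, 12)))
        w = sf.RegularizationWeights(1, 1, 1, 1)
        assert sf.objective_value(i, d, c, small_geometry, w) == 0.0

    def test_zero_weights_leave_data_term_only(self, rng, small_geometry):
        i = sf.TransientCube(rng.random((2, 12, 12)))
        d = sf.TransientCube(rng.random((2, 4, 4)), grid=sf.LOW)
        c = sf.IntensityImage(rng.random((12, 12)))
        w0 = sf.RegularizationWeights(0, 0, 0, 0)
        fwd = sf.forward_project_cube(i, small_geometry)
        expect = np.linalg.norm((fwd.values - d.values).ravel())
        assert sf.objective_value(i, d, c, small_geometry, w0) == pytest.approx(expect, rel=1e-12)

    def test_matches_dense_matrix_recomputation(self, rng, small_geometry):
        """From-scratch oracle: every term rebuilt with the explicit matrix
        and plain numpy norms."""
        i_vals = rng.random((5, 12, 12))
        d_vals = rng.random((5, 4, 4))
        c_vals = rng.random((12, 12))
        w = sf.RegularizationWeights(0.7, 0.3, 0.05, 0.02)

        A = build_forward_matrix(small_geometry)
        r_data = np.linalg.norm(
            np.concatenate([A @ i_vals[k].ravel() - d_vals[k].ravel() for k in range(5)])
        )
        r_ccd = np.linalg.norm((i_vals.sum(0) - c_vals).ravel())
        h_i = i_vals.sum(axis=(1, 2)) / c_vals.sum()
        h_d = d_vals.sum(axis=(1, 2)) / d_vals.sum()
        r_hist = np.linalg.norm(h_i - h_d)
        l1 = np.abs(i_vals).sum()
        tv = sum(
            abs(f[i + 1, j] - f[i, j])
            for f in i_vals for i in range(11) for j in range(12)
        ) + sum(
            abs(f[i, j + 1] - f[i, j])
            for f in i_vals for i in range(12) for j in range(11)
        )
        expect = r_data + w.alpha * r_ccd + w.beta * r_hist + w.gamma * l1 + w.delta * tv

        got = sf.objective_value(
            sf.TransientCube(i_vals),
            sf.TransientCube(d_vals, grid=sf.LOW),
            sf.IntensityImage(c_vals),
            small_geometry,
            w,
        )
        assert got == pytest.approx(expect, rel=1e-10)

    def test_shape_mismatch_rejected(self, small_geometry):
        i = sf.TransientCube(np.zeros((2, 10, 10)))
        d = sf.TransientCube(np.zeros((2, 4, 4)), grid=sf.LOW)
        c = sf.IntensityImage(np.zeros((12, 12)))
        with pytest.raises(ValueError, match="inconsistent"):
            sf.objective_value(i, d, c, small_geometry, sf.RegularizationWeights(0, 0, 0, 0))


class TestWeightPresets:
    def test_published_parameter_table(self):
        lidar = sf.WEIGHT_PRESETS["lidar"]
        assert (lidar.alpha, lidar.beta, lidar.gamma, lidar.delta) == (1.0, 1e-4, 1e-2, 0.0)
        flim = sf.WEIGHT_PRESETS["flim"]
        assert (flim.alpha, flim.beta, flim.gamma, flim.delta) == (1.0, 1e-3, 1e-7, 1e-5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            sf.RegularizationWeights(-1, 0, 0, 0)


class TestReconstruct:
    def test_degenerate_identity_recovery(self, rng, identity_geometry):
        """With A = I and all weights zero the program returns d itself."""
        d = sf.TransientCube(rng.random((4, 6, 6)), grid=sf.LOW)
        c = sf.IntensityImage(np.ones((6, 6)))
        res = sf.reconstruct(d, c, identity_geometry, sf.RegularizationWeights(0, 0, 0, 0))
        rel = np.linalg.norm(res.cube.values - d.values) / np.linalg.norm(d.values)
        assert rel <= 1e-6

    def test_zero_data_alpha_zero_returns_zero_cube(self, identity_geometry):
        d = sf.TransientCube(np.zeros((3, 6, 6)), grid=sf.LOW)
        c = sf.IntensityImage(np.ones((6, 6)))
        res = sf.reconstruct(d, c, identity_geometry, sf.RegularizationWeights(0, 0, 1e-2, 0))
        np.testing.assert_array_equal(res.cube.values, 0.0)

    def test_result_is_nonnegative_and_finite(self, lidar_scene, small_geometry):
        truth = sf.render_ground_truth(lidar_scene)
        d, c = sf.render_measurements(truth, small_geometry, seed=3)
        res = sf.reconstruct(d, c, small_geometry, sf.WEIGHT_PRESETS["lidar"], max_iter=500)
        assert res.cube.values.min() >= 0.0
        assert np.isfinite(res.objective)
        assert res.solver_status in ("converged", "discrepancy", "stagnation", "max_iter")

    def test_objective_bounded_by_ground_truth_on_noiseless_scene(
        self, lidar_scene, small_geometry
    ):
        truth = sf.render_ground_truth(lidar_scene)
        d, c = sf.render_measurements(truth, small_geometry, noise=False)
        w = sf.WEIGHT_PRESETS["lidar"]
        res = sf.reconstruct(
            d, c, small_geometry, w, max_iter=20000, discrepancy=None, tol=1e-12
        )
        c_s = rescale_ccd(c, d, small_geometry)
        obj_truth = sf.objective_value(truth, d, c_s, small_geometry, w)
        assert res.objective <= obj_truth * (1 + 1e-6) + 1e-9

    def test_solver_routes_agree_on_small_instance(self, rng):
        geom = sf.FusionGeometry(M=8, N=8, m=4, n=4, blur_sigma=1.0)
        depth = np.ones((8, 8), dtype=int)
        spec = sf.SceneSpec(
            mode="lidar", M=8, N=8, tau=4, bin_width_ps=100.0, depth=depth,
            reflectivity=np.ones((8, 8)), irf_sigma=0.5, exposure_scale=1e4,
        )
        truth = sf.render_ground_truth(spec)
        d, c = sf.render_measurements(truth, geom, noise=False)
        w = sf.WEIGHT_PRESETS["lidar"]
        p = sf.reconstruct(d, c, geom, w, solver="pdhg", max_iter=40000, discrepancy=None, tol=1e-13)
        l = sf.reconstruct(d, c, geom, w, solver="lbfgs", max_iter=20000, discrepancy=None, tol=1e-16)
        assert abs(p.objective - l.objective) <= 1e-3 * max(p.objective, l.objective)

    def test_tv_monotone_in_delta(self, lidar_scene, small_geometry):
        truth = sf.render_ground_truth(lidar_scene)
        d, c = sf.render_measurements(truth, small_geometry, noise=False)
        tvs = []
        for delta in (0.0, 1e-2, 1e-1, 1.0):
            w = sf.RegularizationWeights(1.0, 1e-4, 1e-2, delta)
            res = sf.reconstruct(
                d, c, small_geometry, w, max_iter=20000, discrepancy=None, tol=1e-12
            )
            tvs.append(tv2d(res.cube.values))
        for lo, hi in zip(tvs[1:], tvs[:-1]):
            assert lo <= hi * 1.001 + 1e-9

    def test_inconsistent_shapes_rejected(self, small_geometry):
        d = sf.TransientCube(np.ones((2, 5, 5)), grid=sf.LOW)
        c = sf.IntensityImage(np.ones((12, 12)))
        with pytest.raises(ValueError, match="does not match"):
            sf.reconstruct(d, c, small_geometry, sf.WEIGHT_PRESETS["lidar"])

    def test_unknown_solver_rejected(self, identity_geometry):
        d = sf.TransientCube(np.ones((1, 6, 6)), grid=sf.LOW)
        c = sf.IntensityImage(np.ones((6, 6)))
        with pytest.raises(ValueError, match="unknown solver"):
            sf.reconstruct(d, c, identity_geometry, sf.WEIGHT_PRESETS["lidar"], solver="cvx")

    def test_squared_variant_runs_and_reports_squared_objective(
        self, lidar_scene, small_geometry
    ):
        truth = sf.render_ground_truth(lidar_scene)
        d, c = sf.render_measurements(truth, small_geometry, seed=5)
        res = sf.reconstruct(
            d, c, small_geometry, sf.WEIGHT_PRESETS["lidar"],
            squared=True, max_iter=2000, discrepancy=None,
        )
        c_s = rescale_ccd(c, d, small_geometry)
        recomputed = sf.objective_value(
            res.cube, d, c_s, small_geometry, sf.WEIGHT_PRESETS["lidar"], squared=True
        )
        assert res.objective == pytest.approx(recomputed, rel=1e-12)
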