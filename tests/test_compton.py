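import numpy as np
import pandas as pd
import pytest

from hybridpgi.compton import (FovWeights, KinematicsError,
                               RegularizationError, analytic_invert,
                               backproject_cones, combine_images,
                               compton_half_angle, compute_fov_weights,
                               reconstruct_pgi)
from hybridpgi.images import GridSpec, Image2D, rebin

from conftest import make_point_source_cones


class TestComptonKinematics:
    def test_forward_scattering_limit(self):
        assert compton_half_angle(1e-6, 1000.0) == pytest.approx(0.0,
                                                                 abs=1e-3)

    def test_worked_example_200_1000(self):
        # cos(theta) = 1 - 511 (1/1000 - 1/1200) = 0.914833...
        theta = compton_half_angle(200.0, 1000.0)
        assert np.cos(theta) == pytest.approx(0.9148333, abs=1e-6)
        assert np.degrees(theta) == pytest.approx(23.818, abs=0.01)

    def test_invalid_pair_raises(self):
        # cos(theta) = 1 - 511 (1/100 - 1/500) = -3.088
        with pytest.raises(KinematicsError):
            compton_half_angle(400.0, 100.0)

    def test_nonpositive_energy_raises(self):
        with pytest.raises(KinematicsError):
            compton_half_angle(0.0, 500.0)


def _single_cone(apex, axis, theta):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return pd.DataFrame({
        "apex_x": [apex[0]], "apex_y": [apex[1]], "apex_z": [apex[2]],
        "axis_x": [axis[0]], "axis_y": [axis[1]], "axis_z": [axis[2]],
        "half_angle": [theta], "imager": ["A"],
    })


class TestBackprojection:
    def test_vertical_cone_ridge_on_circle(self):
        # apex above the origin, axis straight down, 45 degrees: the conic
        # is the circle x^2 + y^2 = 100^2
        cone = _single_cone((0, 0, 100.0), (0, 0, -1.0), np.deg2rad(45))
        g = GridSpec((-150, 150, -150, 150), 300, 300)
        img = backproject_cones(cone, g, ring_sigma=2.0)
        iy, ix = np.where(img.values > 0.99 * img.values.max())
        radii = np.hypot(img.x_centers[ix], img.y_centers[iy])
        assert radii == pytest.approx(100.0, abs=1.5)

    def test_point_source_argmax_within_one_pixel(self, setup, rng):
        src = (-80.0, 0.0, 0.0)
        cones = make_point_source_cones(src, setup, 10_000, rng)
        g = GridSpec((-130, -30, -25, 25), 100, 50)  # 1 mm pixels
        img = backproject_cones(cones, g, ring_sigma=3.0)
        x, y = img.argmax_xy()
        assert abs(x - src[0]) <= 1.0
        assert abs(y - src[1]) <= 1.0

    def test_linearity_in_event_weights(self, setup, rng):
        cones = make_point_source_cones((-60, 0, 0), setup, 200, rng)
        g = GridSpec((-90, -30, -15, 15), 60, 30)
        img1 = backproject_cones(cones, g)
        img2 = backproject_cones(cones, g,
                                 weights=2.0 * np.ones(len(cones)))
        np.testing.assert_allclose(img2.values, 2.0 * img1.values,
                                   rtol=1e-12)

    def test_permutation_invariance(self, setup, rng):
        cones = make_point_source_cones((-60, 0, 0), setup, 300, rng)
        g = GridSpec((-90, -30, -15, 15), 60, 30)
        img1 = backproject_cones(cones, g)
        img2 = backproject_cones(
            cones.sample(frac=1.0, random_state=1), g)
        np.testing.assert_allclose(img1.values, img2.values, atol=1e-9)

    def test_empty_event_set_raises(self):
        g = GridSpec((-10, 10, -10, 10), 10, 10)
        with pytest.raises(ValueError):
            backproject_cones(_single_cone((0, 0, 1), (0, 0, -1),
                                           0.5).iloc[:0], g)

    def test_generator_cones_contain_source(self, setup, rng):
        # generator-kinematics consistency: the true source direction lies
        # on every unsmeared cone within 1e-6 rad
        src = np.array([-70.0, 5.0, 0.0])
        cones = make_point_source_cones(src, setup, 500, rng)
        apex = cones[["apex_x", "apex_y", "apex_z"]].to_numpy()
        axis = cones[["axis_x", "axis_y", "axis_z"]].to_numpy()
        u = src - apex
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        ang = np.arccos(np.clip(np.einsum("ij,ij->i", u, axis), -1, 1))
        np.testing.assert_allclose(ang, cones["half_angle"], atol=1e-6)


class TestAnalyticInversion:
    GRID = GridSpec((-120, 0, -30, 30), 120, 60)  # 1 mm pixels

    def test_matches_backprojection_argmax(self, setup, rng):
        src = (-65.0, 5.0, 0.0)
        cones = make_point_source_cones(src, setup, 8000, rng)
        bp = backproject_cones(cones, self.GRID, ring_sigma=3.0)
        parts = [analytic_invert(grp, self.GRID, l_max=40).values
                 for _, grp in cones.groupby("imager")]
        ai = Image2D(self.GRID, np.sum(parts, axis=0))
        bx, by = bp.argmax_xy()
        axx, ay = ai.argmax_xy()
        assert abs(bx - axx) <= 1.0 and abs(by - ay) <= 1.0

    def test_shift_covariance(self, setup, rng):
        g = GridSpec((-130, 10, -30, 30), 140, 60)
        maxima = []
        for x0 in (-80.0, -70.0):
            cones = make_point_source_cones(
                (x0, 0, 0), setup, 6000, np.random.default_rng(3))
            parts = [analytic_invert(grp, g, l_max=40).values
                     for _, grp in cones.groupby("imager")]
            maxima.append(Image2D(g, np.sum(parts, axis=0)).argmax_xy()[0])
        assert maxima[1] - maxima[0] == pytest.approx(10.0, abs=1.0)

    def test_oscillations_shrink_with_statistics(self, setup):
        rng = np.random.default_rng(7)
        g = GridSpec((-120, 20, -35, 35), 140, 70)
        rel = {}
        for n in (1000, 10_000):
            cones = make_point_source_cones((-50, 0, 0), setup, n, rng)
            parts = [analytic_invert(grp, g, l_max=40).values
                     for _, grp in cones.groupby("imager")]
            img = np.sum(parts, axis=0)
            # source-free corner region vs the peak
            quiet = img[:15, :20]
            rel[n] = quiet.std() / img.max()
        assert rel[10_000] < rel[1000]

    def test_lmax_zero_gives_uniform_image(self, setup, rng):
        cones = make_point_source_cones((-60, 0, 0), setup, 500, rng)
        img = analytic_invert(cones[cones["imager"] == "A"],
                              self.GRID, l_max=0)
        assert np.ptp(img.values) <= 1e-9 * abs(img.values).max()

    def test_min_events_enforced(self, setup, rng):
        cones = make_point_source_cones((-60, 0, 0), setup, 5, rng)
        with pytest.raises(ValueError):
            analytic_invert(cones, self.GRID, min_events=10)

    def test_all_coefficients_below_floor_raises(self, setup, rng):
        cones = make_point_source_cones((-60, 0, 0), setup, 100, rng)
        with pytest.raises(RegularizationError):
            analytic_invert(cones, self.GRID, l_max=20, floor=1e9)


class TestFovWeightsAndCombination:
    def test_weight_peaks_facing_scatter_center(self, setup):
        g = GridSpec((-150, 150, -60, 60), 75, 30)
        w = compute_fov_weights(setup, g, n_lattice=(31, 7),
                                n_photons=20_000, seed=1)
        for im_id in ("A", "B"):
            m = w.maps[im_id]
            cx = setup.imagers[im_id].scatter.center[0]
            x_at_max, _ = m.argmax_xy()
            assert abs(x_at_max - cx) <= 10.0
            assert m.values.max() == pytest.approx(1.0)

    def test_mirror_imagers_have_mirror_maps(self, setup):
        g = GridSpec((-150, 150, -60, 60), 75, 30)
        w = compute_fov_weights(setup, g, n_lattice=(15, 7),
                                n_photons=4000, seed=1)
        # A (+z) and D (-z) see the z = 0 plane identically
        np.testing.assert_allclose(w.maps["A"].values, w.maps["D"].values,
                                   atol=1e-12)

    def test_identical_images_equal_weights_identity(self):
        g = GridSpec((-10, 10, -10, 10), 20, 20)
        base = Image2D(g, np.random.default_rng(0).random((20, 20)))
        ones = Image2D(g, np.ones((20, 20)))
        w = FovWeights({"A": ones, "D": ones})
        out = combine_images({"A": base, "D": base}, w)
        np.testing.assert_allclose(out.values, base.values)

    def test_efficiency_scale_correction(self):
        g = GridSpec((-10, 10, -10, 10), 20, 20)
        img = Image2D(g, np.full((20, 20), 0.93))
        ones = Image2D(g, np.ones((20, 20)))
        out = combine_images({"C": img}, FovWeights({"C": ones}),
                             efficiency_scales={"C": 0.93})
        np.testing.assert_allclose(out.values, 1.0)

    def test_zero_weight_image_ignored(self):
        g = GridSpec((-10, 10, -10, 10), 20, 20)
        a = Image2D(g, np.full((20, 20), 3.0))
        b = Image2D(g, np.zeros((20, 20)))
        w = FovWeights({"A": Image2D(g, np.ones((20, 20))),
                        "B": Image2D(g, np.zeros((20, 20)))})
        out = combine_images({"A": a, "B": b}, w)
        np.testing.assert_allclose(out.values, a.values)

    def test_grid_mismatch_raises(self):
        g1 = GridSpec((-10, 10, -10, 10), 20, 20)
        g2 = GridSpec((-10, 10, -10, 10), 10, 10)
        w = FovWeights({"A": Image2D(g2, np.ones((10, 10)))})
        with pytest.raises(ValueError):
            combine_images({"A": Image2D(g1, np.ones((20, 20)))}, w)


class TestReconstructPgi:
    def test_analytic_route_combines_imagers(self, setup, rng):
        cones = make_point_source_cones((-60, 0, 0), setup, 2000, rng)
        g = GridSpec((-100, -20, -20, 20), 80, 40)
        img = reconstruct_pgi(cones, g, setup, method="analytic", l_max=30)
        x, y = img.argmax_xy()
        assert abs(x + 60.0) <= 2.0
        assert abs(y) <= 2.0

    def test_unknown_method_rejected(self, setup, rng):
        cones = make_point_source_cones((-60, 0, 0), setup, 100, rng)
        g = GridSpec((-100, -20, -20, 20), 40, 20)
        with pytest.raises(ValueError):
            reconstruct_pgi(cones, g, setup, method="mlem")


class TestRebin:
    def test_block_sum_preserves_total(self):
        g = GridSpec((-10, 10, -10, 10), 20, 20)
        img = Image2D(g, np.random.default_rng(0).random((20, 20)))
        r = rebin(img, 4)
        assert r.values.shape == (5, 5)
        assert r.values.sum() == pytest.approx(img.values.sum())

    def test_indivisible_factor_raises(self):
        g = GridSpec((-10, 10, -10, 10), 20, 20)
        with pytest.raises(ValueError):
            rebin(Image2D(g, np.zeros((20, 20))), 3)
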