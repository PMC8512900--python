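"""Landmark detection steps: oracles, symmetry, and end-to-end recovery
on the default synthetic body."""

from __future__ import annotations

import numpy as np
import pytest

from backmark.config import DetectionConfig
from backmark.detection import (
    DetectionContext,
    DetectionFailure,
    LandmarkDetector,
    SpineProfile,
    detect_axilla,
    detect_c7t1,
    detect_landmarks,
    detect_shoulder,
    detect_waist,
    extract_spine_band,
    find_arm_boundaries,
    fit_sagittal_profile,
    locate_profile_landmarks,
    map_to_surface,
)
from backmark.io_formats import LANDMARK_NAMES
from backmark.preprocessing import _as_points, preprocess_frames
from backmark.synthetic import BackSurface, render_frames


def _mirror(cloud):
    pts = _as_points(cloud).copy()
    pts[:, 0] = -pts[:, 0]
    return pts


class TestFindArmBoundaries:
    def test_aux_points_track_true_trunk_width(self, subject_cloud,
                                               default_surface):
        ctx = find_arm_boundaries(subject_cloud)
        w_true = float(default_surface._width(ctx.diagnostics["centroid_y"]))
        assert ctx.aux_right[0] == pytest.approx(w_true, abs=0.015)
        assert ctx.aux_left[0] == pytest.approx(-w_true, abs=0.015)

    def test_mirrored_cloud_swaps_aux_points(self, subject_cloud):
        ctx = find_arm_boundaries(subject_cloud)
        ctx_m = find_arm_boundaries(_mirror(subject_cloud))
        assert ctx_m.aux_left[0] == pytest.approx(-ctx.aux_right[0], abs=1e-9)
        assert ctx_m.aux_right[0] == pytest.approx(-ctx.aux_left[0], abs=1e-9)

    def test_armless_torso_spans_whole_band(self, default_params):
        surface = BackSurface(default_params, include_arms=False)
        frames, _ = render_frames(surface, n=10, seed=11)
        cloud, _ = preprocess_frames(frames)
        pts = _as_points(cloud)
        ctx = find_arm_boundaries(cloud)
        band = pts[np.abs(pts[:, 1] - ctx.diagnostics["centroid_y"]) <= 0.02]
        assert ctx.torso_x_range[0] == pytest.approx(band[:, 0].min(), abs=1e-9)
        assert ctx.torso_x_range[1] == pytest.approx(band[:, 0].max(), abs=1e-9)

    def test_tiny_cloud_fails(self, rng):
        with pytest.raises(DetectionFailure):
            find_arm_boundaries(rng.uniform(0, 1, (50, 3)))


class TestAxillaAndShoulder:
    def test_axilla_found_below_shoulder_on_default_body(self, subject_cloud,
                                                         default_surface):
        ctx = find_arm_boundaries(subject_cloud)
        truth = default_surface.ground_truth()
        for side, name in (("left", "AL"), ("right", "AR")):
            ax = detect_axilla(subject_cloud, ctx, side)
            err = np.hypot(*((ax[:2] - truth.position(name)[:2])))
            assert err <= 0.025
            sh = detect_shoulder(subject_cloud, ax, side)
            assert sh[1] > ax[1]

    def test_mirror_symmetry_of_axillae(self, subject_cloud):
        ctx = find_arm_boundaries(subject_cloud)
        al = detect_axilla(subject_cloud, ctx, "left")
        mirrored = _mirror(subject_cloud)
        ctx_m = find_arm_boundaries(mirrored)
        ar_m = detect_axilla(mirrored, ctx_m, "right")
        assert np.allclose([-ar_m[0], ar_m[1]], al[:2], atol=0.005)

    def test_shoulder_is_brute_force_belt_argmax(self, rng):
        pts = rng.uniform(-0.2, 0.2, (500, 3))
        axilla = np.array([0.05, 0.0, 1.7])
        cfg = DetectionConfig()
        sh = detect_shoulder(pts, axilla, "right", cfg)
        belt = pts[np.abs(pts[:, 0] - 0.05) <= cfg.shoulder_belt_halfwidth]
        assert sh[1] == belt[:, 1].max()

    def test_single_point_belt_returned(self):
        pts = np.array([[0.05, 0.1, 1.7], [0.5, 0.9, 1.7]])
        sh = detect_shoulder(pts, np.array([0.05, 0.0, 1.7]), "left")
        assert np.array_equal(sh, pts[0])

    def test_empty_belt_fails(self):
        pts = np.array([[0.5, 0.1, 1.7]])
        with pytest.raises(DetectionFailure):
            detect_shoulder(pts, np.array([-0.5, 0, 1.7]), "left")


class TestC7T1:
    def test_exact_midpoint_member_returned(self):
        sl = np.array([-0.2, 1.5, 1.6])
        sr = np.array([0.2, 1.5, 1.6])
        cloud = np.array([[0.0, 1.5, 1.55], [0.1, 1.4, 1.5], [-0.3, 1.0, 1.7]])
        assert np.array_equal(detect_c7t1(cloud, sl, sr), cloud[0])

    def test_is_brute_force_xy_nearest(self, rng):
        pts = rng.uniform(-1, 1, (300, 3))
        sl, sr = pts[10], pts[20]
        res = detect_c7t1(pts, sl, sr)
        target = 0.5 * (sl[:2] + sr[:2])
        d = np.hypot(pts[:, 0] - target[0], pts[:, 1] - target[1])
        assert np.hypot(*(res[:2] - target)) == d.min()

    def test_recovered_on_default_body(self, detected_landmarks,
                                       default_surface):
        truth = default_surface.ground_truth().position("C7T1")
        det = detected_landmarks.position("C7T1")
        assert np.hypot(*(det[:2] - truth[:2])) <= 0.020


class TestSpineBandAndProfile:
    def test_band_is_comprehension(self, rng):
        pts = rng.uniform(-0.3, 0.3, (2000, 3))
        c7 = np.array([0.01, 0.25, 1.7])
        cfg = DetectionConfig()
        band = extract_spine_band(pts, c7, cfg)
        expected = np.array([p for p in pts
                             if abs(p[0] - 0.01) <= cfg.spine_band_halfwidth
                             and p[1] <= 0.25])
        assert np.array_equal(band.points, expected)

    def test_band_spans_most_of_trunk_height(self, subject_cloud,
                                             detected_landmarks,
                                             default_surface):
        band = extract_spine_band(subject_cloud,
                                  detected_landmarks.position("C7T1"))
        trunk_h = default_surface.y_top - default_surface.y_hip
        assert np.ptp(band.points[:, 1]) >= 0.6 * trunk_h

    def test_sparse_band_fails(self, rng):
        pts = rng.uniform(-1, 1, (10, 3))
        with pytest.raises(DetectionFailure, match="sparse"):
            extract_spine_band(pts, np.array([0.0, 2.0, 1.7]))

    def test_exact_quartic_recovered(self, rng):
        coeffs = np.array([1.7, -0.3, 0.8, 0.5, -1.2])
        y = rng.uniform(-0.5, 0.1, 200)
        z = np.polynomial.polynomial.polyval(y, coeffs)
        prof = fit_sagittal_profile(np.column_stack([np.zeros_like(y), y, z]),
                                    degree=4)
        assert np.allclose(prof.poly_coeffs, coeffs, rtol=1e-8, atol=1e-10)
        assert prof.fit_domain == (y.min(), y.max())

    def test_noise_floor_reflected_in_rss(self, rng):
        y = rng.uniform(-0.5, 0.1, 500)
        z = 1.7 + 0.1 * y ** 2 + rng.normal(0, 1e-3, y.size)
        prof = fit_sagittal_profile(np.column_stack([np.zeros_like(y), y, z]),
                                    degree=5)
        assert prof.rss / y.size == pytest.approx(1e-6, rel=1.0)

    def test_fit_invariant_to_point_order(self, rng):
        y = rng.uniform(-0.5, 0.1, 300)
        z = 1.7 - 0.2 * y + 0.5 * y ** 3 + rng.normal(0, 1e-4, y.size)
        pts = np.column_stack([np.zeros_like(y), y, z])
        p1 = fit_sagittal_profile(pts, 5)
        p2 = fit_sagittal_profile(pts[rng.permutation(len(pts))], 5)
        assert np.allclose(p1.poly_coeffs, p2.poly_coeffs, rtol=1e-9, atol=1e-12)

    def test_degenerate_band_rejected(self):
        pts = np.column_stack([np.zeros(50), np.full(50, 0.3),
                               np.linspace(1, 2, 50)])
        with pytest.raises(ValueError):
            fit_sagittal_profile(pts, 5)
        with pytest.raises(ValueError):
            fit_sagittal_profile(pts, degree=3)


def _profile_from_coeffs(coeffs, domain):
    poly = np.polynomial.Polynomial(coeffs)
    y = np.linspace(*domain, 50)
    fitted = np.polynomial.Polynomial.fit(y, poly(y), len(coeffs) - 1)
    return SpineProfile(poly=fitted, fit_domain=domain, rss=0.0)


def _scan_landmarks(coeffs, domain, n=100_001):
    """Dense-scan oracle for TK/LL/S1 on a polynomial profile."""
    y = np.linspace(*domain, n)
    z = np.polynomial.Polynomial(coeffs)(y)
    interior = slice(1, -1)
    left, mid, right = z[:-2], z[1:-1], z[2:]
    minima = y[interior][(mid < left) & (mid < right)]
    maxima = y[interior][(mid > left) & (mid > right)]
    y_tk = minima.max()
    y_ll = maxima[maxima < y_tk].max()
    d2 = np.diff(z, 2)
    flips = np.nonzero(np.sign(d2[:-1]) * np.sign(d2[1:]) < 0)[0]
    y_s1 = y[flips.min() + 1]
    return {"y_TK": y_tk, "y_LL": y_ll, "y_S1": y_s1}


class TestProfileLandmarks:
    def test_constructed_quartic_matches_dense_scan(self):
        """z(y) = (y-1.3)^2 (y-0.9)^2 - 0.01 (y-1.1) on [0.8, 1.4]."""
        base = np.polynomial.Polynomial.fromroots([1.3, 1.3, 0.9, 0.9])
        tilt = np.polynomial.Polynomial([0.011, -0.01])  # -0.01*(y-1.1)
        coeffs = (base + tilt).coef
        domain = (0.8, 1.4)
        found = locate_profile_landmarks(_profile_from_coeffs(coeffs, domain))
        oracle = _scan_landmarks(coeffs, domain)
        for key in ("y_TK", "y_LL", "y_S1"):
            assert found[key] == pytest.approx(oracle[key], abs=1e-5)

    def test_symmetric_double_well_closed_form(self):
        """z = (y-c)^4 - 2b(y-c)^2: extrema at c, c+-sqrt(b); inflections
        at c +- sqrt(b/3)."""
        c, b = 1.1, 0.04
        poly = (np.polynomial.Polynomial([-c, 1.0]) ** 4
                - 2 * b * np.polynomial.Polynomial([-c, 1.0]) ** 2)
        prof = _profile_from_coeffs(poly.coef, (c - 0.5, c + 0.5))
        found = locate_profile_landmarks(prof)
        assert found["y_TK"] == pytest.approx(c + np.sqrt(b), abs=1e-9)
        assert found["y_LL"] == pytest.approx(c, abs=1e-9)
        assert found["y_S1"] == pytest.approx(c - np.sqrt(b / 3), abs=1e-9)

    def test_monotone_profile_reports_missing_landmark(self):
        prof = _profile_from_coeffs([0.0, 1.0, 0.0, 0.0, 0.001], (0.0, 1.0))
        with pytest.raises(DetectionFailure):
            locate_profile_landmarks(prof)


class TestMapToSurface:
    def test_exact_target_member(self):
        pts = np.array([[0.0, 0.5, 1.7], [0.3, 0.52, 1.8], [-0.3, 0.48, 1.6]])
        res = map_to_surface(pts, 0.5, x_center=0.0)
        assert np.array_equal(res, pts[0])

    def test_is_brute_force_nearest_in_slab(self, rng):
        pts = rng.uniform(-0.3, 0.3, (1000, 3))
        cfg = DetectionConfig()
        y_t = 0.05
        res = map_to_surface(pts, y_t, None, cfg)
        slab = pts[np.abs(pts[:, 1] - y_t) <= cfg.surface_slab_halfwidth]
        xc = 0.5 * (slab[:, 0].min() + slab[:, 0].max())
        d = np.hypot(slab[:, 0] - xc, slab[:, 1] - y_t)
        assert np.hypot(res[0] - xc, res[1] - y_t) == d.min()
        assert abs(res[1] - y_t) <= cfg.surface_slab_halfwidth

    def test_empty_slab_fails(self, rng):
        with pytest.raises(DetectionFailure):
            map_to_surface(rng.uniform(0, 1, (10, 3)), 5.0)


def _ellipse_cloud(width_fn, y_range=(-0.45, -0.15), z0=1.8):
    """Dense torso-like slab whose silhouette follows ``width_fn(y)``."""
    pts = []
    for y in np.arange(*y_range, 0.004):
        w = width_fn(y)
        for x in np.arange(-w, w + 1e-9, 0.004):
            pts.append([x, y, z0])
    return np.array(pts)


class TestDetectWaist:
    def _context(self, half_width=0.15):
        p = np.array([half_width, -0.3, 1.8])
        return DetectionContext(aux_left=-p * [1, -1, -1], aux_right=p,
                                torso_x_range=(-half_width, half_width))

    def test_sinusoidal_indentation_recovered(self):
        y0 = -0.33
        width = lambda y: 0.14 - 0.02 * np.exp(-((y - y0) / 0.05) ** 2)
        cloud = _ellipse_cloud(width)
        wl, wr = detect_waist(cloud, self._context(), y_s1=-0.44,
                              y_axilla_min=-0.10)
        assert wl[1] == pytest.approx(y0, abs=0.02)
        assert wr[1] == pytest.approx(y0, abs=0.02)
        assert wl[0] == pytest.approx(-width(wl[1]), abs=0.006)
        assert wr[0] == pytest.approx(width(wr[1]), abs=0.006)

    def test_straight_cylinder_flagged_indistinct(self):
        cloud = _ellipse_cloud(lambda y: 0.14)
        with pytest.raises(DetectionFailure, match="waist"):
            detect_waist(cloud, self._context(), y_s1=-0.44, y_axilla_min=-0.10)

    def test_mirror_symmetry(self):
        y0 = -0.35
        width = lambda y: 0.14 - 0.018 * np.exp(-((y - y0) / 0.04) ** 2)
        cloud = _ellipse_cloud(width)
        wl, wr = detect_waist(cloud, self._context(), -0.44, -0.10)
        m = cloud.copy()
        m[:, 0] = -m[:, 0]
        wl_m, wr_m = detect_waist(m, self._context(), -0.44, -0.10)
        assert wl_m[0] == pytest.approx(-wr[0], abs=1e-9)
        assert wr_m[0] == pytest.approx(-wl[0], abs=1e-9)


class TestDetectLandmarks:
    def test_default_body_yields_all_ten(self, detected_landmarks):
        assert len(detected_landmarks.present()) == 10

    def test_every_landmark_is_a_cloud_point(self, subject_cloud,
                                             detected_landmarks):
        pts = {tuple(p) for p in _as_points(subject_cloud)}
        for name, pos in detected_landmarks.present().items():
            assert tuple(pos) in pts

    def test_height_ordering_invariants(self, detected_landmarks):
        y = {n: detected_landmarks.position(n)[1] for n in LANDMARK_NAMES}
        assert y["C7T1"] > y["TK"] > y["LL"] > y["S1"]
        assert y["SL"] > y["AL"] and y["SR"] > y["AR"]

    def test_random_points_give_total_failure_set(self, rng):
        ls = detect_landmarks(rng.uniform(0, 1, (10, 3)))
        assert len(ls.failures()) == 10

    def test_deterministic(self, subject_cloud):
        assert detect_landmarks(subject_cloud) == detect_landmarks(subject_cloud)

    def test_mirror_equivariance(self, subject_cloud, detected_landmarks):
        """Mirroring the cloud swaps the lateral landmarks (within 5 mm)."""
        mirrored = detect_landmarks(_mirror(subject_cloud))
        swap = {"AL": "AR", "AR": "AL", "SL": "SR", "SR": "SL",
                "WL": "WR", "WR": "WL"}
        for name in LANDMARK_NAMES:
            other = swap.get(name, name)
            a = detected_landmarks.position(name)
            b = mirrored.position(other)
            assert np.allclose([-b[0], b[1]], a[:2], atol=0.005), name


class TestLandmarkDetectorEstimator:
    def test_sklearn_param_interface(self):
        det = LandmarkDetector(polynomial_degree=6)
        assert det.get_params()["polynomial_degree"] == 6
        det.set_params(spine_band_halfwidth=0.03)
        assert det.spine_band_halfwidth == 0.03

    def test_predict_matches_function(self, subject_cloud, detected_landmarks):
        det = LandmarkDetector().fit()
        assert det.predict(subject_cloud) == detected_landmarks

    def test_predict_on_sequence(self, subject_cloud):
        det = LandmarkDetector().fit()
        out = det.predict([subject_cloud, subject_cloud])
        assert len(out) == 2 and out[0] == out[1]

    def test_invalid_degree_rejected(self):
        with pytest.raises(ValueError):
            LandmarkDetector(polynomial_degree=3).fit()
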