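"""Two-phase calibration: staged solvers, line matching, full pair recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenostereo import (
    CameraIntrinsics,
    CalibrationError,
    LinePair,
    MatchConfig,
    PairCalibration,
    ScanlineSpec,
    SceneSpec,
    fit_ground_plane,
    make_field_scene,
    phase1_rough_align,
    render_stereo_pair,
    solve_alpha,
    solve_beta,
    solve_gamma,
    solve_translation,
)
from phenostereo.calibration import (
    _robust_line_fit,
    apply_alignment,
    invert_alignment,
    match_scanlines,
    solve_alpha_rows,
)
from conftest import QUARTER_SCALE, SMALL_FOCAL, SMALL_SHAPE, textured_image


def line_pairs(slopes, intercepts, rows=None):
    sup = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    rows = rows if rows is not None else intercepts
    return [
        LinePair(left_row=r, right_slope=a, right_intercept=b, support=sup, residual_rms=0.0)
        for a, b, r in zip(slopes, intercepts, rows)
    ]


class TestSolveBeta:
    def test_equal_slopes_give_zero(self):
        assert solve_beta(line_pairs([0.01, 0.01], [100.0, 200.0]), 3000.0) == pytest.approx(0.0)

    def test_two_pair_substitution(self):
        pairs = line_pairs([0.010, 0.020], [200.0, 100.0])
        assert solve_beta(pairs, 3000.0) == pytest.approx(np.arctan(-0.3))

    def test_symmetric_under_pair_swap(self):
        a = solve_beta(line_pairs([0.010, 0.020], [200.0, 100.0]), 3000.0)
        b = solve_beta(line_pairs([0.020, 0.010], [100.0, 200.0]), 3000.0)
        assert a == pytest.approx(b)

    def test_forward_rotation_model_cross_check(self):
        """Line pairs generated by an exact y-rotation must reproduce it."""
        f, beta = 3000.0, np.deg2rad(0.8)
        rows = [-300.0, 0.0, 300.0]
        pairs = []
        for c in rows:
            x = np.linspace(-400, 400, 41)
            xm, ym = invert_alignment(x, np.full_like(x, c), f, beta, 0.0, 0.0)
            a, b = np.polyfit(xm, ym, 1)
            pairs.append(LinePair(c, a, b, np.zeros((2, 3)), 0.0))
        # the printed estimator measures the leftover motion; its magnitude
        # matches the commanded rotation
        assert abs(solve_beta(pairs, f)) == pytest.approx(beta, rel=0.01)

    def test_equal_intercepts_degenerate(self):
        with pytest.raises(CalibrationError):
            solve_beta(line_pairs([0.01, 0.02], [100.0, 100.0]), 3000.0)


class TestSolveGamma:
    def test_zero_slopes(self):
        assert solve_gamma(line_pairs([0.0, 0.0, 0.0], [0.0, 100.0, 200.0])) == 0.0

    def test_unit_slope_is_45_degrees(self):
        assert solve_gamma(line_pairs([1.0, 1.0], [0.0, 100.0])) == pytest.approx(np.pi / 4)

    def test_mean_slope(self):
        got = solve_gamma(line_pairs([0.01, 0.012, 0.011], [0.0, 100.0, 200.0]))
        assert got == pytest.approx(np.arctan(0.011))

    def test_empty_rejected(self):
        with pytest.raises(CalibrationError):
            solve_gamma([])


class TestSolveAlpha:
    def test_equal_spacing_gives_zero(self):
        assert solve_alpha(100.0, 200.0, 300.0, 3000.0) == pytest.approx(0.0)

    def test_substitution(self):
        assert solve_alpha(100.0, 210.0, 300.0, 3000.0) == pytest.approx(
            np.arctan(60000.0 / 114000.0)
        )

    def test_symmetric_under_outer_swap(self):
        a = solve_alpha(100.0, 210.0, 300.0, 3000.0)
        b = solve_alpha(300.0, 210.0, 100.0, 3000.0)
        assert a == pytest.approx(b)

    def test_zero_denominator_degenerate(self):
        # b_j (b_i + b_k) + b_i b_k = 0 for (100, -50, 100)
        with pytest.raises(CalibrationError):
            solve_alpha(100.0, -50.0, 100.0, 3000.0)

    def test_rows_regression_recovers_forward_rotation(self):
        """Intercept spacing of exactly rotated scanlines yields the angle."""
        f, alpha = 3000.0, np.deg2rad(0.6)
        rows = np.linspace(-400, 400, 9)
        pairs = []
        for c in rows:
            x = np.linspace(-300, 300, 21)
            _, ym = invert_alignment(x, np.full_like(x, c), f, 0.0, 0.0, alpha)
            a, b = np.polyfit(x, ym, 1)
            pairs.append(LinePair(c, a, b, np.zeros((2, 3)), 0.0))
        assert abs(solve_alpha_rows(pairs, f)) == pytest.approx(alpha, rel=0.05)


class TestSolveTranslation:
    def test_identity(self):
        c = [-100.0, 0.0, 100.0]
        assert solve_translation(line_pairs([0] * 3, c, rows=c)) == pytest.approx((0.0, 1.0))

    def test_pure_shift(self):
        c = [-100.0, 0.0, 100.0]
        b = [x + 10 for x in c]
        dy, s = solve_translation(line_pairs([0] * 3, b, rows=c))
        assert dy == pytest.approx(10.0)
        assert s == pytest.approx(1.0)

    def test_pure_scale(self):
        c = [-100.0, 0.0, 100.0]
        b = [1.05 * x for x in c]
        dy, s = solve_translation(line_pairs([0] * 3, b, rows=c))
        assert dy == pytest.approx(0.0)
        assert s == pytest.approx(1 / 1.05)

    def test_zero_row_spread_rejected(self):
        with pytest.raises(CalibrationError):
            solve_translation(line_pairs([0] * 3, [5.0, 5.0, 5.0], rows=[0.0, 0.0, 0.0]))


class TestFitGroundPlane:
    def test_exact_plane_recovered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(-1, 1, (50, 2))
        z = 0.01 * xy[:, 0] + 0.02 * xy[:, 1] + 4.0
        plane = fit_ground_plane(np.column_stack([xy, z]))
        assert plane.a == pytest.approx(0.01, abs=1e-12)
        assert plane.b == pytest.approx(0.02, abs=1e-12)
        assert plane.c == pytest.approx(4.0, abs=1e-12)
        assert plane.fit_rms == pytest.approx(0.0, abs=1e-12)

    def test_horizontal_plane(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(-1, 1, (30, 2))
        plane = fit_ground_plane(np.column_stack([xy, np.full(30, 4.1)]))
        assert plane.a == pytest.approx(0.0, abs=1e-12)
        assert plane.b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_plane_within_three_standard_errors(self):
        rng = np.random.default_rng(2)
        n, sigma = 200, 0.005
        xy = rng.uniform(-1, 1, (n, 2))
        z = 0.01 * xy[:, 0] + 0.02 * xy[:, 1] + 4.0 + rng.normal(0, sigma, n)
        plane = fit_ground_plane(np.column_stack([xy, z]))
        # analytic least-squares covariance as the oracle
        a_mat = np.column_stack([xy, np.ones(n)])
        cov = sigma**2 * np.linalg.inv(a_mat.T @ a_mat)
        se = np.sqrt(np.diag(cov))
        for got, true, s in zip((plane.a, plane.b, plane.c), (0.01, 0.02, 4.0), se):
            assert abs(got - true) < 3 * s

    def test_collinear_support_rejected(self):
        pts = np.array([[0, 0, 1.0], [1, 0, 1.1], [2, 0, 1.2], [3, 0, 1.3]])
        with pytest.raises(CalibrationError):
            fit_ground_plane(pts)


class TestAlignmentTransforms:
    @given(
        beta=st.floats(-0.02, 0.02),
        gamma=st.floats(-0.02, 0.02),
        alpha=st.floats(-0.02, 0.02),
        dy=st.floats(-10, 10),
        scale=st.floats(0.95, 1.05),
        x=st.floats(-600, 600),
        y=st.floats(-400, 400),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_apply_invert_roundtrip(self, beta, gamma, alpha, dy, scale, x, y):
        f = 3000.0
        xr, yr = apply_alignment(np.array([x]), np.array([y]), f, beta, gamma, alpha, dy, scale)
        xb, yb = invert_alignment(xr, yr, f, beta, gamma, alpha, dy, scale)
        assert xb[0] == pytest.approx(x, abs=1e-8)
        assert yb[0] == pytest.approx(y, abs=1e-8)


class TestRobustLineFit:
    def test_outliers_do_not_move_the_line(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 100, 80)
        y = 0.01 * x + 5.0 + rng.normal(0, 0.05, 80)
        y_dirty = y.copy()
        idx = rng.choice(80, 8, replace=False)
        y_dirty[idx] += rng.uniform(-30, 30, 8)
        a_clean, b_clean, _ = _robust_line_fit(x, y)
        a_dirty, b_dirty, keep = _robust_line_fit(x, y_dirty)
        assert abs(a_dirty - a_clean) * 100 + abs(b_dirty - b_clean) < 0.5
        assert not keep[idx].all()


class TestPhase1RoughAlign:
    def _base(self):
        return textured_image(21, (300, 400), contrast=45)

    def test_identity_pair(self):
        img = self._base()
        rot, scale = phase1_rough_align(img, np.roll(img, -60, axis=1), gnss_hint=0.8)
        assert abs(rot) < np.deg2rad(0.05)
        assert scale == pytest.approx(1.0, abs=0.002)

    def test_small_rotation_recovered(self):
        from skimage.transform import rotate

        img = self._base()
        right = rotate(np.roll(img, -60, axis=1), 0.5, mode="reflect", order=3)
        rot, _ = phase1_rough_align(img, right, gnss_hint=0.8)
        # rotate() turns counter-clockwise; the correction has opposite sign
        assert abs(abs(rot) - np.deg2rad(0.5)) < np.deg2rad(0.05)

    def test_small_scaling_recovered(self):
        from skimage.transform import rescale, resize

        img = self._base()
        scaled = rescale(np.roll(img, -60, axis=1), 1.02, order=3)
        h, w = img.shape
        off_y = (scaled.shape[0] - h) // 2
        off_x = (scaled.shape[1] - w) // 2
        right = scaled[off_y : off_y + h, off_x : off_x + w]
        _, scale = phase1_rough_align(img, right, gnss_hint=0.8)
        assert scale == pytest.approx(1 / 1.02, rel=0.002)

    def test_textureless_pair_fails(self):
        flat = np.full((200, 300), 100.0)
        with pytest.raises(CalibrationError, match="corner"):
            phase1_rough_align(flat, flat, gnss_hint=0.8)


class TestMatchScanlines:
    def test_identity_pair_lines_on_rows(self, small_flat_pair):
        rp = small_flat_pair
        h, w = rp.left.shape
        cfg = MatchConfig(window_radius=5, search_center=int(round(rp.ground_disparity)),
                          search_span=32)
        spec = ScanlineSpec.evenly_spaced(h, n_rows=5, margin=20)
        pairs = match_scanlines(rp.left, rp.right, spec, cfg)
        assert len(pairs) >= 3
        cy = (h - 1) / 2
        for p in pairs:
            assert abs(p.right_slope) < 2e-3
            assert p.right_intercept == pytest.approx(p.left_row, abs=0.2)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ScanlineSpec(rows=(10, 20))
        with pytest.raises(ValueError):
            ScanlineSpec(rows=(30, 20, 40))
        with pytest.raises(ValueError):
            ScanlineSpec(rows=(10, 20, 30), band_halfwidth=0)


class TestCalibratePair:
    def test_zero_perturbation_returns_identity(self, small_flat_pair):
        rp = small_flat_pair
        model = PairCalibration(
            rp.left, rp.right, CameraIntrinsics(SMALL_FOCAL), rp.baseline,
            altitude_hint_m=rp.altitude,
            spec=ScanlineSpec.evenly_spaced(rp.left.shape[0], n_rows=7, margin=20),
        )
        res = model.fit()
        for angle in (res.beta, res.gamma, res.alpha):
            assert abs(np.rad2deg(angle)) < 0.1
        assert abs(res.delta_y) < 1.0
        assert res.delta_z_scale == pytest.approx(1.0, abs=0.005)

    def test_perturbed_quarter_scale_pair_recovered(self):
        scene = make_field_scene(SceneSpec(extent=(8.0, 4.0), texture_seed=31))
        pert = dict(
            beta=np.deg2rad(1.0), gamma=np.deg2rad(0.5), alpha=np.deg2rad(0.8),
            delta_y=6.0, tilt_beta=np.deg2rad(0.7), tilt_alpha=np.deg2rad(0.4),
        )
        rp = render_stereo_pair(scene, perturbations=pert, noise_seed=31, **QUARTER_SCALE)
        model = PairCalibration(
            rp.left, rp.right, CameraIntrinsics(rp.focal), rp.baseline,
            altitude_hint_m=rp.altitude,
            spec=ScanlineSpec.evenly_spaced(rp.left.shape[0], n_rows=13),
        )
        res = model.fit()
        assert np.rad2deg(abs(res.beta - pert["beta"])) < 0.1
        assert np.rad2deg(abs(res.gamma - pert["gamma"])) < 0.1
        assert np.rad2deg(abs(res.alpha - pert["alpha"])) < 0.1
        assert abs(res.delta_y - pert["delta_y"]) < 1.0
        assert np.rad2deg(abs(res.left_tilt_betab - pert["tilt_beta"])) < 0.1
        assert np.rad2deg(abs(res.left_tilt_alphab - pert["tilt_alpha"])) < 0.1
        # SSE should improve from start to convergence on a planar scene
        assert res.sse_trace[-1] <= res.sse_trace[0]
        # idempotence: calibrating the rectified pair returns near-identity
        rect = model.rectify_right(res)
        model2 = PairCalibration(
            rp.left, rect, CameraIntrinsics(rp.focal), rp.baseline,
            altitude_hint_m=rp.altitude,
            spec=ScanlineSpec.evenly_spaced(rp.left.shape[0], n_rows=13),
        )
        res2 = model2.fit()
        for angle in (res2.beta, res2.gamma, res2.alpha):
            assert abs(np.rad2deg(angle)) < 0.02
        assert res2.delta_z_scale == pytest.approx(1.0, abs=1e-3)
        # post-rectification disparity rows of the planar scene are flat
        from phenostereo import compute_disparity_map

        cfg = MatchConfig(search_center=int(round(rp.ground_disparity)), search_span=64)
        dm = compute_disparity_map(rp.left, rect, cfg)
        mid = dm.disparity[dm.valid.shape[0] // 2]
        row_valid = dm.valid[dm.valid.shape[0] // 2]
        assert np.ptp(mid[row_valid]) <= 2

    def test_summary_and_json_report(self, small_flat_pair):
        rp = small_flat_pair
        model = PairCalibration(
            rp.left, rp.right, CameraIntrinsics(SMALL_FOCAL), rp.baseline,
            altitude_hint_m=rp.altitude,
            spec=ScanlineSpec.evenly_spaced(rp.left.shape[0], n_rows=7, margin=20),
        )
        res = model.fit()
        text = res.summary()
        assert "rotation beta" in text and "delta-y" in text
        blob = res.to_json()
        assert set(blob) >= {"beta_deg", "gamma_deg", "alpha_deg", "delta_y_px",
                             "scale", "iterations", "sse_trace", "rows_used"}

    def test_overlap_violation_refused(self, small_flat_pair):
        rp = small_flat_pair
        with pytest.raises(CalibrationError, match="overlap|half"):
            PairCalibration(
                rp.left, rp.right, CameraIntrinsics(SMALL_FOCAL), rp.baseline,
                cfg=MatchConfig(search_center=SMALL_SHAPE[1]),
            )
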