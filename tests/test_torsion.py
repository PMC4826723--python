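"""Tests for cylindrical decomposition, rotation traces and torsion curves."""

import numpy as np
import pytest

import tpmtorsion as tt
from tpmtorsion.torsion import RotationTrace


def make_trace(theta, dt_ms=20.0, layer="full", label="base"):
    theta = np.asarray(theta, dtype=float)
    return RotationTrace(
        omega_deg_s=np.gradient(theta, dt_ms / 1000.0),
        theta_deg=theta, radius_mm=np.full(len(theta), 20.0),
        layer=layer, slice_label=label, dt_ms=dt_ms,
    )


class TestCylindrical:
    def test_clockwise_tangential_convention(self):
        v_x = np.zeros((21, 21))
        v_y = np.zeros((21, 21))
        v_y[10, 20] = 5.0  # at (row=0, col=+10) from center: downward motion
        cyl = tt.to_cylindrical(v_x, v_y, np.zeros_like(v_x), (10, 10))
        assert cyl.v_phi[10, 20] == pytest.approx(5.0)
        assert cyl.v_r[10, 20] == pytest.approx(0.0)

    def test_inward_radial_positive(self):
        v_x = np.zeros((21, 21))
        v_x[10, 20] = -5.0  # pointing back toward the center
        cyl = tt.to_cylindrical(v_x, np.zeros_like(v_x), np.zeros_like(v_x), (10, 10))
        assert cyl.v_r[10, 20] == pytest.approx(5.0)
        assert cyl.v_phi[10, 20] == pytest.approx(0.0)

    def test_norm_preserved_everywhere(self):
        rng = np.random.default_rng(0)
        v_x, v_y = rng.normal(size=(2, 31, 31))
        cyl = tt.to_cylindrical(v_x, v_y, np.zeros_like(v_x), (15.3, 14.7), (2.0, 2.2))
        lhs = cyl.v_r**2 + cyl.v_phi**2
        np.testing.assert_allclose(lhs, v_x**2 + v_y**2, atol=1e-9)

    def test_center_pixel_zeroed(self):
        v_x = np.ones((5, 5))
        cyl = tt.to_cylindrical(v_x, v_x, v_x, (2, 2))
        assert cyl.v_r[2, 2] == 0.0 and cyl.v_phi[2, 2] == 0.0


class TestMeanRadius:
    def test_annulus_matches_area_weighted_integral(self):
        rr, cc = np.mgrid[0:256, 0:256]
        r = np.hypot(rr - 128, cc - 128)  # 1 mm pixels
        mask = (r >= 15) & (r <= 25)
        expected = (2 / 3) * (25**3 - 15**3) / (25**2 - 15**2)  # 20.4167
        assert tt.mean_radius(mask, (128, 128)) == pytest.approx(expected, rel=0.01)

    def test_single_pixel(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 17] = True
        assert tt.mean_radius(mask, (5, 5), (1.0, 1.0)) == pytest.approx(12.0)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            tt.mean_radius(np.zeros((5, 5), bool), (2, 2))


class TestAngularVelocity:
    def test_unit_conversion(self):
        v_phi = np.full((10, 10), 20.0)
        cyl = tt.CylindricalFrame(v_r=v_phi * 0, v_phi=v_phi, v_z=v_phi * 0, center=(5, 5))
        out = tt.angular_velocity(cyl, np.ones((10, 10), bool), 25.0)
        assert out == pytest.approx(np.degrees(0.8))  # 45.8366 deg/s

    def test_zero_field(self):
        z = np.zeros((6, 6))
        cyl = tt.CylindricalFrame(v_r=z, v_phi=z, v_z=z, center=(3, 3))
        assert tt.angular_velocity(cyl, np.ones((6, 6), bool), 10.0) == 0.0

    def test_rigid_rotation_recovered_within_one_percent(self):
        omega_true = 12.0  # deg/s
        rr, cc = np.mgrid[0:128, 0:128]
        d_row, d_col = (rr - 64) * 2.0, (cc - 64) * 2.0
        w = np.deg2rad(omega_true)
        v_x, v_y = -w * d_row, w * d_col
        mask = (np.hypot(d_row, d_col) >= 30) & (np.hypot(d_row, d_col) <= 50)
        cyl = tt.to_cylindrical(v_x, v_y, v_x * 0, (64, 64), (2.0, 2.0))
        R = tt.mean_radius(mask, (64, 64), (2.0, 2.0))
        assert tt.angular_velocity(cyl, mask, R) == pytest.approx(omega_true, rel=0.01)


class TestRotationAngle:
    def test_constant_omega(self):
        theta = tt.rotation_angle(np.full(16, 10.0), 20.0)
        assert theta[0] == 0.0
        assert theta[15] == pytest.approx(3.0)  # 10 deg/s * 0.3 s

    def test_alternating_omega_cancels(self):
        omega = np.tile([5.0, -5.0], 8)
        theta = tt.rotation_angle(omega, 10.0)
        np.testing.assert_allclose(theta[::2][1:], theta[2], atol=1e-12)

    def test_sinusoid_matches_closed_form(self):
        T_sys = 0.3
        t = np.arange(0, T_sys + 1e-9, 0.005)
        A = 30.0
        omega = A * np.sin(np.pi * t / T_sys)
        theta = tt.rotation_angle(omega, 5.0)
        expected = A * T_sys / np.pi * (1 - np.cos(np.pi * t / T_sys))
        np.testing.assert_allclose(theta[1:], expected[1:], rtol=1e-3)


class TestTranslationCorrection:
    def test_constant_offset_removed_exactly(self, clean_phantom):
        spec, slices, _ = clean_phantom
        s = slices.series["mid"]
        mask = np.ones((s.n_frames,) + s.shape, bool)
        shifted = s.copy_with_velocity(s.velocity.copy())
        shifted.velocity[0] += 3.0
        shifted.velocity[1] += 4.0
        a = tt.correct_translation(shifted, mask).velocity
        b = tt.correct_translation(s, mask).velocity
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_mask_mean_zero_after_correction(self, clean_phantom):
        _, slices, _ = clean_phantom
        s = slices.series["base"]
        mask = np.ones((s.n_frames,) + s.shape, bool)
        out = tt.correct_translation(s, mask)
        for t in range(s.n_frames):
            assert abs(out.velocity[0, t].mean()) < 1e-9
            assert abs(out.velocity[1, t].mean()) < 1e-9

    def test_pure_rotation_unchanged(self):
        rr, cc = np.mgrid[0:96, 0:96]
        d_row, d_col = (rr - 47.5), (cc - 47.5)
        v_x = np.broadcast_to(-0.1 * d_row, (2, 96, 96)).copy()
        v_y = np.broadcast_to(0.1 * d_col, (2, 96, 96)).copy()
        s = tt.TPMSeries("mid", np.ones((2, 96, 96)),
                         np.stack([v_x, v_y, np.zeros_like(v_x)]),
                         (2, 2), 20, 0, 1e6)
        r = np.hypot(d_row, d_col)
        mask = np.broadcast_to((r >= 10) & (r <= 20), (2, 96, 96)).copy()
        out = tt.correct_translation(s, mask)
        np.testing.assert_allclose(out.velocity, s.velocity, atol=1e-6)

    def test_empty_mask_names_frame(self, clean_phantom):
        _, slices, _ = clean_phantom
        s = slices.series["mid"]
        mask = np.ones((s.n_frames,) + s.shape, bool)
        mask[3] = False
        with pytest.raises(ValueError, match="frame 3"):
            tt.correct_translation(s, mask)


class TestTorsionCurve:
    def test_hand_arithmetic(self):
        upper = make_trace(np.linspace(0, 3.0, 16))
        lower = make_trace(np.zeros(16), label="apex")
        curve = tt.torsion_curve(upper, lower, 50.0)
        assert curve.values[-1] == pytest.approx(0.06)

    def test_identical_traces_give_zero(self):
        tr = make_trace(np.sin(np.linspace(0, 3, 20)))
        lower = make_trace(np.sin(np.linspace(0, 3, 20)), label="apex")
        curve = tt.torsion_curve(tr, lower, 40.0)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_constant_rate_twist(self):
        # base 10 deg/s, apex 0, h = 40 mm: T(0.25 s) = 0.0625 deg/mm
        dt = 10.0
        n = 26
        upper = make_trace(10.0 * np.arange(n) * dt / 1000.0, dt_ms=dt)
        lower = make_trace(np.zeros(n), dt_ms=dt, label="apex")
        curve = tt.torsion_curve(upper, lower, 40.0)
        k = int(250 / dt)
        assert curve.values[k] == pytest.approx(0.0625, rel=0.02)
        assert curve.t_ms[k] == pytest.approx(250.0)

    def test_mismatched_dt_rejected(self):
        upper = make_trace(np.zeros(10), dt_ms=20.0)
        lower = make_trace(np.zeros(10), dt_ms=30.0, label="apex")
        with pytest.raises(ValueError, match="10%"):
            tt.torsion_curve(upper, lower, 40.0)


class TestTransmuralSummary:
    @pytest.mark.parametrize(
        "endo_max, epi_max, expected_d",
        [(0.46, 0.30, 0.16), (0.56, 0.34, 0.22), (0.3, 0.3, 0.0)],
    )
    def test_peak_difference(self, endo_max, epi_max, expected_d):
        t = np.arange(0, 400, 20.0)
        mk = lambda peak, layer: tt.TorsionCurve(
            t_ms=t, values=peak * np.sin(np.pi * t / 400), slice_pair=("base", "apex"),
            layer=layer, h_mm=50.0,
        )
        out = tt.transmural_summary(mk(endo_max, "endo"), mk(epi_max, "epi"))
        assert out.dT_max == pytest.approx(expected_d, abs=1e-12)
        if endo_max:
            assert out.dPctT_max == pytest.approx(expected_d / endo_max * 100)

    def test_zero_endo_peak_yields_nan_percent(self):
        t = np.arange(0, 100, 10.0)
        endo = tt.TorsionCurve(t, np.zeros_like(t), ("base", "apex"), "endo", 50.0)
        epi = tt.TorsionCurve(t, np.zeros_like(t), ("base", "apex"), "epi", 50.0)
        with pytest.warns(UserWarning, match="undefined"):
            out = tt.transmural_summary(endo, epi)
        assert np.isnan(out.dPctT_max)

    def test_different_slice_pairs_rejected(self):
        t = np.arange(0, 100, 10.0)
        a = tt.TorsionCurve(t, np.zeros_like(t), ("base", "apex"), "endo", 50.0)
        b = tt.TorsionCurve(t, np.zeros_like(t), ("base", "mid"), "epi", 30.0)
        with pytest.raises(ValueError, match="slice pairs"):
            tt.transmural_summary(a, b)


class TestResampleAndAverage:
    def curve(self, dur_ms, f, dt=20.0):
        t = np.arange(0, dur_ms + 1e-9, dt)
        return tt.TorsionCurve(t, f(t), ("base", "apex"), "full", 50.0)

    def test_identical_curves_average_to_themselves(self):
        c = self.curve(800, lambda t: np.sin(t / 100))
        t, mean, sd = tt.resample_and_average([c, c], dt_out_ms=5.0)
        np.testing.assert_allclose(mean, np.interp(t, c.t_ms, c.values), atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_linear_curve_resampled_exactly(self):
        c = self.curve(800, lambda t: 0.001 * t)
        t, mean, _ = tt.resample_and_average([c], dt_out_ms=5.0)
        np.testing.assert_allclose(mean, 0.001 * t, atol=1e-12)
        assert t[1] - t[0] == 5.0 and t[0] == 0.0

    def test_half_coverage_truncation(self):
        short = self.curve(800, lambda t: t * 0)
        long = self.curve(1000, lambda t: t * 0)
        t, _, _ = tt.resample_and_average([short, long], dt_out_ms=5.0)
        assert t[-1] == pytest.approx(800.0)
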