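"""Resampling, spectral filtering and curvature of closed contours."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dropstress import phantoms as ph
from dropstress.contour_geometry import (
    Contour,
    GeometryError,
    curvature_profile,
    fft_lowpass,
    mean_curvature_sum,
    resample_closed,
)

from conftest import turning_number


def circle(R=6.5, n=512, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.column_stack([center[0] + R * np.cos(t), center[1] + R * np.sin(t)]))


class TestResampleClosed:
    def test_square_corners_retained(self):
        sq = Contour(np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float))
        out = resample_closed(sq, 128)
        assert out.n_points == 128
        spacing = sq.perimeter() / 128
        for corner in sq.points:
            d = np.min(np.hypot(*(out.points - corner).T))
            assert d <= spacing / 2
        # 32 points per side
        on_bottom = np.isclose(out.points[:, 1], 0.0) & (out.points[:, 0] < 4)
        assert on_bottom.sum() == 32

    def test_uniform_circle_is_fixed_point(self):
        c = circle(n=512)
        out = resample_closed(c, 512)
        assert np.allclose(out.points, c.points, atol=1e-9)

    def test_star_polygon_perimeter_preserved(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        amps = rng.uniform(-0.05, 0.05, 8)
        r = 6.5 * (1 + 0.3 * np.sin(5 * t))
        for k, a in enumerate(amps, start=1):
            r = r + 6.5 * a * np.cos(k * t + rng.uniform(0, 2 * np.pi))
        star = Contour(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        out = resample_closed(star, 1024)
        assert abs(out.perimeter() / star.perimeter() - 1) < 1e-3

    def test_rejects_bad_n_and_degenerate_contour(self):
        c = circle()
        with pytest.raises(ValueError):
            resample_closed(c, 200)  # not a power of two
        with pytest.raises(ValueError):
            resample_closed(c, 64)  # too small
        degenerate = Contour(np.zeros((8, 2)) + 1.0)
        with pytest.raises(GeometryError):
            resample_closed(degenerate, 128)


class TestFFTLowpass:
    def test_circle_is_fixed_point(self):
        c = circle()
        out = fft_lowpass(c, 5)
        assert np.allclose(out.points, c.points, atol=1e-9)

    def test_high_harmonic_ripple_removed(self):
        n = 512
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = 6.5 + 0.2 * np.cos(40 * t)
        rippled = Contour(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        out = fft_lowpass(rippled, 20)
        assert np.max(np.abs(np.hypot(*out.points.T) - 6.5)) < 1e-6

    def test_all_pass_cutoff_is_identity(self):
        c = circle(n=512)
        out = fft_lowpass(c, 255)
        assert np.allclose(out.points, c.points, atol=1e-9)

    def test_idempotent_and_mean_preserving(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        r = 6.5 * (1 + 0.1 * np.cos(3 * t) + 0.02 * rng.standard_normal(512))
        c = Contour(np.column_stack([3 + r * np.cos(t), -2 + r * np.sin(t)]))
        once = fft_lowpass(c, 16)
        twice = fft_lowpass(once, 16)
        assert np.allclose(once.points, twice.points, atol=1e-12)
        assert np.allclose(once.points.mean(axis=0), c.points.mean(axis=0), atol=1e-12)

    def test_cutoff_out_of_range_rejected(self):
        c = circle(n=512)
        with pytest.raises(ValueError):
            fft_lowpass(c, 0)
        with pytest.raises(ValueError):
            fft_lowpass(c, 256)


class TestCurvatureProfile:
    def test_circle_curvature(self):
        prof = curvature_profile(circle(R=6.5))
        assert np.max(np.abs(prof.kappa * 6.5 - 1)) < 1e-6
        # positive for convex CCW, theta spans the circle
        assert np.all(prof.kappa > 0)
        assert prof.theta.min() < -3 and prof.theta.max() > 3

    def test_ellipse_vertex_curvature(self):
        a, b = 7.0, 6.5
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        ell = Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]))
        prof = curvature_profile(ell)
        # point 0 sits on the major-axis vertex where kappa = a / b^2
        assert prof.kappa[0] == pytest.approx(a / b**2, rel=1e-4)
        assert prof.kappa.max() == pytest.approx(a / b**2, rel=1e-4)
        assert prof.kappa.min() == pytest.approx(b / a**2, rel=1e-4)

    def test_pear_matches_analytic_polar_curvature(self):
        p = ph.ParametricContour(R0=6.5, a1=0.15, a2=0.10)
        c = ph.make_parametric_contour(p)
        prof = curvature_profile(c)
        kappa_true = ph.parametric_curvature(p)
        assert np.max(np.abs(prof.kappa / kappa_true - 1)) < 1e-3

    def test_rigid_motion_invariance(self):
        p = ph.ParametricContour(R0=6.5, a1=0.12, a2=0.07)
        c = ph.make_parametric_contour(p)
        moved = c.rotated(0.8).translated(12.3, -4.5)
        k0 = curvature_profile(c).kappa
        k1 = curvature_profile(moved).kappa
        assert np.max(np.abs(k1 / k0 - 1)) < 1e-9

    def test_dilation_scales_curvature_inversely(self):
        p = ph.ParametricContour(R0=6.5, a1=0.1, a2=0.05)
        c = ph.make_parametric_contour(p)
        lam = 2.7
        k0 = curvature_profile(c).kappa
        k1 = curvature_profile(c.scaled(lam)).kappa
        assert np.allclose(k1 * lam, k0, rtol=1e-9)

    def test_orientation_normalized_to_ccw(self):
        c = circle()
        cw = Contour(c.points[::-1].copy())
        prof = curvature_profile(cw)
        assert np.all(prof.kappa > 0)

    def test_degenerate_speed_rejected(self):
        pts = np.ones((128, 2)) + 1e-12 * np.random.default_rng(0).standard_normal((128, 2))
        with pytest.raises(GeometryError):
            curvature_profile(Contour(pts))

    @given(a1=st.floats(-0.2, 0.2), a2=st.floats(-0.15, 0.15))
    def test_turning_number_is_one(self, a1, a2):
        c = ph.make_parametric_contour(ph.ParametricContour(R0=6.5, a1=a1, a2=a2))
        prof = curvature_profile(c)
        # integral of kappa ds via the parameter form
        n = c.n_points
        d = np.roll(c.points, -1, axis=0) - np.roll(c.points, 1, axis=0)
        speed = np.hypot(d[:, 0], d[:, 1]) / 2.0
        total = np.sum(prof.kappa * speed)
        assert abs(total / (2 * np.pi) - 1) < 1e-3
        assert abs(turning_number(c.points) - 1) < 1e-9


class TestMeanCurvatureSum:
    @pytest.mark.parametrize(
        "k_in, k_out, expected",
        [
            (1 / 6.5, 1 / 6.5, 2 / 6.5),  # sphere
            (0.2, 0.0, 0.2),  # cylinder: no out-of-plane term
            (0.15, 2 / 8.0, 0.40),  # pancake mid-plane, 8 um channel height
        ],
    )
    def test_principal_curvatures_add(self, k_in, k_out, expected):
        assert mean_curvature_sum(k_in, k_out) == pytest.approx(expected)
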