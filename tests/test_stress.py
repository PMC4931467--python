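"""Curvature-change inversion into normal stress, pairing and pooling."""

import numpy as np
import pytest

from dropstress import phantoms as ph
from dropstress.contour_geometry import CurvatureProfile, curvature_profile
from dropstress.stress import (
    DropletState,
    PairingError,
    cohort_stress,
    contact_stress,
    locate_contact,
    match_states,
)
from dropstress.tension import EstimationError

FULL_WINDOW = (-np.pi, np.pi)


def profile_from_param(p: ph.ParametricContour, frame=0) -> CurvatureProfile:
    prof = curvature_profile(ph.make_parametric_contour(p))
    prof.frame_index = frame
    return prof


def state(p: ph.ParametricContour, label, frame=0) -> DropletState:
    c = ph.make_parametric_contour(p)
    prof = curvature_profile(c)
    return DropletState(contour=c, profile=prof, label=label, frame_index=frame)


class TestMatchStates:
    def test_single_pair(self):
        rest = state(ph.ParametricContour(R0=6.5), "resting", 0)
        deform = state(ph.ParametricContour(R0=6.5, a2=0.1, center=(1.0, 0)), "deformed", 1)
        pairs = match_states([rest, deform])
        assert pairs == [(rest, deform)]

    def test_two_droplets_no_cross_pairing(self):
        r1 = state(ph.ParametricContour(R0=6.5), "resting", 0)
        d1 = state(ph.ParametricContour(R0=6.5, a2=0.1), "deformed", 1)
        r2 = state(ph.ParametricContour(R0=6.0, center=(100, 0)), "resting", 0)
        d2 = state(ph.ParametricContour(R0=6.0, a2=0.1, center=(100, 0)), "deformed", 1)
        pairs = match_states([r1, r2, d1, d2])
        assert len(pairs) == 2
        matched = {id(d): id(r) for r, d in pairs}
        assert matched[id(d1)] == id(r1)
        assert matched[id(d2)] == id(r2)

    def test_temporally_closest_resting_frame_wins(self):
        r_far = state(ph.ParametricContour(R0=6.5), "resting", 0)
        r_near = state(ph.ParametricContour(R0=6.5), "resting", 9)
        d = state(ph.ParametricContour(R0=6.5, a2=0.1), "deformed", 10)
        pairs = match_states([r_far, r_near, d])
        assert pairs[0][0] is r_near

    def test_unpaired_deformed_state_raises(self):
        rest = state(ph.ParametricContour(R0=6.5), "resting", 0)
        lonely = state(ph.ParametricContour(R0=6.5, center=(100, 0)), "deformed", 1)
        with pytest.raises(PairingError):
            match_states([rest, lonely])

    def test_missing_label_raises(self):
        rest = state(ph.ParametricContour(R0=6.5), "resting", 0)
        with pytest.raises(PairingError):
            match_states([rest])


class TestLocateContact:
    def test_pear_minimum_at_half_pi(self):
        # a2-only pear: curvature minima exactly at +/- pi/2; the upper-half
        # window selects +pi/2
        p = ph.ParametricContour(R0=6.5, a2=0.10)
        prof = profile_from_param(p)
        contact = locate_contact(prof, window=(0.0, np.pi))
        spacing = 2 * np.pi / p.n_points
        assert abs(contact.theta_star - np.pi / 2) <= spacing
        assert contact.distinct

    def test_constant_curvature_ties_to_smallest_angle(self):
        prof = profile_from_param(ph.ParametricContour(R0=6.5))
        contact = locate_contact(prof, window=FULL_WINDOW, flat_tol=1e-6)
        assert not contact.distinct
        assert abs(contact.theta_star) <= 2 * np.pi / 512

    def test_window_excluding_minimum_returns_windowed_minimum(self):
        p = ph.ParametricContour(R0=6.5, a2=0.10)
        prof = profile_from_param(p)
        window = (-0.5, 0.5)  # away from the flattened flanks at +/- pi/2
        contact = locate_contact(prof, window=window)
        assert -0.5 <= contact.theta_star <= 0.5
        global_min = prof.kappa.min()
        assert contact.kappa_min > global_min

    def test_tiny_window_rejected(self):
        prof = profile_from_param(ph.ParametricContour(R0=6.5))
        with pytest.raises(ValueError):
            locate_contact(prof, window=(0.0, 0.01))


class TestContactStress:
    def test_identical_profiles_give_zero_stress(self):
        p = ph.ParametricContour(R0=6.5, a2=0.1)
        m = contact_stress(8.4, profile_from_param(p), profile_from_param(p))
        assert m.delta_sigma_pa == pytest.approx(0.0, abs=1e-9)

    def test_pressure_arithmetic_and_units(self):
        # gamma = 8.4 mN/m, kappa drop 0.1538 - 0.0943 um^-1 -> ~500 Pa
        theta = np.linspace(-np.pi, np.pi, 256, endpoint=False)
        pts = np.column_stack([6.5 * np.cos(theta), 6.5 * np.sin(theta)])
        rest = CurvatureProfile(theta, np.full(256, 0.1538), pts, np.zeros(2))
        kappa_def = np.full(256, 0.1538)
        kappa_def[np.abs(theta - np.pi / 2) < 0.3] = 0.0943
        deform = CurvatureProfile(theta, kappa_def, pts, np.zeros(2))
        m = contact_stress(8.4, rest, deform)
        assert m.delta_sigma_pa == pytest.approx(1000 * 8.4 * (0.1538 - 0.0943), rel=1e-9)
        assert m.delta_sigma_pa == pytest.approx(499.8, abs=0.1)

    def test_stress_in_pa_equals_pn_per_um2(self):
        p_rest = ph.ParametricContour(R0=6.5)
        p_def = ph.ParametricContour(R0=6.5, a2=0.1)
        m = contact_stress(8.4, profile_from_param(p_rest), profile_from_param(p_def))
        assert m.delta_sigma_pn_per_um2 == m.delta_sigma_pa

    def test_linear_in_gamma_and_delta_kappa(self):
        rest = profile_from_param(ph.ParametricContour(R0=6.5))
        d1 = profile_from_param(ph.ParametricContour(R0=6.5, a2=0.05))
        m1 = contact_stress(4.0, rest, d1)
        m2 = contact_stress(8.0, rest, d1)
        assert m2.delta_sigma_pa == pytest.approx(2 * m1.delta_sigma_pa, rel=1e-12)

    def test_flattening_gives_compressive_positive_stress(self):
        rest = profile_from_param(ph.ParametricContour(R0=6.5))
        deform = profile_from_param(ph.ParametricContour(R0=6.5, a2=0.1))
        m = contact_stress(8.4, rest, deform)
        assert m.delta_sigma_pa > 0

    def test_rigid_motion_invariance(self):
        p_rest = ph.ParametricContour(R0=6.5)
        p_def = ph.ParametricContour(R0=6.5, a1=0.08, a2=0.1)
        c_rest = ph.make_parametric_contour(p_rest)
        c_def = ph.make_parametric_contour(p_def)
        m0 = contact_stress(
            8.4, curvature_profile(c_rest), curvature_profile(c_def), FULL_WINDOW
        )
        ang, dx, dy = 0.0, 15.0, -7.0  # translation only: window is angle-fixed
        m1 = contact_stress(
            8.4,
            curvature_profile(c_rest.rotated(ang).translated(dx, dy)),
            curvature_profile(c_def.rotated(ang).translated(dx, dy)),
            FULL_WINDOW,
        )
        assert m1.delta_sigma_pa == pytest.approx(m0.delta_sigma_pa, rel=1e-9)

    def test_rotation_with_full_window_invariance(self):
        p_rest = ph.ParametricContour(R0=6.5)
        p_def = ph.ParametricContour(R0=6.5, a2=0.1)
        c_rest = ph.make_parametric_contour(p_rest)
        c_def = ph.make_parametric_contour(p_def)
        m0 = contact_stress(8.4, curvature_profile(c_rest), curvature_profile(c_def), FULL_WINDOW)
        rot = 0.7
        m1 = contact_stress(
            8.4,
            curvature_profile(c_rest.rotated(rot)),
            curvature_profile(c_def.rotated(rot)),
            FULL_WINDOW,
        )
        assert m1.delta_sigma_pa == pytest.approx(m0.delta_sigma_pa, rel=1e-9)

    def test_nonpositive_gamma_rejected(self):
        p = ph.ParametricContour(R0=6.5)
        with pytest.raises(ValueError):
            contact_stress(0.0, profile_from_param(p), profile_from_param(p))


class TestCohortStress:
    def test_single_measurement(self):
        rest = profile_from_param(ph.ParametricContour(R0=6.5))
        deform = profile_from_param(ph.ParametricContour(R0=6.5, a2=0.1))
        m = contact_stress(8.4, rest, deform)
        cohort = cohort_stress([m])
        assert cohort.n == 1 and cohort.sd_pa is None
        assert cohort.mean_pa == m.delta_sigma_pa

    def test_hand_arithmetic(self):
        ms = []
        rest = profile_from_param(ph.ParametricContour(R0=6.5))
        for target in (400.0, 500.0, 600.0):
            m = contact_stress(8.4, rest, profile_from_param(ph.ParametricContour(R0=6.5, a2=0.05)))
            m.delta_sigma_pa = target  # inject known values for the pooling check
            ms.append(m)
        cohort = cohort_stress(ms)
        assert cohort.mean_pa == pytest.approx(500.0)
        assert cohort.sd_pa == pytest.approx(100.0)

    def test_simulated_cohort_recovers_construction_mean(self):
        rng = np.random.default_rng(8)
        gamma = 8.4
        rest = profile_from_param(ph.ParametricContour(R0=6.5))
        truths, ms = [], []
        for _ in range(8):
            a2 = 0.1 + rng.normal(0, 0.01)
            p_def = ph.ParametricContour(R0=6.5, a2=a2)
            dk = 1 / 6.5 - ph.parametric_curvature(p_def).min()
            truths.append(1000 * gamma * dk)
            ms.append(contact_stress(gamma, rest, profile_from_param(p_def)))
        cohort = cohort_stress(ms)
        sd = np.std(truths, ddof=1)
        assert abs(cohort.mean_pa - np.mean(truths)) < 2 * sd / np.sqrt(8)

    def test_empty_cohort_raises(self):
        with pytest.raises(EstimationError):
            cohort_stress([])
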