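"""Potentials, closed forms and Morse calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silkbundle import forcefield as ff


class TestMorse:
    def test_zero_at_equilibrium(self, ff_=None):
        p = ff.ForceFieldParams()
        assert ff.morse_energy(p.r0, p.D, p.alpha, p.r0) == 0.0
        assert ff.morse_force(p.r0, p.D, p.alpha, p.r0) == 0.0

    def test_dissociation_plateau(self):
        p = ff.ForceFieldParams()
        assert ff.morse_energy(1.0, p.D, p.alpha, p.r0) == pytest.approx(p.D, rel=1e-6)

    def test_quarter_well_at_log2_extension(self):
        # at r = r0 + ln2/alpha the exponential equals 1/2, so E = D/4
        p = ff.ForceFieldParams()
        r = p.r0 + math.log(2.0) / p.alpha
        assert ff.morse_energy(r, p.D, p.alpha, p.r0) == pytest.approx(p.D / 4, rel=1e-12)

    def test_peak_tension_is_D_alpha_over_2(self):
        p = ff.ForceFieldParams()
        r = p.r0 + math.log(2.0) / p.alpha
        peak = ff.morse_tension(r, p.D, p.alpha, p.r0)
        assert peak == pytest.approx(p.D * p.alpha / 2.0, rel=1e-12)
        # and it is the maximum over a dense grid
        rs = np.linspace(p.r0, p.r0 + 10 / p.alpha, 4000)
        assert ff.morse_tension(rs, p.D, p.alpha, p.r0).max() <= peak * (1 + 1e-9)

    def test_small_strain_stiffness(self):
        p = ff.ForceFieldParams()
        assert p.bond_stiffness == pytest.approx(1.2916e5, rel=1e-3)

    def test_monotone_and_bounded_above_r0(self):
        p = ff.ForceFieldParams()
        rs = np.linspace(p.r0, p.r0 + 20 / p.alpha, 500)
        es = ff.morse_energy(rs, p.D, p.alpha, p.r0)
        assert np.all(np.diff(es) > 0)
        assert es.max() <= p.D

    @given(st.floats(min_value=0.5, max_value=2.0))
    @settings(max_examples=50, deadline=None)
    def test_force_is_negative_gradient(self, rel_r):
        p = ff.ForceFieldParams()
        r = rel_r * p.r0
        h = 1e-5 * p.r0
        num = -(ff.morse_energy(r + h, p.D, p.alpha, p.r0)
                - ff.morse_energy(r - h, p.D, p.alpha, p.r0)) / (2 * h)
        ana = ff.morse_force(r, p.D, p.alpha, p.r0)
        # abs floor: O(h^2) truncation of the central difference, ~1e6x
        # below the peak bond force
        assert ana == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestBendingAndLJ:
    def test_kb_closed_form_matches_printed_value(self):
        # E sigma^4/(128 r0) with E = 11.2 GPa, sigma = 10 um, r0 = 7.1 um
        kb = ff.bending_stiffness_closed_form(11.2e9, 10e-6, 7.1e-6)
        assert kb == pytest.approx(1.2e-7, rel=0.03)

    def test_bending_zero_at_straight_and_symmetric(self):
        kb = 1.2e-7
        assert ff.bending_energy(math.pi, kb) == 0.0
        d = math.radians(1.0)
        assert ff.bending_energy(math.pi - d, kb) == pytest.approx(kb * d * d)

    def test_lj_fixed_points(self):
        eps, sigma = 0.6e-8, 10e-6
        assert ff.lj_energy(sigma, eps, sigma, shifted=False) == pytest.approx(0.0, abs=1e-30)
        rmin = 2 ** (1 / 6) * sigma
        assert ff.lj_energy(rmin, eps, sigma, shifted=False) == pytest.approx(-eps, rel=1e-9)
        rc = 2.5 * sigma
        assert ff.lj_energy(rc * 0.999999, eps, sigma, cutoff=rc) == pytest.approx(0.0, abs=1e-6 * eps)
        assert ff.lj_energy(rc * 1.01, eps, sigma, cutoff=rc) == 0.0

    @given(st.floats(min_value=0.9, max_value=2.4))
    @settings(max_examples=50, deadline=None)
    def test_lj_force_is_negative_gradient(self, rel_r):
        eps, sigma = 0.6e-8, 10e-6
        r = rel_r * sigma
        h = 1e-8 * sigma
        num = -(ff.lj_energy(r + h, eps, sigma, shifted=False)
                - ff.lj_energy(r - h, eps, sigma, shifted=False)) / (2 * h)
        assert ff.lj_force(r, eps, sigma) == pytest.approx(num, rel=1e-5, abs=1e-10)

    def test_lj_zero_distance_raises(self):
        with pytest.raises(ValueError):
            ff.lj_energy(0.0, 1.0, 1.0)


class TestEpsilonOfRadius:
    def test_endpoints_exact(self, ff):
        assert ff_eps(ff, ff.R1) == pytest.approx(0.6e-8, rel=1e-12)
        assert ff_eps(ff, ff.R2) == pytest.approx(0.6e-8 / 6.0, rel=1e-12)

    def test_linear_in_inverse_radius(self, ff):
        inv_mid = 0.5 * (1 / ff.R1 + 1 / ff.R2)
        got = ff_eps(ff, 1.0 / inv_mid)
        assert got == pytest.approx(0.5 * (ff.eps1 + ff.eps2), rel=1e-12)

    def test_monotone_decreasing_on_calibration_interval(self, ff):
        rs = np.linspace(ff.R1, ff.R2, 200)
        vals = np.array([ff_eps(ff, r) for r in rs])
        assert np.all(np.diff(vals) < 0)

    def test_clamped_outside(self, ff):
        assert ff_eps(ff, ff.R1 / 2) == pytest.approx(ff.eps1)
        assert ff_eps(ff, ff.R2 * 2) == pytest.approx(ff.eps2)

    def test_nonpositive_radius_raises(self, ff):
        with pytest.raises(ValueError):
            ff_eps(ff, 0.0)


def ff_eps(p, R):
    from silkbundle.forcefield import epsilon_of_radius
    return epsilon_of_radius(R, p)


class TestCalibration:
    def test_closed_form_modulus_near_printed(self, ff):
        # 2 D alpha^2 r0 / (pi sigma^2/4) with printed parameters
        assert ff_small_strain(ff) / 1e9 == pytest.approx(11.7, rel=0.01)

    def test_rupture_strain_for_printed_toughness(self, ff):
        from silkbundle.forcefield import rupture_strain_for_toughness, single_fibril_curve
        eps_r = rupture_strain_for_toughness(3.0, ff)
        assert 0.02 < eps_r < 0.035
        strain, stress = single_fibril_curve(ff, eps_r, n=20000)
        assert np.trapezoid(stress, strain) == pytest.approx(3.0, rel=1e-4)

    def test_recovers_printed_parameters(self, ff):
        from silkbundle.forcefield import calibrate_morse
        D, alpha = calibrate_morse(11.2, 3.0)
        assert D == pytest.approx(1.41e-8, rel=0.10)
        assert alpha == pytest.approx(2.14e6, rel=0.10)

    def test_round_trip_on_arbitrary_targets(self, ff):
        from silkbundle.forcefield import (calibrate_morse,
                                           _measured_modulus_toughness,
                                           rupture_strain_for_toughness)
        D, alpha = calibrate_morse(9.0, 2.0)
        trial = ff.with_(D=D, alpha=alpha)
        er = rupture_strain_for_toughness(3.0, ff)
        mod, tough = _measured_modulus_toughness(trial, er)
        assert mod == pytest.approx(9.0, rel=0.02)
        assert tough == pytest.approx(2.0, rel=0.05)

    def test_invalid_targets_raise(self):
        from silkbundle.forcefield import calibrate_morse
        with pytest.raises(ValueError):
            calibrate_morse(-1.0, 3.0)


def ff_small_strain(p):
    from silkbundle.forcefield import small_strain_modulus
    return small_strain_modulus(p)
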