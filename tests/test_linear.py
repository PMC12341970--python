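"""Closed-form coupled-resonator theory against independent ODE oracles."""

import numpy as np
import pytest
from scipy import signal

from ecres import ValidationError, linear
from ecres.linear import (
    LinearResonator,
    coupled_impedances,
    coupling_coefficient,
    design_resonator,
    find_peak,
    resonance_vs_gc,
    scaled_gc_profiles,
    uncoupled_impedance,
)

BAND = (0.1, 4.0)


def _sinusoid_response_amplitude(A, B, Cmat, f_hz, n_cycles=12):
    """ODE oracle: drive the linear system with a unit sinusoid at f_hz and
    measure the steady-state output amplitude over the last cycle."""
    period_ms = 1000.0 / f_hz
    t = np.arange(0, n_cycles * period_ms, min(period_ms / 200, 1.0))
    u = np.sin(2 * np.pi * f_hz * t / 1000.0)
    sys = signal.StateSpace(A, B, Cmat, np.zeros((Cmat.shape[0], B.shape[1])))
    _, y, _ = signal.lsim(sys, u, t)
    last = t >= (n_cycles - 1) * period_ms
    y = np.atleast_2d(y.T)
    return np.array([0.5 * (yi[last].max() - yi[last].min()) for yi in y])


class TestUncoupled:
    def test_passive_cell_matches_rc_closed_form(self):
        cell = LinearResonator(C=1.0, g_leak=0.1, g_res=0.0, tau_res=100.0)
        f = np.linspace(0.05, 10, 50)
        z = np.abs(uncoupled_impedance(cell, f))
        w = 2 * np.pi * f / 1000.0
        expected = (1 / 0.1) / np.sqrt(1 + (w * 1.0 / 0.1) ** 2)
        np.testing.assert_allclose(z, expected, rtol=1e-12)
        assert np.all(np.diff(z) < 0)

    def test_impedance_vanishes_at_high_frequency(self):
        cell = LinearResonator()
        assert np.abs(uncoupled_impedance(cell, 1e6)) < 1e-3

    def test_unstable_parameters_rejected(self):
        with pytest.raises(ValidationError):
            LinearResonator(C=1.0, g_leak=-0.2, g_res=0.0, tau_res=100.0)

    def test_resonance_peak_matches_ode_simulation(self, resonator_pair):
        # brute-force oracle: sinusoidal drive on a 0.05 Hz grid
        cell = resonator_pair[0]
        A = cell.jacobian()
        B = np.array([[1.0 / cell.C], [0.0]])
        Cm = np.array([[1.0, 0.0]])
        grid = np.arange(0.5, 1.51, 0.05)
        amps = np.array(
            [_sinusoid_response_amplitude(A, B, Cm, f)[0] for f in grid]
        )
        f_ode = grid[np.argmax(amps)]
        f_formula, _, _ = find_peak(
            lambda f: np.abs(uncoupled_impedance(cell, f)), BAND
        )
        assert abs(f_formula - f_ode) <= 0.05  # within one grid step


class TestCoupled:
    def test_uncoupled_limit(self, resonator_pair):
        p1, p2 = resonator_pair
        f = np.linspace(*BAND, 40)
        zpre, zpost = coupled_impedances(p1, p2, 0.0, f)
        np.testing.assert_allclose(zpre, uncoupled_impedance(p1, f), rtol=1e-12)
        assert np.all(zpost == 0)

    def test_postjunctional_always_below_prejunctional(self, resonator_pair):
        p1, p2 = resonator_pair
        f = np.linspace(*BAND, 200)
        for gc in (0.001, 0.02, 0.5):
            zpre, zpost = coupled_impedances(p1, p2, gc, f)
            assert np.all(np.abs(zpost) < np.abs(zpre))

    def test_identical_cells_match_coupled_ode_simulation(self, resonator_pair):
        # oracle: simulate the 4-variable coupled system per frequency
        p1 = p2 = resonator_pair[0]
        gc = 0.02
        A = linear._coupled_state_space(p1, p2, gc).A
        B = np.array([[1.0 / p1.C], [0.0], [0.0], [0.0]])
        Cm = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
        grid = np.linspace(0.1, 4.0, 14)
        zpre, zpost = coupled_impedances(p1, p2, gc, grid)
        for i, f in enumerate(grid):
            amp = _sinusoid_response_amplitude(A, B, Cm, f)
            assert amp[0] == pytest.approx(np.abs(zpre[i]), rel=0.01)
            assert amp[1] == pytest.approx(np.abs(zpost[i]), rel=0.01)

    def test_swapping_cells_swaps_roles(self, resonator_pair):
        p1, p2 = resonator_pair
        f = np.linspace(*BAND, 60)
        gc = 0.05
        zpre_12, zpost_12 = coupled_impedances(p1, p2, gc, f)
        zpre_21, zpost_21 = coupled_impedances(p2, p1, gc, f)
        # the transfer impedance is reciprocal; the input impedance now sees
        # the other cell's isolated admittance in the numerator
        np.testing.assert_allclose(zpost_12, zpost_21, rtol=1e-12)
        y1 = 1.0 / uncoupled_impedance(p1, f)
        y2 = 1.0 / uncoupled_impedance(p2, f)
        den = (y1 + gc) * (y2 + gc) - gc**2
        np.testing.assert_allclose(zpre_21, (y1 + gc) / den, rtol=1e-12)


class TestCouplingCoefficient:
    def test_limits(self, resonator_pair):
        _, p2 = resonator_pair
        f = np.linspace(*BAND, 30)
        assert np.all(coupling_coefficient(p2, 0.0, f) == 0)
        assert coupling_coefficient(p2, 1e6, f) == pytest.approx(1.0, abs=1e-4)

    def test_independent_of_prejunctional_cell(self, resonator_pair):
        # CC depends only on the postjunctional isolated impedance
        p1a, p2 = resonator_pair
        f = np.linspace(*BAND, 120)
        gc = 0.02
        cc_direct = coupling_coefficient(p2, gc, f)
        others = [
            p1a,
            LinearResonator(C=1.0, g_leak=0.5, g_res=0.0, tau_res=50.0),
            LinearResonator(C=4.0, g_leak=0.05, g_res=0.3, tau_res=400.0),
        ]
        for p1 in others:
            zpre, zpost = coupled_impedances(p1, p2, gc, f)
            ratio = np.abs(zpost) / np.abs(zpre)
            np.testing.assert_allclose(ratio, cc_direct, rtol=1e-9)

    def test_passive_postjunctional_cell_gives_flat_cc(self):
        # algebraic limit: CC = Gc*R2/(1 + Gc*R2), frequency independent
        r2 = 10.0
        p2 = LinearResonator(C=1e-9, g_leak=1.0 / r2, g_res=0.0, tau_res=1.0)
        f = np.linspace(*BAND, 50)
        gc = 0.05
        cc = coupling_coefficient(p2, gc, f)
        expected = gc * r2 / (1 + gc * r2)
        np.testing.assert_allclose(cc, expected, rtol=1e-6)


class TestResonanceVsGc:
    def test_gc_sweep_properties(self, resonator_pair):
        p1, p2 = resonator_pair  # p1 has the lower resonance frequency
        gc_grid = np.array([0.002, 0.01, 0.05, 0.2, 1.0, 5.0])
        tab = resonance_vs_gc(p1, p2, gc_grid, BAND)
        # coupled resonance frequencies converge at strong coupling
        gap = np.abs(tab.f_res_zpre - tab.f_res_zpost)
        assert gap.iloc[-1] < 0.02
        assert gap.iloc[-1] < gap.iloc[0]
        # CC resonance rises monotonically from near f_res(Z2)
        f_cc = tab.f_res_cc.to_numpy()
        assert np.all(np.diff(f_cc) > -1e-6)
        f_z2, _, _ = find_peak(
            lambda f: np.abs(uncoupled_impedance(p2, f)), BAND
        )
        assert tab.f_res_cc.iloc[0] == pytest.approx(f_z2, abs=0.05)

    def test_invalid_grid_rejected(self, resonator_pair):
        p1, p2 = resonator_pair
        with pytest.raises(ValidationError):
            resonance_vs_gc(p1, p2, np.array([0.1, 0.05]))


class TestScaledGc:
    def test_unit_scale_reduces_to_constant_coupling(self, resonator_pair):
        p1, p2 = resonator_pair
        f = np.linspace(*BAND, 100)
        out = scaled_gc_profiles(p1, p2, 0.02, lambda x: np.ones_like(x), f)
        zpre, zpost = coupled_impedances(p1, p2, 0.02, f)
        np.testing.assert_allclose(out["zpre"], np.abs(zpre), rtol=1e-12)
        np.testing.assert_allclose(out["cc"], coupling_coefficient(p2, 0.02, f), rtol=1e-12)

    def test_inverted_u_amplifies_and_shifts_cc(self, resonator_pair):
        # junction matched to the constant value at the top band edge but
        # larger through the middle: CC is amplified and its resonance
        # pulled toward the scale profile's peak
        p1, p2 = resonator_pair
        f = np.linspace(*BAND, 400)
        f_scale_peak = np.log(50.0) / 4.9
        bump = lambda x: linear.inverted_u_scale(x, normalize_at="band_top")
        scaled = scaled_gc_profiles(p1, p2, 0.02, bump, f)
        const = coupling_coefficient(p2, 0.02, f)
        assert scaled["cc"].max() > const.max()
        f_cc_scaled = f[np.argmax(scaled["cc"])]
        f_cc_const = f[np.argmax(const)]
        assert abs(f_cc_scaled - f_scale_peak) < abs(f_cc_const - f_scale_peak)

    def test_nonpositive_scale_rejected(self, resonator_pair):
        p1, p2 = resonator_pair
        with pytest.raises(ValidationError):
            scaled_gc_profiles(p1, p2, 0.02, lambda x: 0.0 * x, np.linspace(0.1, 4, 10))


class TestDesignHelper:
    @pytest.mark.parametrize("f_res, z_peak", [(0.7, 10.0), (1.27, 8.0), (2.0, 20.0)])
    def test_inversion_hits_requested_resonance(self, f_res, z_peak):
        cell = design_resonator(f_res, z_peak)
        fp, pk, edge = find_peak(
            lambda f: np.abs(uncoupled_impedance(cell, f)), (0.01, 10.0)
        )
        assert not edge
        assert fp == pytest.approx(f_res, rel=1e-3)
        assert pk == pytest.approx(z_peak, rel=1e-3)
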