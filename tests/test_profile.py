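"""Spectral-ratio estimation, polynomial resonance fits, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecres import FitError, Trace, ValidationError, linear
from ecres.profile import (
    FrequencyProfile,
    chirp_segment,
    coupling_profiles,
    fit_resonance,
    normalize_profile,
    spectral_ratio,
    step_coupling_estimate,
)
from ecres.stimulus import (
    ZapParams,
    current_zap,
    generate_zap,
    step_protocol,
    step_windows,
)

BAND = (0.1, 4.0)


def make_profile(f, a, **kw):
    return FrequencyProfile(f=f, amplitude=a, **kw)


class TestSpectralRatio:
    def test_identical_channels_give_unity(self, short_zap):
        tr = generate_zap(short_zap, "a", "mV")
        tr.add_channel("b", tr["a"].copy(), "mV")
        prof = spectral_ratio(tr, "a", "b", BAND)
        np.testing.assert_allclose(prof.amplitude, 1.0, rtol=1e-9)

    def test_rc_impedance_recovered_within_2_percent(self, standard_zap):
        # analytic oracle: |Z| = R/sqrt(1+(wRC)^2) for R = 10 MOhm, C = 1 nF
        cell = linear.LinearResonator(C=1.0, g_leak=0.1, g_res=0.0, tau_res=1.0)
        tr = linear.simulate_coupled_currentclamp(cell, cell, 0.0, standard_zap)
        seg = chirp_segment(tr, standard_zap)
        prof = spectral_ratio(seg, "V_pre", "I_pre", BAND, quantity="Zpre")
        w = 2 * np.pi * prof.f / 1000.0
        expected = 10.0 / np.sqrt(1 + (w * 10.0) ** 2)
        err = np.abs(prof.amplitude - expected) / expected
        assert np.nanmax(err) < 0.02

    def test_cc_profile_matches_closed_form_within_2_percent(
        self, resonator_pair, standard_zap
    ):
        p1, p2 = resonator_pair
        tr = linear.simulate_coupled_currentclamp(p1, p2, 0.02, standard_zap)
        profs = coupling_profiles(tr, standard_zap)
        cc_ref = linear.coupling_coefficient(p2, 0.02, profs["CC"].f)
        err = np.abs(profs["CC"].amplitude - cc_ref) / cc_ref
        assert np.nanmax(err) < 0.02

    def test_cc_equals_zpost_over_zpre_pointwise(self, resonator_pair, short_zap):
        p1, p2 = resonator_pair
        tr = linear.simulate_coupled_currentclamp(p1, p2, 0.02, short_zap)
        profs = coupling_profiles(tr, short_zap, smooth_bw=0.0)
        ratio = profs["Zpost"].amplitude / profs["Zpre"].amplitude
        np.testing.assert_allclose(profs["CC"].amplitude, ratio, rtol=1e-9)

    def test_sweep_direction_invariance(self, resonator_pair):
        # up- and down-sweep chirps see the same transfer function
        p1, p2 = resonator_pair
        kw = dict(f_lo=0.1, f_hi=4.0, t_max=50.0, amplitude=1.5, offset=1.5,
                  n_precycles=2, dt=1e-3, phase0=np.pi)
        up = ZapParams(**kw, sweep="up")
        down = ZapParams(**kw, sweep="down")
        prof_up = coupling_profiles(
            linear.simulate_coupled_currentclamp(p1, p2, 0.02, up), up
        )["Zpre"]
        prof_down = coupling_profiles(
            linear.simulate_coupled_currentclamp(p1, p2, 0.02, down), down
        )["Zpre"]
        np.testing.assert_allclose(
            prof_up.amplitude, prof_down.amplitude, rtol=0.01
        )

    def test_dead_denominator_points_masked_with_warning(self):
        rng = np.random.default_rng(0)
        dt = 1e-3
        t = np.arange(0, 60, dt)
        den = np.sin(2 * np.pi * 0.5 * t)  # energy only at 0.5 Hz
        num = rng.normal(0, 1, t.size)
        tr = Trace(0.0, dt, {"n": num, "d": den}, {"n": "mV", "d": "mV"})
        with pytest.warns(RuntimeWarning, match="masked"):
            prof = spectral_ratio(tr, "n", "d", BAND)
        assert np.isnan(prof.amplitude).any()
        assert prof.n_valid > 0

    def test_missing_channel_rejected(self, short_zap):
        tr = generate_zap(short_zap, "a", "mV")
        with pytest.raises(ValidationError):
            spectral_ratio(tr, "a", "nope", BAND)


class TestFitResonance:
    def test_known_unimodal_curve_peak_recovered(self, resonator_pair):
        cell = resonator_pair[0]
        f = np.linspace(0.1, 4.0, 200)
        amp = np.abs(linear.uncoupled_impedance(cell, f))
        s = fit_resonance(make_profile(f, amp))
        true_peak = f[np.argmax(amp)]
        assert abs(s.f_res - true_peak) <= f[1] - f[0]
        assert not s.at_edge
        assert s.peak >= amp.max() * 0.99

    def test_monotone_profile_flagged_no_interior_resonance(self):
        f = np.linspace(0.1, 4.0, 100)
        amp = 10.0 / (1 + f)
        s = fit_resonance(make_profile(f, amp))
        assert s.at_edge
        assert s.f_res == pytest.approx(0.1)

    def test_too_few_points_rejected(self):
        f = np.linspace(0.1, 4.0, 6)
        with pytest.raises(FitError):
            fit_resonance(make_profile(f, np.ones(6)))

    def test_fit_ignores_masked_points(self):
        f = np.linspace(0.1, 4.0, 150)
        amp = np.exp(-0.5 * (f - 1.5) ** 2)
        amp_masked = amp.copy()
        amp_masked[40:45] = np.nan
        s = fit_resonance(make_profile(f, amp_masked))
        assert s.f_res == pytest.approx(1.5, abs=0.05)


class TestNormalize:
    def test_unit_value_at_lowest_frequency(self):
        f = np.linspace(0.1, 4.0, 50)
        prof = make_profile(f, 3.0 + f)
        out = normalize_profile(prof)
        assert out.amplitude[0] == pytest.approx(1.0)
        assert out.normalized

    def test_peak_becomes_ratio_to_baseline(self):
        f = np.linspace(0.1, 4.0, 50)
        amp = 2.0 * np.exp(-0.5 * (f - 1.0) ** 2) + 1.0
        out = normalize_profile(make_profile(f, amp))
        assert out.amplitude.max() == pytest.approx(amp.max() / amp[0])

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=15, deadline=None)
    def test_idempotent(self, scale):
        f = np.linspace(0.1, 4.0, 30)
        prof = make_profile(f, scale * (1 + np.sin(f) ** 2))
        once = normalize_profile(prof)
        twice = normalize_profile(once)
        np.testing.assert_allclose(once.amplitude, twice.amplitude, rtol=1e-12)

    def test_zero_baseline_rejected(self):
        f = np.linspace(0.1, 4.0, 30)
        amp = np.ones(30)
        amp[0] = 0.0
        with pytest.raises(ValidationError):
            normalize_profile(make_profile(f, amp))


class TestStepEstimates:
    def test_exact_proportional_voltages(self):
        cmd = step_protocol(np.array([-80.0, -70.0, -50.0, -40.0]), -60.0, dt=1e-3)
        tr = Trace(
            0.0, 1e-3,
            {"V_pre": cmd["V"], "V_post": 0.3 * cmd["V"]},
            {"V_pre": "mV", "V_post": "mV"},
        )
        cc = step_coupling_estimate(tr, "currentclamp", step_windows(4))
        assert cc == pytest.approx(0.3, rel=1e-9)

    def test_zero_coupling_gives_zero_slope(self):
        cmd = step_protocol(np.array([-80.0, -60.0, -40.0]), -60.0, dt=1e-3)
        tr = Trace(
            0.0, 1e-3,
            {"V_pre": cmd["V"], "I_post": np.zeros(len(cmd))},
            {"V_pre": "mV", "I_post": "nA"},
        )
        gc = step_coupling_estimate(tr, "voltageclamp", step_windows(3))
        assert gc == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_steps_rejected(self):
        cmd = step_protocol(np.array([-80.0, -40.0]), -60.0, dt=1e-3)
        tr = Trace(
            0.0, 1e-3,
            {"V_pre": cmd["V"], "V_post": cmd["V"]},
            {"V_pre": "mV", "V_post": "mV"},
        )
        with pytest.raises(ValidationError, match="3 steps"):
            step_coupling_estimate(tr, "currentclamp", step_windows(2))

    def test_passive_coupled_cells_recover_junctional_conductance(self):
        # simulation oracle: two passive cells, both somas clamped, steps
        # -80..-40 mV; the I_post/V_pre regression slope returns Gc
        from ecres.cells import CellSpec, ChannelSpec, NetworkSpec, simulate

        passive = CellSpec(
            "p", C=1.0, channels=(ChannelSpec("leak", g_max=100.0, e_rev=-60.0),)
        )
        levels = np.array([-80.0, -70.0, -50.0, -40.0])
        cmd = step_protocol(levels, -60.0, t_baseline=0.5, t_step=0.5, dt=5e-5)
        n = cmd.n_samples
        gc_true = 30.0  # nS
        net = NetworkSpec(
            cells=[passive, CellSpec("q", C=1.0, channels=passive.channels)],
            coupling_ns=np.array([[0.0, gc_true], [gc_true, 0.0]]),
            clamp=[cmd["V"], np.full(n, -60.0)],
        )
        sim = simulate(net, None, (n - 1) * 0.05, dt_ms=0.05, record_dt_ms=0.5)
        tr = Trace(
            0.0, sim.dt,
            {"V_pre": sim["V_p"], "I_post": sim["I_clamp_q"]},
            {"V_pre": "mV", "I_post": "nA"},
        )
        windows = step_windows(4, 0.5, 0.5)
        gc = step_coupling_estimate(tr, "voltageclamp", windows)
        assert gc * 1e3 == pytest.approx(gc_true, rel=0.01)
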