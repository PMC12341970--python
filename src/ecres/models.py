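"""PD-like resonator cell models and the coupled-pair protocols.

The resonator cell is a single compartment with leak, a slowly
inactivating calcium current (the resonant, restorative current) and a
hyperpolarization-activated inward current.  Around the holding range it
produces subthreshold membrane-potential resonance near 1 Hz.  A variant
with larger leak and slower kinetics realizes the same peak impedance at
a lower resonance frequency; a third, distinct resonator (leak + Ca +
slow K + modulatory inward current) stands in for an unclamped
pacemaker-type neighbour in the three-cell voltage-clamp circuit.
"""

from __future__ import annotations

import numpy as np

from .cells import CellSpec, ChannelSpec, GateSpec, NetworkSpec, simulate
from .profile import FrequencyProfile, coupling_profiles, spectral_ratio, chirp_segment
from .stimulus import ZapParams, generate_zap
from .trace import Trace


def resonator_cell(name: str = "pd", low_fres_variant: bool = False) -> CellSpec:
    """Single-compartment resonant cell (C = 2 nF).

    ``low_fres_variant=True`` selects the prejunctional variant with a
    larger leak (107.8 nS), 1.8x slower Ca inactivation and slower
    h-current activation, which lowers the resonance frequency while
    keeping the peak impedance.
    """
    g_leak = 107.8 if low_fres_variant else 98.0
    ca_tau_h = GateSpec(v_half=-60.0, k=5.0, power=1, tau0=220.0, tau1=400.0,
                        tau_vhalf=-60.0, tau_k=5.0)
    h_tau_m = (100.0, 1400.0)
    if low_fres_variant:
        ca_tau_h = ca_tau_h.scale_tau(1.8)
        h_tau_m = (800.0, 1600.0)
    return CellSpec(
        name=name,
        C=2.0,
        channels=(
            ChannelSpec("leak", g_max=g_leak, e_rev=-60.0),
            ChannelSpec(
                "Ca",
                g_max=100.0,
                e_rev=120.0,
                m=GateSpec(v_half=-52.0, k=-7.2, power=3, tau0=40.0),
                h=ca_tau_h,
            ),
            ChannelSpec(
                "h",
                g_max=60.0,
                e_rev=-20.0,
                m=GateSpec(v_half=-65.0, k=4.0, power=2,
                           tau0=h_tau_m[0], tau1=h_tau_m[1],
                           tau_vhalf=-65.0, tau_k=4.0),
            ),
        ),
    )


def model_cell_3(name: str = "cell3") -> CellSpec:
    """The distinct third resonator: leak, Ca, slow K (KS) and a
    modulatory inward current (MI); C = 2 nF."""
    return CellSpec(
        name=name,
        C=2.0,
        channels=(
            ChannelSpec("leak", g_max=30.0, e_rev=-58.0),
            ChannelSpec(
                "Ca",
                g_max=12.0,
                e_rev=120.0,
                m=GateSpec(v_half=-55.56, k=-3.0, power=3,
                           tau0=8.95, tau1=58.37, tau_vhalf=-54.5, tau_k=3.0),
                h=GateSpec(v_half=-60.12, k=2.0, power=1, tau0=3155.4),
            ),
            ChannelSpec(
                "KS",
                g_max=30.0,
                e_rev=-80.0,
                m=GateSpec(v_half=-56.0, k=-2.0, power=2,
                           tau0=2000.0, tau1=-1500.0, tau_vhalf=-55.0, tau_k=-1.0),
            ),
            ChannelSpec(
                "MI",
                g_max=11.0,
                e_rev=-10.0,
                m=GateSpec(v_half=-55.0, k=-5.0, power=1, tau0=20.0),
            ),
        ),
    )


def _settle_pad(zap: ZapParams, settle_s: float, value: float) -> np.ndarray:
    n_settle = int(round(settle_s / zap.dt))
    return np.full(n_settle, value)


def _zap_with_settle(
    zap: ZapParams, settle_s: float, channel: str, unit: str, tail_s: float = 2.0
) -> Trace:
    """Stimulus padded with a settling period before and a baseline tail
    after; the tail lets the analysis capture the response ring-down."""
    body = generate_zap(zap, channel=channel, unit=unit)
    pad = _settle_pad(zap, settle_s, body[channel][0])
    tail = _settle_pad(zap, tail_s, body[channel][0])
    sig = np.concatenate([pad, body[channel], tail])
    return Trace(t0=0.0, dt=zap.dt, channels={channel: sig}, units={channel: unit})


def run_coupled_currentclamp(
    cell1: CellSpec,
    cell2: CellSpec,
    gc_ns: float,
    zap: ZapParams,
    settle_s: float = 5.0,
    dt_ms: float = 0.05,
    record_dt_ms: float = 1.0,
    v_init: float = -60.0,
    include_isolated: bool = True,
) -> dict:
    """ZAP current into cell 1 of a coupled pair; measure Zpre, Zpost, CC.

    An initial ``settle_s`` seconds at the stimulus baseline sheds the
    relaxation to rest before the pre-cycles begin; the analysis excludes
    both.  With ``include_isolated`` the same stimulus is also applied to
    each cell alone (Gc = 0) to obtain the isolated profiles Z1 and Z2.
    """
    stim = _zap_with_settle(zap, settle_s, "I", "nA")
    duration_ms = (stim.n_samples - 1) * zap.dt * 1000.0
    # the kernel consumes stimuli on its own time grid
    t_sim = np.arange(int(round(duration_ms / dt_ms)) + 1) * dt_ms
    i_sim = np.interp(t_sim, stim.time() * 1000.0, stim["I"])
    gmat = np.array([[0.0, gc_ns], [gc_ns, 0.0]])
    net = NetworkSpec(cells=[cell1, cell2], coupling_ns=gmat)
    sim = simulate(net, {0: i_sim}, duration_ms, dt_ms=dt_ms,
                   record_dt_ms=record_dt_ms, v_init=v_init)
    rec = Trace(
        t0=0.0,
        dt=sim.dt,
        channels={
            "V_pre": sim[f"V_{cell1.name}"],
            "V_post": sim[f"V_{cell2.name}"],
            "I_pre": _resample(stim["I"], zap.dt, sim.dt, sim.n_samples),
            "I_post": np.zeros(sim.n_samples),
        },
        units={"V_pre": "mV", "V_post": "mV", "I_pre": "nA", "I_post": "nA"},
    )
    out = {
        "trace": rec,
        "profiles": coupling_profiles(rec, zap, mode="currentclamp",
                                      t_stim_start=settle_s),
    }
    if include_isolated:
        for tag, cell in (("Z1", cell1), ("Z2", cell2)):
            iso = simulate(
                NetworkSpec(cells=[cell], coupling_ns=np.zeros((1, 1))),
                {0: i_sim}, duration_ms, dt_ms=dt_ms,
                record_dt_ms=record_dt_ms, v_init=v_init,
            )
            iso_rec = Trace(
                t0=0.0, dt=iso.dt,
                channels={"V": iso[f"V_{cell.name}"],
                          "I": _resample(stim["I"], zap.dt, iso.dt, iso.n_samples)},
                units={"V": "mV", "I": "nA"},
            )
            seg = chirp_segment(iso_rec, zap, settle_s)
            prof = spectral_ratio(seg, "V", "I", (zap.f_lo, zap.f_hi), quantity="Zk")
            prof.quantity = tag
            out["profiles"][tag] = prof
    return out


def _resample(x: np.ndarray, dt_in: float, dt_out: float, n_out: int) -> np.ndarray:
    step = int(round(dt_out / dt_in))
    y = x[::step]
    if len(y) < n_out:
        y = np.concatenate([y, np.full(n_out - len(y), y[-1])])
    return y[:n_out].copy()


def run_dual_voltageclamp(
    cells: list[CellSpec],
    coupling_ns: np.ndarray,
    zap_cmd: ZapParams,
    v_hold: float = -60.0,
    settle_s: float = 5.0,
    dt_ms: float = 0.05,
    record_dt_ms: float = 1.0,
    tail_s: float = 2.0,
) -> dict:
    """Dual voltage-clamp protocol on a 2- or 3-cell coupled circuit.

    Cell 0 (prejunctional) is clamped with the voltage ZAP, cell 1
    (postjunctional) is held at ``v_hold``; any further cells run free.
    Returns the recording plus the Zpre and Gc profiles (and, with a
    third cell, its voltage for inspection).  For a two-cell circuit the
    postjunctional current amplitude is frequency independent and the Gc
    profile recovers the configured junctional conductance; a free
    resonant third cell coupled to both makes |I_post|(f) peak at an
    interior frequency.
    """
    cmd_body = generate_zap(zap_cmd, channel="V", unit="mV")
    n_settle = int(round(settle_s / zap_cmd.dt))
    n_tail = int(round(tail_s / zap_cmd.dt))
    cmd_pre = np.concatenate(
        [np.full(n_settle, cmd_body["V"][0]), cmd_body["V"], np.full(n_tail, v_hold)]
    )
    # upsample commands to the simulation grid by linear interpolation
    t_cmd = np.arange(cmd_pre.size) * zap_cmd.dt * 1000.0
    duration_ms = t_cmd[-1]
    t_sim = np.arange(int(round(duration_ms / dt_ms)) + 1) * dt_ms
    cmd_pre_sim = np.interp(t_sim, t_cmd, cmd_pre)
    cmd_post_sim = np.full(t_sim.size, v_hold)
    clamp = [cmd_pre_sim, cmd_post_sim] + [None] * (len(cells) - 2)
    net = NetworkSpec(cells=list(cells), coupling_ns=np.asarray(coupling_ns, float),
                      clamp=clamp)
    sim = simulate(net, None, duration_ms, dt_ms=dt_ms, record_dt_ms=record_dt_ms,
                   v_init=v_hold)
    rec = Trace(
        t0=0.0,
        dt=sim.dt,
        channels={
            "V_pre": sim[f"V_{cells[0].name}"],
            "V_post": sim[f"V_{cells[1].name}"],
            "I_pre": sim[f"I_clamp_{cells[0].name}"],
            "I_post": sim[f"I_clamp_{cells[1].name}"],
        },
        units={"V_pre": "mV", "V_post": "mV", "I_pre": "nA", "I_post": "nA"},
    )
    profiles = coupling_profiles(rec, zap_cmd, mode="voltageclamp",
                                 t_stim_start=settle_s)
    out = {"trace": rec, "profiles": profiles, "sim": sim}
    if len(cells) > 2:
        out["v_free"] = sim[f"V_{cells[2].name}"]
    return out
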