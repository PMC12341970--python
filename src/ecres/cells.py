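"""Single-compartment conductance-based cells and coupled networks.

Cells are Hodgkin-Huxley style: C dV/dt = -sum(I_ion) - sum_j Gc_ij*(V-Vj)
+ I_inj, with each ionic current I = gmax * m^p * h^q * (V - E) and gates
obeying dx/dt = (x_inf(V) - x)/tau_x(V).  All steady-state curves are
logistic, x_inf(v) = 1/(1 + exp((v - v_half)/k)) with signed slope k, and
every voltage-dependent time constant in this family is of the form
tau(v) = tau0 + tau1/(1 + exp((v - tau_vhalf)/tau_k)), which covers
constants, curves proportional to the gate's own steady state, and
independent logistics.

Integration is fixed-step classical Runge-Kutta (RK4) in a numba kernel.
Voltage clamp is ideal: a clamped compartment's voltage follows its
command exactly and the reported clamp current is the residual of the
current balance, C dVcmd/dt + sum(I_ion) + sum(coupling current out).

Units: mV, ms, nF, uS (conductance specs are given in nS and converted),
nA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import IntegrationError, ValidationError
from .trace import Trace

V_CHECK_RANGE = (-120.0, 60.0)


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: logistic steady state plus its time constant.

    ``x_inf(v) = 1/(1 + exp((v - v_half)/k))`` (k < 0: activates with
    depolarization); ``tau(v) = tau0 + tau1/(1 + exp((v - tau_vhalf)/tau_k))``
    in ms.  ``tau0 = tau1 = 0`` marks an instantaneous gate (x = x_inf(V)).
    """

    v_half: float
    k: float
    power: int
    tau0: float
    tau1: float = 0.0
    tau_vhalf: float = 0.0
    tau_k: float = 1.0

    def __post_init__(self) -> None:
        if self.k == 0 or self.tau_k == 0:
            raise ValidationError("logistic slopes must be nonzero")
        if self.power < 1:
            raise ValidationError("gate exponent must be a positive integer")
        if not self.instantaneous:
            v = np.linspace(*V_CHECK_RANGE, 361)
            if np.any(self.tau(v) <= 0):
                raise ValidationError(
                    f"tau(v) must stay positive over {V_CHECK_RANGE} mV"
                )

    @property
    def instantaneous(self) -> bool:
        return self.tau0 == 0.0 and self.tau1 == 0.0

    def x_inf(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((np.asarray(v, float) - self.v_half) / self.k))

    def tau(self, v: np.ndarray) -> np.ndarray:
        return self.tau0 + self.tau1 / (
            1.0 + np.exp((np.asarray(v, float) - self.tau_vhalf) / self.tau_k)
        )

    def scale_tau(self, factor: float) -> "GateSpec":
        """Return a copy with both tau terms multiplied by ``factor``."""
        return replace(self, tau0=self.tau0 * factor, tau1=self.tau1 * factor)


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    g_max: float  # nS
    e_rev: float  # mV
    m: GateSpec | None = None  # activation
    h: GateSpec | None = None  # inactivation

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValidationError("g_max must be nonnegative")


@dataclass(frozen=True)
class CellSpec:
    name: str
    C: float  # nF
    channels: tuple[ChannelSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("capacitance must be positive")
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass
class NetworkSpec:
    """Cells plus a symmetric gap-junction conductance matrix (nS).

    ``clamp[i]`` is None for a free cell or a per-sample command array
    (mV, at the simulation dt) for an ideally voltage-clamped cell.
    """

    cells: list[CellSpec]
    coupling_ns: np.ndarray
    clamp: list[np.ndarray | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.coupling_ns, dtype=float)
        n = len(self.cells)
        if g.shape != (n, n):
            raise ValidationError("coupling matrix shape must match cell count")
        if not np.allclose(g, g.T):
            raise ValidationError("coupling matrix must be symmetric")
        if np.any(g < 0) or np.any(np.diag(g) != 0):
            raise ValidationError("coupling matrix must be nonnegative with zero diagonal")
        self.coupling_ns = g
        if not self.clamp:
            self.clamp = [None] * n
        if len(self.clamp) != n:
            raise ValidationError("clamp list length must match cell count")


# ---------------------------------------------------------------------------
# Parameter packing and the RK4 kernel
# ---------------------------------------------------------------------------

_NPAR = 16
# packed channel row: g(uS), e, p, m_vh, m_k, m_t0, m_t1, m_tvh, m_tk,
#                     q, h_vh, h_k, h_t0, h_t1, h_tvh, h_tk


def _pack_network(net: NetworkSpec):
    cap = np.array([c.C for c in net.cells])
    rows, owner = [], []
    for ci, cell in enumerate(net.cells):
        for ch in cell.channels:
            row = np.zeros(_NPAR)
            row[0] = ch.g_max * 1e-3  # nS -> uS
            row[1] = ch.e_rev
            if ch.m is not None:
                row[2] = ch.m.power
                row[3:9] = (ch.m.v_half, ch.m.k, ch.m.tau0, ch.m.tau1,
                            ch.m.tau_vhalf, ch.m.tau_k)
            if ch.h is not None:
                row[9] = ch.h.power
                row[10:16] = (ch.h.v_half, ch.h.k, ch.h.tau0, ch.h.tau1,
                              ch.h.tau_vhalf, ch.h.tau_k)
            rows.append(row)
            owner.append(ci)
    chp = np.array(rows) if rows else np.zeros((0, _NPAR))
    chc = np.array(owner, dtype=np.int64)
    ii, jj, gg = [], [], []
    n = len(net.cells)
    for i in range(n):
        for j in range(i + 1, n):
            if net.coupling_ns[i, j] > 0:
                ii.append(i)
                jj.append(j)
                gg.append(net.coupling_ns[i, j] * 1e-3)  # nS -> uS
    return (
        cap,
        chp,
        chc,
        np.array(ii, dtype=np.int64),
        np.array(jj, dtype=np.int64),
        np.array(gg, dtype=float),
    )


@njit(cache=True, fastmath=False)
def _xinf(v, vh, k):
    return 1.0 / (1.0 + np.exp((v - vh) / k))


@njit(cache=True, fastmath=False)
def _tau(v, t0, t1, tvh, tk):
    if t1 == 0.0:
        return t0
    return t0 + t1 / (1.0 + np.exp((v - tvh) / tk))


@njit(cache=True, fastmath=False)
def _ipow(x, p):
    out = 1.0
    for _ in range(p):
        out *= x
    return out


@njit(cache=True, fastmath=False)
def _derivs(V, m, h, cap, chp, chc, ei, ej, eg, clamped, inj, dV, dm, dh, imem):
    ncell = cap.size
    for c in range(ncell):
        imem[c] = 0.0
        dV[c] = 0.0
    for k in range(chp.shape[0]):
        c = chc[k]
        v = V[c]
        gate = 1.0
        p = int(chp[k, 2])
        if p > 0:
            minf = _xinf(v, chp[k, 3], chp[k, 4])
            if chp[k, 5] == 0.0 and chp[k, 6] == 0.0:  # instantaneous
                m[k] = minf
                dm[k] = 0.0
            else:
                dm[k] = (minf - m[k]) / _tau(v, chp[k, 5], chp[k, 6], chp[k, 7], chp[k, 8])
            gate *= _ipow(m[k], p)
        else:
            dm[k] = 0.0
        q = int(chp[k, 9])
        if q > 0:
            hinf = _xinf(v, chp[k, 10], chp[k, 11])
            if chp[k, 12] == 0.0 and chp[k, 13] == 0.0:
                h[k] = hinf
                dh[k] = 0.0
            else:
                dh[k] = (hinf - h[k]) / _tau(v, chp[k, 12], chp[k, 13], chp[k, 14], chp[k, 15])
            gate *= _ipow(h[k], q)
        else:
            dh[k] = 0.0
        imem[c] += chp[k, 0] * gate * (v - chp[k, 1])
    for e in range(ei.size):
        icpl = eg[e] * (V[ei[e]] - V[ej[e]])
        imem[ei[e]] += icpl
        imem[ej[e]] -= icpl
    for c in range(ncell):
        if clamped[c]:
            dV[c] = 0.0
        else:
            dV[c] = (inj[c] - imem[c]) / cap[c]


@njit(cache=True, fastmath=False)
def _rk4_run(cap, chp, chc, ei, ej, eg, clamped, cmd, stim, v0, m0, h0,
             dt, nsteps, rec_every):
    """cmd, stim: (ncell, nsteps+1) command voltage / injected current at
    the simulation grid (rows of zeros for cells without one).

    Returns (Vrec, Icl_rec, m_rec_last, status_step).  status_step >= 0
    marks the first step at which a non-finite state appeared.
    """
    ncell = cap.size
    nch = chp.shape[0]
    V = v0.copy()
    m = m0.copy()
    h = h0.copy()
    nrec = nsteps // rec_every + 1
    Vrec = np.empty((ncell, nrec))
    Iclrec = np.empty((ncell, nrec))

    dV1 = np.zeros(ncell); dV2 = np.zeros(ncell); dV3 = np.zeros(ncell); dV4 = np.zeros(ncell)
    dm1 = np.zeros(nch); dm2 = np.zeros(nch); dm3 = np.zeros(nch); dm4 = np.zeros(nch)
    dh1 = np.zeros(nch); dh2 = np.zeros(nch); dh3 = np.zeros(nch); dh4 = np.zeros(nch)
    imem = np.zeros(ncell)
    Vt = np.zeros(ncell); mt = np.zeros(nch); ht = np.zeros(nch)
    injm = np.zeros(ncell)

    # record initial state
    _derivs(V, m, h, cap, chp, chc, ei, ej, eg, clamped, stim[:, 0], dV1, dm1, dh1, imem)
    for c in range(ncell):
        Vrec[c, 0] = V[c]
        dcmd = (cmd[c, 1] - cmd[c, 0]) / dt if nsteps > 0 else 0.0
        Iclrec[c, 0] = cap[c] * dcmd + imem[c] if clamped[c] else 0.0

    r = 1
    for i in range(nsteps):
        # substep inputs
        for c in range(ncell):
            injm[c] = 0.5 * (stim[c, i] + stim[c, i + 1])
        # k1 at t_i
        for c in range(ncell):
            if clamped[c]:
                V[c] = cmd[c, i]
        _derivs(V, m, h, cap, chp, chc, ei, ej, eg, clamped, stim[:, i], dV1, dm1, dh1, imem)
        # k2, k3 at t_i + dt/2
        for c in range(ncell):
            Vt[c] = cmd[c, i] + 0.5 * (cmd[c, i + 1] - cmd[c, i]) if clamped[c] else V[c] + 0.5 * dt * dV1[c]
        for k in range(nch):
            mt[k] = m[k] + 0.5 * dt * dm1[k]
            ht[k] = h[k] + 0.5 * dt * dh1[k]
        _derivs(Vt, mt, ht, cap, chp, chc, ei, ej, eg, clamped, injm, dV2, dm2, dh2, imem)
        for c in range(ncell):
            if not clamped[c]:
                Vt[c] = V[c] + 0.5 * dt * dV2[c]
        for k in range(nch):
            mt[k] = m[k] + 0.5 * dt * dm2[k]
            ht[k] = h[k] + 0.5 * dt * dh2[k]
        _derivs(Vt, mt, ht, cap, chp, chc, ei, ej, eg, clamped, injm, dV3, dm3, dh3, imem)
        # k4 at t_{i+1}
        for c in range(ncell):
            Vt[c] = cmd[c, i + 1] if clamped[c] else V[c] + dt * dV3[c]
        for k in range(nch):
            mt[k] = m[k] + dt * dm3[k]
            ht[k] = h[k] + dt * dh3[k]
        _derivs(Vt, mt, ht, cap, chp, chc, ei, ej, eg, clamped, stim[:, i + 1], dV4, dm4, dh4, imem)
        # combine
        ok = True
        for c in range(ncell):
            if clamped[c]:
                V[c] = cmd[c, i + 1]
            else:
                V[c] += dt / 6.0 * (dV1[c] + 2.0 * dV2[c] + 2.0 * dV3[c] + dV4[c])
            if not np.isfinite(V[c]):
                ok = False
        for k in range(nch):
            m[k] += dt / 6.0 * (dm1[k] + 2.0 * dm2[k] + 2.0 * dm3[k] + dm4[k])
            h[k] += dt / 6.0 * (dh1[k] + 2.0 * dh2[k] + 2.0 * dh3[k] + dh4[k])
            if m[k] < 0.0:
                m[k] = 0.0
            elif m[k] > 1.0:
                m[k] = 1.0
            if h[k] < 0.0:
                h[k] = 0.0
            elif h[k] > 1.0:
                h[k] = 1.0
        if not ok:
            return Vrec, Iclrec, m, h, i + 1
        if (i + 1) % rec_every == 0:
            _derivs(V, m, h, cap, chp, chc, ei, ej, eg, clamped, stim[:, i + 1],
                    dV1, dm1, dh1, imem)
            for c in range(ncell):
                Vrec[c, r] = V[c]
                if clamped[c]:
                    if i + 2 <= nsteps:
                        dcmd = (cmd[c, i + 2] - cmd[c, i]) / (2.0 * dt)
                    else:
                        dcmd = (cmd[c, i + 1] - cmd[c, i]) / dt
                    Iclrec[c, r] = cap[c] * dcmd + imem[c]
                else:
                    Iclrec[c, r] = 0.0
            r += 1
    return Vrec, Iclrec, m, h, -1


def steady_gates(cell: CellSpec, v: float) -> tuple[np.ndarray, np.ndarray]:
    """Gate values at steady state for a fixed voltage."""
    m0, h0 = [], []
    for ch in cell.channels:
        m0.append(float(ch.m.x_inf(v)) if ch.m is not None else 1.0)
        h0.append(float(ch.h.x_inf(v)) if ch.h is not None else 1.0)
    return np.array(m0), np.array(h0)


def simulate(
    net: NetworkSpec,
    stimuli: dict[int, np.ndarray] | None,
    duration_ms: float,
    dt_ms: float = 0.05,
    record_dt_ms: float = 1.0,
    v_init: float | np.ndarray = -60.0,
) -> Trace:
    """Integrate the network and return voltages (and clamp currents).

    ``stimuli`` maps cell index -> injected current (nA) sampled at
    ``dt_ms`` covering the whole run (shorter arrays are zero-padded).
    Clamped cells take their command from ``net.clamp`` (mV, same
    sampling).  Gates start at steady state for the initial voltage.
    The returned trace holds ``V_<cellname>`` channels (mV) and
    ``I_clamp_<cellname>`` (nA) for clamped cells, sampled every
    ``record_dt_ms``.
    """
    cap, chp, chc, ei, ej, eg = _pack_network(net)
    n = len(net.cells)
    nsteps = int(round(duration_ms / dt_ms))
    rec_every = max(int(round(record_dt_ms / dt_ms)), 1)

    v0 = np.full(n, v_init, dtype=float) if np.isscalar(v_init) else np.asarray(v_init, float).copy()
    clamped = np.zeros(n, dtype=np.bool_)
    cmd = np.zeros((n, nsteps + 1))
    for i, c in enumerate(net.clamp):
        if c is not None:
            clamped[i] = True
            cmd[i, : min(len(c), nsteps + 1)] = np.asarray(c, float)[: nsteps + 1]
            if len(c) < nsteps + 1:
                cmd[i, len(c):] = c[-1]
            v0[i] = cmd[i, 0]
    stim = np.zeros((n, nsteps + 1))
    for i, s in (stimuli or {}).items():
        s = np.asarray(s, dtype=float)
        stim[i, : min(len(s), nsteps + 1)] = s[: nsteps + 1]
        if len(s) < nsteps + 1:
            stim[i, len(s):] = s[-1]

    m0 = np.empty(chp.shape[0])
    h0 = np.empty(chp.shape[0])
    k = 0
    for ci, cell in enumerate(net.cells):
        mm, hh = steady_gates(cell, v0[ci])
        for j in range(len(cell.channels)):
            m0[k] = mm[j]
            h0[k] = hh[j]
            k += 1

    Vrec, Icl, _, _, bad = _rk4_run(
        cap, chp, chc, ei, ej, eg, clamped, cmd, stim, v0, m0, h0,
        dt_ms, nsteps, rec_every,
    )
    if bad >= 0:
        raise IntegrationError(f"non-finite state at t = {bad * dt_ms:.3f} ms")
    channels, units = {}, {}
    for i, cell in enumerate(net.cells):
        channels[f"V_{cell.name}"] = Vrec[i]
        units[f"V_{cell.name}"] = "mV"
        if clamped[i]:
            channels[f"I_clamp_{cell.name}"] = Icl[i]
            units[f"I_clamp_{cell.name}"] = "nA"
    return Trace(t0=0.0, dt=record_dt_ms / 1000.0, channels=channels, units=units)


def membrane_current(cell: CellSpec, v: float, m: np.ndarray, h: np.ndarray) -> float:
    """Total ionic current (nA) of a cell at state (v, gates)."""
    total = 0.0
    for ch, mm, hh in zip(cell.channels, m, h):
        gate = 1.0
        if ch.m is not None:
            gate *= mm ** ch.m.power
        if ch.h is not None:
            gate *= hh ** ch.h.power
        total += ch.g_max * 1e-3 * gate * (v - ch.e_rev)
    return total


def linearized_admittance(cell: CellSpec, v0: float, f: np.ndarray) -> np.ndarray:
    """Quasi-active membrane admittance (uS) linearized around v0 (mV).

    For each channel I = g*m^p*h^q*(V-E), the small-signal admittance at
    angular frequency w is the chord conductance plus one first-order
    term per gate:

        Y(w) = g0 + sum_x g*(d(m^p h^q)/dx)*(v0-E)*x_inf'(v0)/(1+i*w*tau_x(v0))

    evaluated at the steady state, plus i*w*C for the capacitance.
    """
    f = np.asarray(f, dtype=float)
    w = 2.0 * np.pi * f / 1000.0  # rad/ms
    y = 1j * w * cell.C
    for ch in cell.channels:
        g = ch.g_max * 1e-3
        m0 = float(ch.m.x_inf(v0)) if ch.m is not None else 1.0
        h0 = float(ch.h.x_inf(v0)) if ch.h is not None else 1.0
        p = ch.m.power if ch.m is not None else 0
        q = ch.h.power if ch.h is not None else 0
        y = y + g * (m0**p) * (h0**q)
        drive = v0 - ch.e_rev
        for gate, x0, pw, other in (
            (ch.m, m0, p, h0**q),
            (ch.h, h0, q, m0**p),
        ):
            if gate is None or pw == 0:
                continue
            # derivative of the logistic steady state
            dxinf = -x0 * (1.0 - x0) / gate.k
            coeff = g * pw * x0 ** (pw - 1) * other * drive * dxinf
            if gate.instantaneous:
                y = y + coeff
            else:
                tau = float(gate.tau(v0))
                y = y + coeff / (1.0 + 1j * w * tau)
    return y
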