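"""Ball-and-stick cable models: space-clamp errors in coupling estimates.

Two identical neurons, each a spherical soma plus a single neurite split
into many cylindrical (or linearly tapering) compartments, are joined by
a gap junction placed at the same compartment index of both neurites.
Both somas are ideally voltage clamped; one is stepped while the other is
held, and the apparent coupling conductance is the postjunctional clamp
current change divided by the step, Gc_app = I2/(V1 - Vhold).  Because
voltage control decays with electrotonic distance, Gc_app underestimates
the true junctional conductance increasingly with distance from the soma.

The passive problem is linear, so steady states come from a direct solve
of the nodal conductance network rather than time stepping.  The same
machinery evaluated with complex, frequency-dependent membrane
admittances (the quasi-active linearization of the resonant channel set)
yields the frequency profile of the apparent coupling conductance for
the resonant variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import CellSpec, ChannelSpec, linearized_admittance
from .errors import ValidationError


@dataclass(frozen=True)
class BallAndStickSpec:
    """Geometry and passive constants (lengths/diameters um, Rm Ohm*cm^2,
    Ra Ohm*cm, Cm uF/cm^2)."""

    soma_diameter: float = 100.0
    neurite_length: float = 1000.0
    n_compartments: int = 101
    geometry: str = "uniform"  # 'uniform' | 'taper'
    diameter: float = 10.0  # uniform cylinder diameter
    taper_from: float = 20.0
    taper_to: float = 0.5
    r_m: float = 10000.0
    r_a: float = 100.0
    c_m: float = 1.0
    channels: tuple[ChannelSpec, ...] | None = None  # resonant variant
    channel_ref_area_cm2: float = 2e-3  # area implied by the 2 nF reference cell

    def __post_init__(self) -> None:
        if self.n_compartments < 2:
            raise ValidationError("need at least 2 neurite compartments")
        if min(self.soma_diameter, self.neurite_length, self.r_m, self.r_a,
               self.c_m) <= 0:
            raise ValidationError("geometric and specific parameters must be positive")
        if self.geometry == "uniform":
            if self.diameter <= 0:
                raise ValidationError("diameter must be positive")
        elif self.geometry == "taper":
            if self.taper_from <= 0 or self.taper_to <= 0:
                raise ValidationError("taper diameters must be strictly positive")
        else:
            raise ValidationError("geometry must be 'uniform' or 'taper'")


@dataclass(frozen=True)
class CouplingPlacement:
    """Gap junction at a neurite compartment (0 = soma-adjacent) with
    junctional conductance in nS."""

    index: int
    gc_ns: float = 100.0

    def validate(self, spec: BallAndStickSpec) -> None:
        if not 0 <= self.index < spec.n_compartments:
            raise ValidationError("placement index outside the neurite")
        if self.gc_ns <= 0:
            raise ValidationError("junctional conductance must be positive")


class Cable:
    """Discretized single ball-and-stick neuron.

    Node 0 is the soma; nodes 1..n are neurite compartments centred at
    ``x_um``.  Membrane conductance/capacitance follow compartment areas
    (sphere surface for the soma, pi*d*l side area per segment) and the
    axial conductances between neighbouring midpoints use the frustum
    formula g = pi*d_a*d_b/(4*Ra*l), which reduces to the cylinder
    formula for equal diameters.  Units: uS, nF.
    """

    def __init__(self, spec: BallAndStickSpec):
        self.spec = spec
        n = spec.n_compartments
        um = 1e-4  # cm per um
        ell = spec.neurite_length / n  # um
        x_mid = (np.arange(n) + 0.5) * ell
        if spec.geometry == "uniform":
            diam = np.full(n, spec.diameter)
            d0 = spec.diameter  # diameter at the somatic end
        else:
            slope = (spec.taper_to - spec.taper_from) / spec.neurite_length
            diam = spec.taper_from + slope * x_mid
            d0 = spec.taper_from
        self.x_um = x_mid
        self.diam_um = diam
        area = np.empty(n + 1)  # cm^2
        area[0] = np.pi * (spec.soma_diameter * um) ** 2
        area[1:] = np.pi * diam * um * ell * um
        self.area_cm2 = area
        self.g_m = area / spec.r_m * 1e6  # uS (passive leak)
        self.c_nF = area * spec.c_m * 1e3  # uF/cm^2 * cm^2 -> uF -> *1e3 = nF
        # axial conductances: g_ax[i] joins node i and node i+1
        g_ax = np.empty(n)
        # soma to first midpoint: frustum over half a segment
        g_ax[0] = np.pi * (d0 * um) * (diam[0] * um) / (4.0 * spec.r_a * (ell / 2) * um) * 1e6
        for i in range(1, n):
            g_ax[i] = (np.pi * (diam[i - 1] * um) * (diam[i] * um)
                       / (4.0 * spec.r_a * ell * um) * 1e6)
        self.g_axial = g_ax

    def membrane_admittance(self, f: float) -> np.ndarray:
        """Per-node membrane admittance (uS, complex) at frequency f (Hz).

        Passive: g_m + i*w*C.  With a resonant channel set, the
        channels' quasi-active admittance (linearized at -60 mV, scaled
        by area relative to the reference cell) replaces the passive
        leak.
        """
        w = 2.0 * np.pi * f / 1000.0  # rad/ms
        if self.spec.channels is None:
            return self.g_m + 1j * w * self.c_nF
        ref = CellSpec(name="ref", C=1.0, channels=self.spec.channels)
        y_ref = linearized_admittance(ref, -60.0, np.array([f]))[0]
        # remove the reference capacitance term, keep channel admittance only
        y_ch = y_ref - 1j * w * 1.0
        scale = self.area_cm2 / self.spec.channel_ref_area_cm2
        return scale * y_ch + 1j * w * self.c_nF


def _pair_matrix(cable: Cable, placement: CouplingPlacement, f: float) -> np.ndarray:
    """Complex nodal admittance matrix of the coupled two-cell system."""
    n1 = cable.spec.n_compartments + 1
    ym = cable.membrane_admittance(f)
    g_ax = cable.g_axial
    N = 2 * n1
    Y = np.zeros((N, N), dtype=complex)
    for cell in range(2):
        off = cell * n1
        for i in range(n1):
            Y[off + i, off + i] += ym[i]
        for i in range(n1 - 1):
            a, b = off + i, off + i + 1
            g = g_ax[i]
            Y[a, a] += g
            Y[b, b] += g
            Y[a, b] -= g
            Y[b, a] -= g
    j = placement.index + 1  # node index of the junction compartment
    gj = placement.gc_ns * 1e-3
    a, b = j, n1 + j
    Y[a, a] += gj
    Y[b, b] += gj
    Y[a, b] -= gj
    Y[b, a] -= gj
    return Y


def apparent_gc(
    spec: BallAndStickSpec,
    placement: CouplingPlacement,
    f: float = 0.0,
) -> float:
    """Apparent junctional conductance (nS) seen by dual somatic clamp.

    Solves the (quasi-static at f = 0, quasi-active otherwise) nodal
    system with soma 1 stepped by a unit deviation and soma 2 held, and
    returns |I2| / dV1 -- the magnitude of the postjunctional clamp
    current change per unit prejunctional step.  The passive network is
    linear, so the step amplitude cancels.
    """
    placement.validate(spec)
    cable = Cable(spec)
    n1 = spec.n_compartments + 1
    Y = _pair_matrix(cable, placement, f)
    clamped = np.array([0, n1])
    v_clamped = np.array([1.0, 0.0], dtype=complex)
    free = np.setdiff1d(np.arange(2 * n1), clamped)
    Yff = Y[np.ix_(free, free)]
    Yfc = Y[np.ix_(free, clamped)]
    v_free = np.linalg.solve(Yff, -Yfc @ v_clamped)
    v = np.zeros(2 * n1, dtype=complex)
    v[clamped] = v_clamped
    v[free] = v_free
    # clamp current into soma 2 = sum of currents the amplifier must supply
    i2 = Y[n1, :] @ v
    return float(np.abs(i2)) * 1e3  # uS*mV per mV -> uS -> nS


def attenuation_curve(
    spec: BallAndStickSpec,
    placements: np.ndarray | list[int],
    gc_true_ns: float = 100.0,
) -> pd.DataFrame:
    """Apparent Gc against coupling position along the neurite.

    Returns a table with the placement index, its position (um), the
    apparent conductance and the attenuation ratio (true/apparent).
    """
    cable = Cable(spec)
    rows = []
    for idx in placements:
        pl = CouplingPlacement(index=int(idx), gc_ns=gc_true_ns)
        g = apparent_gc(spec, pl)
        rows.append(
            {
                "index": int(idx),
                "position_um": float(cable.x_um[int(idx)]),
                "apparent_gc_ns": g,
                "attenuation": gc_true_ns / g,
            }
        )
    return pd.DataFrame(rows)


def gc_frequency_profile(
    spec: BallAndStickSpec,
    placement: CouplingPlacement,
    f_grid: np.ndarray,
) -> pd.DataFrame:
    """|Gc_app|(f) for the (typically resonant-variant) coupled pair."""
    rows = [{"f_hz": float(f), "apparent_gc_ns": apparent_gc(spec, placement, f)}
            for f in np.asarray(f_grid, dtype=float)]
    return pd.DataFrame(rows)


def somatic_clamp_voltage_profile(spec: BallAndStickSpec, f: float = 0.0) -> np.ndarray:
    """Steady-state neurite voltage under a unit somatic clamp (one cell,
    no junction): the discrete counterpart of the sealed-end cable
    solution cosh((L-x)/lambda)/cosh(L/lambda)."""
    cable = Cable(spec)
    n1 = spec.n_compartments + 1
    ym = cable.membrane_admittance(f)
    Y = np.zeros((n1, n1), dtype=complex)
    for i in range(n1):
        Y[i, i] += ym[i]
    for i in range(n1 - 1):
        g = cable.g_axial[i]
        Y[i, i] += g
        Y[i + 1, i + 1] += g
        Y[i, i + 1] -= g
        Y[i + 1, i] -= g
    free = np.arange(1, n1)
    v_free = np.linalg.solve(Y[np.ix_(free, free)], -Y[free, 0] * 1.0)
    return np.abs(np.concatenate([[1.0], v_free]))
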