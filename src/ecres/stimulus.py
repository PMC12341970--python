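"""ZAP chirp and step command generation.

The ZAP (impedance amplitude profile) stimulus is a constant-amplitude
cosine whose instantaneous frequency sweeps exponentially from ``f_lo``
to ``f_hi`` over ``t_max`` seconds:

    s(t)   = offset + amplitude * cos(phase0 + phi(t))
    phi(t) = 2*pi*f_lo*(exp(L*t) - 1)/L,   L = log(f_hi/f_lo)/t_max

so the instantaneous frequency is ``f(t) = f_lo*exp(L*t)``.  The sweep is
preceded by ``n_precycles`` full cycles of a plain cosine at ``f_lo`` that
splice into the chirp with continuous phase and frequency, avoiding an
onset transient.  For voltage-clamp commands the convention is
``phase0 = pi`` so the command starts exactly at the holding potential
(offset - amplitude) with zero initial step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .trace import Trace


@dataclass(frozen=True)
class ZapParams:
    """Exponential-chirp parameters.

    Frequencies in Hz, times in seconds.  ``amplitude`` and ``offset``
    carry the unit of the generated command (nA for current commands,
    mV for voltage commands).
    """

    f_lo: float
    f_hi: float
    t_max: float
    amplitude: float
    offset: float = 0.0
    n_precycles: int = 2
    dt: float = 1e-4
    phase0: float = 0.0
    sweep: str = "up"  # 'up': f_lo -> f_hi; 'down': f_hi -> f_lo

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValidationError("require 0 < f_lo < f_hi")
        if self.t_max <= 0:
            raise ValidationError("t_max must be positive")
        if self.dt <= 0 or self.dt >= 1.0 / (2.0 * self.f_hi):
            raise ValidationError("dt must satisfy 0 < dt < 1/(2*f_hi)")
        if self.n_precycles < 0:
            raise ValidationError("n_precycles must be >= 0")
        if self.sweep not in ("up", "down"):
            raise ValidationError("sweep must be 'up' or 'down'")

    @property
    def sweep_rate(self) -> float:
        """Exponential sweep rate L = log(f_hi/f_lo)/t_max (1/s)."""
        return np.log(self.f_hi / self.f_lo) / self.t_max

    @property
    def f_start(self) -> float:
        """Instantaneous frequency at the start of the chirp."""
        return self.f_lo if self.sweep == "up" else self.f_hi

    @property
    def t_pre(self) -> float:
        """Duration of the lead-in sinusoid (s), cycled at the starting
        frequency of the sweep."""
        return self.n_precycles / self.f_start

    @property
    def t_total(self) -> float:
        return self.t_pre + self.t_max


def instantaneous_frequency(params: ZapParams, t: float | np.ndarray) -> np.ndarray:
    """Instantaneous frequency (Hz) at chirp-segment time ``t`` (s).

    ``t`` is measured from the start of the chirp proper (pre-cycles
    excluded); valid range ``0 <= t <= t_max``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > params.t_max + 1e-12):
        raise ValidationError("t outside the chirp segment [0, t_max]")
    if params.sweep == "up":
        return params.f_lo * np.exp(params.sweep_rate * t)
    return params.f_hi * np.exp(-params.sweep_rate * t)


def chirp_phase(params: ZapParams, t: float | np.ndarray) -> np.ndarray:
    """Accumulated chirp phase phi(t) (rad) at chirp-segment time ``t``."""
    t = np.asarray(t, dtype=float)
    L = params.sweep_rate
    if params.sweep == "up":
        return 2.0 * np.pi * params.f_lo * np.expm1(L * t) / L
    return -2.0 * np.pi * params.f_hi * np.expm1(-L * t) / L


def total_cycles(params: ZapParams) -> float:
    """Number of cycles in the chirp segment, phi(t_max)/(2*pi) = (f_hi-f_lo)/L."""
    return (params.f_hi - params.f_lo) / params.sweep_rate


def generate_zap(params: ZapParams, channel: str = "I", unit: str = "nA") -> Trace:
    """Generate the full command trace: pre-cycles followed by the chirp.

    The pre-cycle segment is ``offset + amplitude*cos(phase0 + 2*pi*f_lo*t)``;
    at ``t = t_pre`` its phase equals ``phase0 + 2*pi*n_precycles`` and the
    chirp continues from there, so both the value and the instantaneous
    frequency are continuous at the splice.
    """
    n = int(round(params.t_total / params.dt)) + 1
    t = params.dt * np.arange(n)
    phase = np.empty(n)
    pre = t < params.t_pre - 1e-12
    phase[pre] = 2.0 * np.pi * params.f_start * t[pre]
    phase[~pre] = 2.0 * np.pi * params.n_precycles + chirp_phase(
        params, np.minimum(t[~pre] - params.t_pre, params.t_max)
    )
    signal = params.offset + params.amplitude * np.cos(params.phase0 + phase)
    return Trace(t0=0.0, dt=params.dt, channels={channel: signal}, units={channel: unit})


def current_zap(
    i_max: float = 3.0,
    f_lo: float = 0.1,
    f_hi: float = 4.0,
    t_max: float = 100.0,
    n_precycles: int = 2,
    dt: float = 1e-4,
) -> ZapParams:
    """Current-clamp ZAP command spanning 0..i_max nA.

    The command rides on a depolarizing baseline (offset = amplitude =
    i_max/2) and starts at zero current (phase0 = pi), so the largest
    instantaneous current is ``i_max`` and the cell is only depolarized,
    matching a subthreshold protocol that drives the membrane from its
    holding potential upward.
    """
    return ZapParams(
        f_lo=f_lo,
        f_hi=f_hi,
        t_max=t_max,
        amplitude=i_max / 2.0,
        offset=i_max / 2.0,
        n_precycles=n_precycles,
        dt=dt,
        phase0=np.pi,
    )


def voltage_zap(
    v_from: float = -60.0,
    v_to: float = -30.0,
    f_lo: float = 0.1,
    f_hi: float = 4.0,
    t_max: float = 100.0,
    n_precycles: int = 2,
    dt: float = 1e-4,
) -> ZapParams:
    """Voltage-clamp ZAP command sweeping between v_from and v_to (mV).

    offset is the midpoint, amplitude the half-range, and phase0 = pi so
    the command starts exactly at ``v_from`` (the holding potential) with
    no step transient at clamp onset.
    """
    return ZapParams(
        f_lo=f_lo,
        f_hi=f_hi,
        t_max=t_max,
        amplitude=abs(v_to - v_from) / 2.0,
        offset=(v_from + v_to) / 2.0,
        n_precycles=n_precycles,
        dt=dt,
        phase0=np.pi if v_to > v_from else 0.0,
    )


def step_protocol(
    levels: np.ndarray,
    baseline: float,
    t_baseline: float = 2.0,
    t_step: float = 2.0,
    dt: float = 1e-4,
    channel: str = "V",
    unit: str = "mV",
) -> Trace:
    """Square-step command: baseline / step / baseline, repeated per level.

    Used for the classical coupling measurements where the coupling
    coefficient or conductance is the regression slope of per-step mean
    responses against per-step prejunctional voltage.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 1:
        raise ValidationError("at least one step level required")
    n_base = int(round(t_baseline / dt))
    n_step = int(round(t_step / dt))
    segs = [np.full(n_base, baseline)]
    for lev in levels:
        segs.append(np.full(n_step, lev))
        segs.append(np.full(n_base, baseline))
    sig = np.concatenate(segs)
    return Trace(t0=0.0, dt=dt, channels={channel: sig}, units={channel: unit})


def step_windows(
    n_levels: int, t_baseline: float = 2.0, t_step: float = 2.0, tail_frac: float = 0.5
) -> list[tuple[float, float]]:
    """Steady-state measurement windows (s) for each step of step_protocol.

    Each window is the final ``tail_frac`` of the step, where the response
    has settled, shrunk by a small margin so boundary samples of the
    neighbouring segments are excluded.
    """
    out = []
    margin = 0.005 * t_step
    for k in range(n_levels):
        start = t_baseline + k * (t_step + t_baseline)
        out.append((start + (1 - tail_frac) * t_step + margin, start + t_step - margin))
    return out
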