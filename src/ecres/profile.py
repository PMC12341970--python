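"""Frequency-profile estimation from chirp-driven recordings.

The measured quantities are magnitude ratios of Fourier transforms of
recorded channels (impedance Zpre = V_pre/I_pre, transfer impedance
Zpost = V_post/I_pre, coupling coefficient CC = V_post/V_pre, coupling
conductance Gc = I_post/V_pre), evaluated on the frequency band swept by
the ZAP stimulus.  Resonance is summarized by fitting a sixth-degree
polynomial to the amplitude profile and taking the peak of the fitted
curve on the closed band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, ValidationError
from .stimulus import ZapParams
from .trace import Trace

#: units of each ratio quantity
QUANTITY_UNITS = {"Zpre": "MOhm", "Zpost": "MOhm", "Zk": "MOhm", "CC": "", "Gc": "uS"}


@dataclass
class FrequencyProfile:
    f: np.ndarray
    amplitude: np.ndarray  # NaN marks masked points
    quantity: str = "Zpre"
    unit: str = "MOhm"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.f.shape != self.amplitude.shape:
            raise ValidationError("frequency grid and amplitudes differ in length")
        if np.any(np.diff(self.f) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        good = np.isfinite(self.amplitude)
        if np.any(self.amplitude[good] < 0):
            raise ValidationError("amplitudes must be nonnegative")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.amplitude).sum())


@dataclass
class ResonanceSummary:
    f_res: float
    peak: float
    amp_at_f_lo: float
    coeffs: np.ndarray = field(repr=False)
    residual: float = 0.0
    at_edge: bool = False  # True: no interior resonance (peak on a band edge)

    def as_dict(self) -> dict:
        return {
            "f_res_hz": float(self.f_res),
            "peak": float(self.peak),
            "amp_at_f_lo": float(self.amp_at_f_lo),
            "residual": float(self.residual),
            "no_interior_resonance": bool(self.at_edge),
        }


def chirp_segment(trace: Trace, zap: ZapParams, t_start: float | None = None) -> Trace:
    """Cut the analysis segment out of a recording (pre-cycles excluded).

    ``t_start`` is the absolute time at which the stimulus (pre-cycles)
    began; defaults to the trace start.  The lead-in sinusoid exists to
    shed transients and carries energy only at f_lo, so it is dropped.
    The segment runs from chirp onset to the end of the recording: any
    post-stimulus samples present capture the response ring-down, which
    keeps the DFT ratio accurate up to the top of the band.
    """
    if t_start is None:
        t_start = trace.t0
    return trace.slice_time(t_start + zap.t_pre, trace.t0 + trace.duration)


def spectral_ratio(
    trace: Trace,
    numerator: str,
    denominator: str,
    band: tuple[float, float] = (0.1, 4.0),
    quantity: str = "Zpre",
    smooth_bw: float = 0.05,
    den_floor_rel: float = 1e-6,
) -> FrequencyProfile:
    """Magnitude of the DFT ratio of two channels, restricted to the band.

    Both channels have their mean removed, the full-segment discrete
    Fourier transforms are taken, and the ratio is evaluated on the rFFT
    grid inside [band].  Chirps concentrate their energy along the sweep,
    so the plain DFT ratio is well conditioned there.  Grid points where
    the denominator magnitude falls below ``den_floor_rel`` times its
    band maximum are masked (NaN) with a warning.  A moving-average
    smoothing over a ``smooth_bw`` Hz window is applied to the ratio
    before it is returned; pass 0 to disable.
    """
    if numerator not in trace.channels or denominator not in trace.channels:
        raise ValidationError("trace lacks the requested channels")
    x = trace[numerator] - trace[numerator].mean()
    y = trace[denominator] - trace[denominator].mean()
    n = x.size
    freqs = np.fft.rfftfreq(n, d=trace.dt)
    sel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    if not np.any(sel):
        raise ValidationError("no FFT grid points inside the band")
    num = np.abs(np.fft.rfft(x))[sel]
    den = np.abs(np.fft.rfft(y))[sel]
    floor = den_floor_rel * den.max()
    bad = den <= floor
    ratio = np.full(num.shape, np.nan)
    ratio[~bad] = num[~bad] / den[~bad]
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} grid points masked: denominator below spectral floor",
            RuntimeWarning,
            stacklevel=2,
        )
    f = freqs[sel]
    if smooth_bw > 0:
        ratio = _nan_moving_average(f, ratio, smooth_bw)
    unit = QUANTITY_UNITS.get(quantity, "")
    return FrequencyProfile(f=f, amplitude=ratio, quantity=quantity, unit=unit)


def _nan_moving_average(f: np.ndarray, y: np.ndarray, bw: float) -> np.ndarray:
    """Moving average over a window of width bw (Hz), NaN-aware."""
    df = np.median(np.diff(f))
    half = max(int(round(bw / (2 * df))), 0)
    if half == 0:
        return y
    out = np.full_like(y, np.nan)
    ok = np.isfinite(y)
    yz = np.where(ok, y, 0.0)
    kernel = np.ones(2 * half + 1)
    s = np.convolve(yz, kernel, mode="same")
    c = np.convolve(ok.astype(float), kernel, mode="same")
    nz = c > 0
    out[nz] = s[nz] / c[nz]
    out[~ok] = np.nan  # keep masked points masked
    return out


def fit_resonance(profile: FrequencyProfile, degree: int = 6) -> ResonanceSummary:
    """Polynomial peak fit of an amplitude profile.

    A least-squares polynomial of the given degree in f (linear Hz grid)
    is fitted to the unmasked amplitudes; the resonance frequency and
    amplitude are the location and value of the global maximum of the
    fitted curve on the closed band (endpoints admissible, found from the
    real roots of the derivative).  The fitted value at the lowest band
    frequency is recorded as the proxy for the zero-frequency response,
    used for normalization.  A peak on a band endpoint is flagged as "no
    interior resonance".
    """
    ok = np.isfinite(profile.amplitude)
    if ok.sum() < degree + 2:
        raise FitError(f"need at least {degree + 2} unmasked points, have {int(ok.sum())}")
    f, a = profile.f[ok], profile.amplitude[ok]
    poly = np.polynomial.Polynomial.fit(f, a, deg=degree)
    resid = float(np.sqrt(np.mean((poly(f) - a) ** 2)))
    lo, hi = profile.f[0], profile.f[-1]
    crit = [lo, hi]
    for r in poly.deriv().roots():
        if abs(r.imag) < 1e-9 and lo < r.real < hi:
            crit.append(float(r.real))
    crit = np.array(sorted(crit))
    vals = poly(crit)
    best = int(np.argmax(vals))  # ties break toward lower frequency (sorted)
    f_res, peak = float(crit[best]), float(vals[best])
    at_edge = best == 0 or f_res >= hi * (1 - 1e-9)
    return ResonanceSummary(
        f_res=f_res,
        peak=peak,
        amp_at_f_lo=float(poly(lo)),
        coeffs=poly.convert().coef,
        residual=resid,
        at_edge=at_edge,
    )


def normalize_profile(profile: FrequencyProfile) -> FrequencyProfile:
    """Divide the profile by its amplitude at the lowest band frequency.

    The value at the lowest swept frequency stands in for the
    zero-frequency response, so the normalized profile reads as resonance
    power.  Idempotent: normalizing twice equals normalizing once.
    """
    if profile.normalized:
        return FrequencyProfile(
            f=profile.f.copy(),
            amplitude=profile.amplitude.copy(),
            quantity=profile.quantity,
            unit="",
            normalized=True,
        )
    base = profile.amplitude[0]
    if not np.isfinite(base) or base <= 0:
        raise ValidationError("lowest-frequency amplitude is zero or masked")
    return FrequencyProfile(
        f=profile.f.copy(),
        amplitude=profile.amplitude / base,
        quantity=profile.quantity,
        unit="",
        normalized=True,
    )


def step_coupling_estimate(
    trace: Trace,
    mode: str,
    windows: list[tuple[float, float]],
    pre_channel: str = "V_pre",
) -> float:
    """Classical step estimate of CC (current clamp) or Gc (voltage clamp).

    Per-step steady-state means of the response channel are regressed
    (ordinary least squares) on the per-step means of the prejunctional
    voltage.  In current clamp the slope of V_post against V_pre is the
    coupling coefficient.  In voltage clamp the response is the
    postjunctional clamp current; with the amplifier-current sign
    convention used throughout (positive clamp current opposes
    depolarizing junctional inflow) the slope is -Gc, so its negative is
    returned and a conventional junction yields a positive value.
    """
    if mode not in ("currentclamp", "voltageclamp"):
        raise ValidationError("mode must be 'currentclamp' or 'voltageclamp'")
    if len(windows) < 3:
        raise ValidationError("at least 3 steps are required")
    resp_channel = "V_post" if mode == "currentclamp" else "I_post"
    t = trace.time()
    xs, ys = [], []
    for w0, w1 in windows:
        sel = (t >= w0) & (t <= w1)
        if not np.any(sel):
            raise ValidationError(f"empty steady-state window ({w0}, {w1})")
        xs.append(trace[pre_channel][sel].mean())
        ys.append(trace[resp_channel][sel].mean())
    slope = np.polyfit(np.asarray(xs), np.asarray(ys), 1)[0]
    return float(slope) if mode == "currentclamp" else float(-slope)


def coupling_profiles(
    trace: Trace,
    zap: ZapParams,
    mode: str = "currentclamp",
    band: tuple[float, float] | None = None,
    t_stim_start: float | None = None,
    smooth_bw: float = 0.05,
) -> dict[str, FrequencyProfile]:
    """All ratio profiles a dual recording supports under the given protocol.

    Current clamp (ZAP current into the prejunctional cell): Zpre, Zpost
    and CC.  Voltage clamp (ZAP command on V_pre, V_post held): Zpre
    (from I_pre) and Gc (from I_post).
    """
    band = band or (zap.f_lo, zap.f_hi)
    seg = chirp_segment(trace, zap, t_stim_start)
    out: dict[str, FrequencyProfile] = {}
    if mode == "currentclamp":
        for q, num, den in (
            ("Zpre", "V_pre", "I_pre"),
            ("Zpost", "V_post", "I_pre"),
            ("CC", "V_post", "V_pre"),
        ):
            out[q] = spectral_ratio(seg, num, den, band, quantity=q, smooth_bw=smooth_bw)
    elif mode == "voltageclamp":
        for q, num, den in (("Zpre", "V_pre", "I_pre"), ("Gc", "I_post", "V_pre")):
            out[q] = spectral_ratio(seg, num, den, band, quantity=q, smooth_bw=smooth_bw)
    else:
        raise ValidationError("mode must be 'currentclamp' or 'voltageclamp'")
    return out
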