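"""Trace, profile and summary serialization.

Two neutral trace containers are supported:

* CSV: header ``time:s,<name>:<unit>,...``, one row per sample, values
  written with 10 significant digits (round trip exact to that printed
  precision).  Channel order is irrelevant on read; the time base must be
  uniform.
* NPZ (the documented binary container): a NumPy ``.npz`` archive with
  keys ``t0`` (scalar, s), ``dt`` (scalar, s), ``names`` (channel names),
  ``units`` (unit per channel) and ``data`` (channels x samples, float64).
  Round trips are bitwise exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceFormatError
from .profile import FrequencyProfile, ResonanceSummary
from .trace import Trace


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    df = trace.to_dataframe()
    df.to_csv(path, index=False, float_format="%.10g")


def read_trace_csv(path: str | Path) -> Trace:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TraceFormatError(f"{path}: need a time column plus at least one channel")
    tcol = df.columns[0]
    if not tcol.startswith("time"):
        raise TraceFormatError(f"{path}: first column must be time, got {tcol!r} (line 1)")
    t = df[tcol].to_numpy(dtype=float)
    dts = np.diff(t)
    if t.size < 2:
        raise TraceFormatError(f"{path}: need at least two samples")
    dt = float(np.median(dts))
    bad = np.flatnonzero(np.abs(dts - dt) > 1e-6 * max(dt, 1e-12))
    if bad.size:
        raise TraceFormatError(
            f"{path}: non-uniform time base at data line {bad[0] + 2}"
        )
    channels, units = {}, {}
    for col in df.columns[1:]:
        if ":" not in col:
            raise TraceFormatError(
                f"{path}: channel column {col!r} lacks a ':unit' suffix (line 1)"
            )
        name, unit = col.rsplit(":", 1)
        channels[name] = df[col].to_numpy(dtype=float)
        units[name] = unit
    return Trace(t0=float(t[0]), dt=dt, channels=channels, units=units)


def write_trace_npz(trace: Trace, path: str | Path) -> None:
    names = list(trace.channels)
    data = np.vstack([trace.channels[n] for n in names]) if names else np.zeros((0, 0))
    np.savez(
        path,
        t0=np.float64(trace.t0),
        dt=np.float64(trace.dt),
        names=np.array(names),
        units=np.array([trace.units[n] for n in names]),
        data=data,
    )


def read_trace_npz(path: str | Path) -> Trace:
    with np.load(path, allow_pickle=False) as z:
        try:
            names = [str(n) for n in z["names"]]
            units = [str(u) for u in z["units"]]
            data = z["data"]
            t0, dt = float(z["t0"]), float(z["dt"])
        except KeyError as e:
            raise TraceFormatError(f"{path}: missing container key {e}") from e
    return Trace(
        t0=t0,
        dt=dt,
        channels={n: data[i].copy() for i, n in enumerate(names)},
        units=dict(zip(names, units)),
    )


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        write_trace_csv(trace, path)
    elif path.suffix == ".npz":
        write_trace_npz(trace, path)
    else:
        raise TraceFormatError(f"unsupported trace format {path.suffix!r}")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    if path.suffix == ".csv":
        return read_trace_csv(path)
    if path.suffix == ".npz":
        return read_trace_npz(path)
    raise TraceFormatError(f"unsupported trace format {path.suffix!r}")


def write_profile_csv(profile: FrequencyProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency:Hz": profile.f,
            f"amplitude:{profile.unit or 'dimensionless'}": profile.amplitude,
            "quantity": profile.quantity,
            "normalized": profile.normalized,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_profile_csv(path: str | Path) -> FrequencyProfile:
    df = pd.read_csv(path)
    amp_col = [c for c in df.columns if c.startswith("amplitude")]
    if "frequency:Hz" not in df.columns or not amp_col:
        raise TraceFormatError(f"{path}: not a profile table")
    unit = amp_col[0].split(":", 1)[1]
    return FrequencyProfile(
        f=df["frequency:Hz"].to_numpy(float),
        amplitude=df[amp_col[0]].to_numpy(float),
        quantity=str(df["quantity"].iloc[0]),
        unit="" if unit == "dimensionless" else unit,
        normalized=bool(df["normalized"].iloc[0]),
    )


def write_summary_json(summary: ResonanceSummary | dict, path: str | Path) -> None:
    payload = summary.as_dict() if isinstance(summary, ResonanceSummary) else summary
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
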