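"""Uniformly sampled multi-channel time series.

A :class:`Trace` is the common currency between stimulus generation,
simulation and profile estimation: a shared time base (start time ``t0``
and sample interval ``dt``, both in seconds) plus named channels, each
carrying a unit string (``mV``, ``nA`` or ``nS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TraceFormatError, ValidationError


@dataclass
class Trace:
    t0: float
    dt: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        n = None
        for name, data in list(self.channels.items()):
            arr = np.asarray(data, dtype=float)
            self.channels[name] = arr
            if arr.ndim != 1:
                raise TraceFormatError(f"channel {name!r} is not 1-D")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise TraceFormatError(
                    f"channel {name!r} has {arr.size} samples, expected {n}"
                )
            if name not in self.units:
                raise TraceFormatError(f"channel {name!r} has no declared unit")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return next(iter(self.channels.values())).size

    def __len__(self) -> int:
        return self.n_samples

    @property
    def duration(self) -> float:
        """Total spanned time in seconds."""
        return (self.n_samples - 1) * self.dt if self.n_samples else 0.0

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.n_samples)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def add_channel(self, name: str, data: np.ndarray, unit: str) -> None:
        arr = np.asarray(data, dtype=float)
        if self.channels and arr.size != self.n_samples:
            raise TraceFormatError(
                f"channel {name!r} has {arr.size} samples, expected {self.n_samples}"
            )
        self.channels[name] = arr
        self.units[name] = unit

    def slice_time(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace covering [t_start, t_end] (absolute seconds, inclusive)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) / self.dt - 1e-9)))
        i1 = min(self.n_samples - 1, int(np.floor((t_end - self.t0) / self.dt + 1e-9)))
        if i1 < i0:
            raise ValidationError("slice window is empty")
        return Trace(
            t0=self.t0 + i0 * self.dt,
            dt=self.dt,
            channels={k: v[i0 : i1 + 1].copy() for k, v in self.channels.items()},
            units=dict(self.units),
        )

    def to_dataframe(self):
        import pandas as pd

        cols = {"time:s": self.time()}
        for name, data in self.channels.items():
            cols[f"{name}:{self.units[name]}"] = data
        return pd.DataFrame(cols)
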