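"""Uniformly sampled periodic signals (flow, pressure, area).

A :class:`Waveform` holds one cardiac cycle on a uniform time grid starting
at 0 with the last sample strictly before the period ``T``; the signal is
understood as periodic, ``v(t + T) = v(t)``.  Cycle statistics (mean,
extrema, integrals) close the period with the first sample, i.e. integrate
over the half-open cycle using the trapezoidal rule on ``[0, T]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Waveform:
    t: np.ndarray
    v: np.ndarray
    T: float
    units: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("waveform needs at least two samples")
        dt = np.diff(self.t)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("sample spacing must be uniform")
        if abs(self.t[0]) > 1e-12:
            raise ValueError("time base must start at 0")
        if not self.t[-1] < self.T:
            raise ValueError("last sample must fall strictly before the period T")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("waveform values must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return int(self.t.size)

    def _closed(self) -> tuple[np.ndarray, np.ndarray]:
        """Time/value arrays with the cycle closed by the periodic image."""
        t = np.append(self.t, self.T)
        v = np.append(self.v, self.v[0])
        return t, v

    def cycle_integral(self) -> float:
        t, v = self._closed()
        return float(np.trapezoid(v, t))

    def cycle_mean(self) -> float:
        return self.cycle_integral() / self.T

    def cycle_max(self) -> float:
        return float(np.max(self.v))

    def cycle_min(self) -> float:
        return float(np.min(self.v))

    def pulse(self) -> float:
        """Peak-to-trough amplitude over the cycle."""
        return self.cycle_max() - self.cycle_min()

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Periodic linear interpolation at arbitrary times."""
        tt = np.mod(np.asarray(t, dtype=float), self.T)
        tc, vc = self._closed()
        out = np.interp(tt, tc, vc)
        return float(out) if np.isscalar(t) else out

    def resampled(self, dt: float) -> "Waveform":
        """Resample on a uniform grid with spacing ``dt`` (must divide T)."""
        n = round(self.T / dt)
        if abs(n * dt - self.T) > 1e-9 * self.T:
            raise ValueError(f"dt={dt} does not divide the period T={self.T}")
        t = np.arange(n) * dt
        return Waveform(t, np.asarray(self(t)), self.T, units=self.units)

    def shifted(self, tau: float) -> "Waveform":
        """Circularly time-shift by ``tau`` (positive = delay)."""
        return Waveform(self.t, np.asarray(self(self.t - tau)), self.T, units=self.units)

    def scaled(self, k: float) -> "Waveform":
        return Waveform(self.t, self.v * k, self.T, units=self.units)

    def __add__(self, other: "Waveform") -> "Waveform":
        self._check_common_base(other)
        return Waveform(self.t, self.v + other.v, self.T, units=self.units)

    def __sub__(self, other: "Waveform") -> "Waveform":
        self._check_common_base(other)
        return Waveform(self.t, self.v - other.v, self.T, units=self.units)

    def _check_common_base(self, other: "Waveform") -> None:
        if abs(self.T - other.T) > 1e-9 * self.T or self.n != other.n:
            raise ValueError("waveforms do not share a common time base")


def from_samples(v: np.ndarray, T: float, units: str = "") -> Waveform:
    """Build a waveform from ``n`` samples evenly spanning one period."""
    v = np.asarray(v, dtype=float)
    t = np.arange(v.size) * (T / v.size)
    return Waveform(t, v, T, units=units)


def read_waveform_csv(path, period: float | None = None) -> Waveform:
    """Read a two-column ``time_s,value`` CSV into a Waveform.

    The period defaults to ``last time + spacing`` (one sample past the end
    of the file closes the cycle).
    """
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    if len(cols) < 2 or cols[0] != "time_s":
        raise ValueError(f"{path}: expected header 'time_s,value'")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~(np.isfinite(t) & np.isfinite(v)))[0]) + 2
        raise ValueError(f"{path}: non-finite value at line {bad}")
    d = np.diff(t)
    if np.any(d <= 0):
        bad = int(np.flatnonzero(d <= 0)[0]) + 2  # +2: header + 1-based
        raise ValueError(f"{path}: time not strictly increasing at line {bad + 1}")
    if period is None:
        period = float(t[-1] + (t[1] - t[0]))
    return Waveform(t, v, period)


def write_waveform_csv(wf: Waveform, path) -> None:
    df = pd.DataFrame({"time_s": wf.t, "value": wf.v})
    df.to_csv(path, index=False, float_format="%.17g")
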