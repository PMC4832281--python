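"""Calcium signature synthesis and trace I/O.

A calcium signature is a clamped cytosolic free-Ca2+ time course, represented
here as a :class:`CalciumTrace` (seconds vs micromolar).  Signatures are either
square-wave ("piecewise") reconstructions that preserve a measured signature's
summary statistics (average, maximum, minimum, period, duration), or smooth
synthetic stand-ins for the three experimentally observed signature classes:
an oscillatory spike train, a single transient, and a prolonged plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CalciumTrace",
    "PiecewiseSpec",
    "dwell_times",
    "make_piecewise",
    "make_synthetic",
    "read_trace",
    "write_trace",
]


@dataclass(frozen=True)
class CalciumTrace:
    """A clamped Ca2+ input signal on a time grid.

    Times are in seconds and non-decreasing (duplicated time points are
    allowed and mark square-wave discontinuities); values are concentrations
    in uM and non-negative.  Between samples the signal is linearly
    interpolated; beyond the ends it is clamped to the end values.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(v < 0):
            raise ValueError("negative calcium concentration in trace")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def __call__(self, t):
        """Interpolated Ca2+ (uM) at time(s) ``t``, clamped beyond the ends."""
        return np.interp(t, self.times, self.values)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def discontinuities(self) -> np.ndarray:
        """Times where the trace jumps (duplicated time points)."""
        dup = self.times[1:] == self.times[:-1]
        return np.unique(self.times[1:][dup])

    def time_average(self, t0: float | None = None, t1: float | None = None) -> float:
        """Trapezoidal time average of the trace over [t0, t1]."""
        t0 = self.times[0] if t0 is None else t0
        t1 = self.times[-1] if t1 is None else t1
        mask = (self.times >= t0) & (self.times <= t1)
        t = self.times[mask]
        v = self.values[mask]
        if t.size < 2 or t1 <= t0:
            return float(self(t0))
        return float(np.trapezoid(v, t) / (t[-1] - t[0]))


@dataclass(frozen=True)
class PiecewiseSpec:
    """Parameters of a square-wave calcium signature.

    The wave alternates ``t_max`` seconds at ``ca_max`` with ``t_min`` seconds
    at ``ca_min`` so that its period average equals ``average``:

        average = (t_max * ca_max + t_min * ca_min) / T,   T = t_max + t_min.

    ``onset``/``duration`` position the oscillatory window inside a trace that
    is otherwise held at ``baseline`` (defaults to ``ca_min``, the resting
    level).
    """

    average: float = 0.16
    ca_max: float = 0.52
    ca_min: float = 0.10
    period: float = 40.0
    duration: float = 400.0
    onset: float = 0.0
    baseline: float | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if not (self.ca_min <= self.average <= self.ca_max):
            raise ValueError("average must lie between ca_min and ca_max")
        if self.baseline is None:
            object.__setattr__(self, "baseline", self.ca_min)
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")

    @property
    def t_max(self) -> float:
        return dwell_times(self.average, self.ca_max, self.ca_min, self.period)[0]

    @property
    def t_min(self) -> float:
        return dwell_times(self.average, self.ca_max, self.ca_min, self.period)[1]

    @property
    def n_spikes(self) -> int:
        return int(round(self.duration / self.period))


def dwell_times(average: float, ca_max: float, ca_min: float, period: float):
    """Dwell times (t_max, t_min) of the square wave with the given average.

    Inverts ``average = (t_max*ca_max + t_min*ca_min)/T`` with
    ``T = t_max + t_min``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if ca_min > ca_max:
        raise ValueError("ca_min must not exceed ca_max")
    if ca_min == ca_max:
        if average != ca_max:
            raise ValueError("degenerate spec: ca_min == ca_max != average")
        return period, 0.0
    if not (ca_min <= average <= ca_max):
        raise ValueError("average must lie between ca_min and ca_max")
    t_max = period * (average - ca_min) / (ca_max - ca_min)
    return t_max, period - t_max


def make_piecewise(spec: PiecewiseSpec, dt: float = 0.1, tail: float = 0.0) -> CalciumTrace:
    """Sample a square-wave signature as a :class:`CalciumTrace`.

    Discontinuities are emitted as double points so linear interpolation
    reproduces the square wave exactly.  Each cycle starts with the high
    phase.  ``tail`` extends the trace at baseline beyond the signature end.
    """
    t_hi, t_lo = dwell_times(spec.average, spec.ca_max, spec.ca_min, spec.period)
    n_cycles = spec.duration / spec.period
    n_full = int(np.floor(n_cycles + 1e-9))
    if abs(n_cycles - n_full) > 1e-9:
        warnings.warn(
            f"duration {spec.duration} s is not a multiple of the period "
            f"{spec.period} s; truncating to {n_full} whole cycles",
            stacklevel=2,
        )
    times: list[float] = []
    values: list[float] = []

    def seg(t0: float, t1: float, level: float) -> None:
        # closed segment with double points at both ends
        if t1 <= t0:
            return
        n = max(int(np.ceil((t1 - t0) / dt)), 1)
        ts = np.linspace(t0, t1, n + 1)
        times.extend(ts)
        values.extend([level] * ts.size)

    if spec.onset > 0:
        seg(0.0, spec.onset, spec.baseline)
    t = spec.onset
    for _ in range(n_full):
        seg(t, t + t_hi, spec.ca_max)
        seg(t + t_hi, t + t_hi + t_lo, spec.ca_min)
        t += spec.period
    if tail > 0:
        seg(t, t + tail, spec.baseline)
    return CalciumTrace(np.array(times), np.array(values))


def _oscillatory(peak, rest, period, n_spikes, dt):
    """Smooth spike train: raised-cosine spikes of width period/2."""
    total = n_spikes * period
    t = np.arange(0.0, total + dt / 2, dt)
    phase = np.mod(t, period)
    width = period / 2.0
    shape = np.where(phase < width, 0.5 * (1 - np.cos(2 * np.pi * phase / width)), 0.0)
    return t, rest + (peak - rest) * shape

def _transient(peak, baseline, rise, decay, total, dt):
    """Single spike: linear rise then exponential decay back to baseline."""
    t = np.arange(0.0, total + dt / 2, dt)
    v = np.where(
        t < rise,
        baseline + (peak - baseline) * t / rise,
        baseline + (peak - baseline) * np.exp(-(t - rise) / decay),
    )
    return t, v

def _prolonged(plateau, baseline, rise, duration, dt):
    """Slow sigmoidal rise to a plateau held for the stated duration."""
    total = rise + duration
    t = np.arange(0.0, total + dt / 2, dt)
    ramp = np.clip(t / rise, 0.0, 1.0)
    v = baseline + (plateau - baseline) * (3 * ramp**2 - 2 * ramp**3)
    return t, v


def make_synthetic(
    kind: str,
    *,
    peak: float = 0.52,
    rest: float = 0.10,
    period: float = 40.0,
    n_spikes: int = 10,
    rise: float = 20.0,
    decay: float = 60.0,
    total: float = 400.0,
    plateau: float = 0.32,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 0.1,
) -> CalciumTrace:
    """Generate a smooth stand-in for one of the three signature classes.

    Parameters not used by the requested ``kind`` are ignored.  Optional
    additive Gaussian measurement noise (``noise_sd`` uM) is reproducible via
    ``seed``; noisy values are clipped at zero.
    """
    if kind == "oscillatory":
        t, v = _oscillatory(peak, rest, period, n_spikes, dt)
    elif kind == "transient":
        t, v = _transient(peak, rest, rise, decay, total, dt)
    elif kind == "prolonged":
        t, v = _prolonged(plateau, rest, rise, total, dt)
    else:
        raise ValueError(f"unknown signature class {kind!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = np.clip(v + rng.normal(0.0, noise_sd, v.size), 0.0, None)
    return CalciumTrace(t, v)


def write_trace(trace: CalciumTrace, path) -> None:
    """Write a trace as delimited text with columns ``time_s`` and ``ca_um``."""
    arr = np.column_stack([trace.times, trace.values])
    np.savetxt(path, arr, fmt="%.17g", delimiter="\t", header="time_s\tca_um", comments="")


def read_trace(path) -> CalciumTrace:
    """Read a two-column (time_s, ca_um) text trace; header row optional."""
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                t, v = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}: malformed row {lineno}: {line!r}") from None
            if times and t < times[-1]:
                raise ValueError(f"{path}: time goes backwards at row {lineno}")
            if v < 0:
                raise ValueError(f"{path}: negative concentration at row {lineno}")
            times.append(t)
            values.append(v)
    if not times:
        raise ValueError(f"{path}: empty trace file")
    return CalciumTrace(np.array(times), np.array(values))
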