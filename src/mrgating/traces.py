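"""Synthetic respiratory motion traces for a programmable motion phantom.

Regular breathing is modelled as ``z(t) = A * sin(pi*t/T)**(2p)`` — a raised
cosine-power waveform with the exhale baseline at 0 mm and the inhale peak at
the amplitude ``A``.  With ``p = 3`` this is the familiar cos^6 respiratory
model.  Irregular breathing concatenates cycles whose rate, amplitude and
waveform power are re-drawn independently every cycle, which reproduces the
cycle-to-cycle variability of self-paced breathing while keeping the trace
continuous (every cycle starts and ends at the 0 mm rest position).

A rotational arm on the phantom couples the longitudinal drive into lateral
and vertical target motion: the drive angle is a linear map of the
longitudinal position onto ``[-rotation_max, +rotation_max]`` and the target
sits ``target_offset`` mm off the rotation axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "IrregularSpec",
    "KinematicsConfig",
    "generate_regular_trace",
    "generate_irregular_trace",
    "apply_kinematics",
    "cycle_table",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass
class MotionTrace:
    """Time-stamped target displacement, 1D (z only) or 3D.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, uniform step ``1/fs`` starting at 0.
    z : ndarray
        Longitudinal displacement in mm (0 = exhale rest position).
    x, y : ndarray or None
        Lateral / vertical displacement in mm, present after the kinematic
        coupling has been applied.
    fs : float
        Sampling rate in Hz.
    meta : dict
        Provenance: nominal rate (BPM), nominal amplitude (mm), waveform
        label, and for irregular traces the per-cycle parameter draws.
    """

    t: np.ndarray
    z: np.ndarray
    fs: float
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.z.shape != self.t.shape:
            raise ValueError("z and t must have the same length")
        for name in ("x", "y"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.t.shape:
                    raise ValueError(f"{name} and t must have the same length")
                setattr(self, name, v)

    @property
    def duration(self) -> float:
        """Trace duration in seconds, ``(n - 1) / fs``."""
        return (len(self.t) - 1) / self.fs

    @property
    def is_3d(self) -> bool:
        return self.x is not None and self.y is not None

    def positions(self) -> np.ndarray:
        """(n, 3) array of [x, y, z]; x and y are zero for 1D traces."""
        x = self.x if self.x is not None else np.zeros_like(self.z)
        y = self.y if self.y is not None else np.zeros_like(self.z)
        return np.column_stack([x, y, self.z])

    def interp_positions(self, times: np.ndarray) -> np.ndarray:
        """Linearly interpolate [x, y, z] at arbitrary times (n, 3)."""
        pos = self.positions()
        out = np.empty((len(times), 3))
        for i in range(3):
            out[:, i] = np.interp(times, self.t, pos[:, i])
        return out


@dataclass(frozen=True)
class IrregularSpec:
    """Per-cycle parameter distributions for an irregular breathing trace."""

    rate_range: tuple[float, float] = (10.0, 14.0)
    amplitude_range: tuple[float, float] = (26.0, 30.0)
    waveform_powers: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_range[0] > self.rate_range[1]:
            raise ValueError("rate_range must satisfy low <= high")
        if self.amplitude_range[0] > self.amplitude_range[1]:
            raise ValueError("amplitude_range must satisfy low <= high")
        if len(self.waveform_powers) == 0:
            raise ValueError("waveform_powers must be non-empty")
        if any(p < 1 for p in self.waveform_powers):
            raise ValueError("waveform powers must be >= 1")


@dataclass(frozen=True)
class KinematicsConfig:
    """Rotational coupling of the longitudinal drive into x/y motion.

    ``rotation_max`` degrees of arm rotation (±) are spanned linearly over
    ``amplitude_ref`` mm of longitudinal travel; the target is mounted
    ``target_offset`` mm off the rotation axis.
    """

    rotation_max: float = 30.0
    target_offset: float = 15.0
    amplitude_ref: float = 30.0

    def __post_init__(self) -> None:
        if self.target_offset < 0:
            raise ValueError("target_offset must be >= 0")
        if not (0 < self.rotation_max <= 90):
            raise ValueError("rotation_max must lie in (0, 90] degrees")


def _waveform(t_local: np.ndarray, period_s: float, amplitude: float, power: int) -> np.ndarray:
    return amplitude * np.sin(np.pi * t_local / period_s) ** (2 * power)


def generate_regular_trace(
    rate_bpm: float,
    amplitude_mm: float,
    power: int = 3,
    duration_s: float = 120.0,
    fs: float = 100.0,
) -> MotionTrace:
    """Regular breathing trace ``z(t) = A sin^{2p}(pi t / T)``, T = 60/rate.

    The exhale baseline sits at 0 mm and the inhale peak at ``amplitude_mm``;
    cycle boundaries (z = 0) occur every ``T`` seconds.
    """
    if rate_bpm <= 0:
        raise ValueError("rate_bpm must be positive")
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if power < 1:
        raise ValueError("power must be >= 1")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    period = 60.0 / rate_bpm
    z = _waveform(t % period, period, amplitude_mm, power)
    meta = {
        "waveform": f"sin^{2 * power}",
        "rate_bpm": rate_bpm,
        "amplitude_mm": amplitude_mm,
        "power": power,
    }
    return MotionTrace(t=t, z=z, fs=fs, meta=meta)


def generate_irregular_trace(
    spec: IrregularSpec,
    duration_s: float = 600.0,
    fs: float = 100.0,
) -> MotionTrace:
    """Irregular breathing: cycles with independently re-drawn parameters.

    Each cycle draws rate ~ U(rate_range) BPM, amplitude ~ U(amplitude_range)
    mm and a waveform power uniformly from ``spec.waveform_powers``; the cycle
    is then ``A sin^{2p}`` over its own period.  Cycle durations are snapped
    to the sample grid so every boundary falls on a sample and z = 0 exactly
    there.  Reproducible under ``spec.seed``.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * fs)) + 1
    z = np.zeros(n)
    cycles: list[dict] = []
    start = 0  # sample index of current cycle boundary
    while start < n - 1:
        rate = rng.uniform(*spec.rate_range)
        amp = rng.uniform(*spec.amplitude_range)
        p = int(rng.choice(spec.waveform_powers))
        period = 60.0 / rate
        # snap the cycle length to the sample grid (>= 2 samples)
        n_cyc = max(int(round(period * fs)), 2)
        period_snapped = n_cyc / fs
        stop = min(start + n_cyc, n - 1)
        idx = np.arange(start, stop + 1)
        z[idx] = _waveform((idx - start) / fs, period_snapped, amp, p)
        cycles.append(
            {
                "start_s": start / fs,
                "period_s": period_snapped,
                "rate_bpm": 60.0 / period_snapped,
                "amplitude_mm": amp,
                "power": p,
                "complete": stop == start + n_cyc,
            }
        )
        start += n_cyc
    t = np.arange(n) / fs
    meta = {
        "waveform": "irregular",
        "rate_range_bpm": spec.rate_range,
        "amplitude_range_mm": spec.amplitude_range,
        "waveform_powers": tuple(spec.waveform_powers),
        "seed": spec.seed,
        "cycles": cycles,
    }
    return MotionTrace(t=t, z=z, fs=fs, meta=meta)


def cycle_table(trace: MotionTrace) -> pd.DataFrame:
    """Per-cycle measurements of an irregular trace, from the trace itself.

    Cycle boundaries are taken from the generator's recorded boundary times;
    the rate is measured from the boundary spacing and the amplitude as the
    peak z within each complete cycle.  Incomplete trailing cycles are
    dropped.
    """
    if "cycles" not in trace.meta:
        raise ValueError("trace has no recorded cycles (not an irregular trace)")
    rows = []
    for c in trace.meta["cycles"]:
        if not c["complete"]:
            continue
        i0 = int(round(c["start_s"] * trace.fs))
        i1 = i0 + int(round(c["period_s"] * trace.fs))
        rows.append(
            {
                "start_s": c["start_s"],
                "rate_bpm": 60.0 / c["period_s"],
                "amplitude_mm": float(np.max(trace.z[i0 : i1 + 1])),
                "power": c["power"],
            }
        )
    return pd.DataFrame(rows)


def apply_kinematics(trace: MotionTrace, cfg: KinematicsConfig = KinematicsConfig()) -> MotionTrace:
    """Couple the longitudinal drive into x/y motion via the rotational arm.

    theta(t) = rotation_max * (2 z(t)/amplitude_ref - 1) degrees;
    x(t) = r sin(theta) - r sin(theta0), y(t) = r cos(theta) - r cos(theta0)
    with r = target_offset, so x = y = 0 at t = 0 and the target stays on the
    radius-r circle about the rotation axis.
    """
    if cfg.amplitude_ref == 0:
        raise ValueError("amplitude_ref must be non-zero")
    theta = np.deg2rad(cfg.rotation_max) * (2.0 * trace.z / cfg.amplitude_ref - 1.0)
    r = cfg.target_offset
    x = r * np.sin(theta) - r * np.sin(theta[0])
    y = r * np.cos(theta) - r * np.cos(theta[0])
    meta = dict(trace.meta)
    meta["kinematics"] = {
        "rotation_max_deg": cfg.rotation_max,
        "target_offset_mm": cfg.target_offset,
        "amplitude_ref_mm": cfg.amplitude_ref,
    }
    return MotionTrace(t=trace.t.copy(), z=trace.z.copy(), fs=trace.fs, x=x, y=y, meta=meta)


def write_trace_csv(trace: MotionTrace, path: str | Path) -> None:
    """Write a trace as CSV (t_s, x_mm, y_mm, z_mm), 6-decimal round-trip."""
    pos = trace.positions()
    df = pd.DataFrame(
        {"t_s": trace.t, "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path: str | Path) -> MotionTrace:
    """Read a trace CSV written by :func:`write_trace_csv`."""
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace CSV must contain at least two samples")
    fs = 1.0 / (t[1] - t[0])
    return MotionTrace(
        t=t,
        z=df["z_mm"].to_numpy(),
        fs=fs,
        x=df["x_mm"].to_numpy(),
        y=df["y_mm"].to_numpy(),
        meta={"source": str(path)},
    )
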