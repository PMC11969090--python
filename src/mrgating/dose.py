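"""2D relative-dose distributions and the time-weighted motion convolution.

The zero-latency reference dose of a gated delivery is modelled by sweeping
a measured (or synthetic) static field along the longitudinal axis with the
target's recorded displacement, weighting each beam-on sub-interval by its
duration:

    D_ref(x, z) = sum_i D_static(x, z + dz_i) * dt_i / sum_i dt_i

where dz_i is the longitudinal displacement during beam-on interval i.
Displacements are clamped to the gating window, which confines the spatial
range of the convolution to where the beam was permitted.

The synthetic static field is a separable product of smooth (erf) edge
functions, placing the 50% dose level at the nominal field edges — a
faithful stand-in for a collimated photon field with Gaussian penumbra.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from .gating import BeamSignal
from .traces import MotionTrace

__all__ = [
    "DoseDistribution2D",
    "DeliverySegments",
    "FieldSpec",
    "synthetic_static_field",
    "build_segments",
    "convolve_reference",
    "write_dose_txt",
    "read_dose_txt",
    "read_dicom_dose",
]


@dataclass
class DoseDistribution2D:
    """Relative dose on a rectilinear grid.

    ``dose[i, j]`` is the dose at ``(x_axis[i], z_axis[j])``; x is the
    cross-plane (lateral) axis, z the in-plane (longitudinal) axis along
    which the target moves.
    """

    x_axis: np.ndarray  # mm, strictly increasing, uniform
    z_axis: np.ndarray  # mm, strictly increasing, uniform
    dose: np.ndarray  # (len(x_axis), len(z_axis)), >= 0

    def __post_init__(self) -> None:
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        for axis in (self.x_axis, self.z_axis):
            d = np.diff(axis)
            if len(axis) < 2 or not np.all(d > 0):
                raise ValueError("axes must be strictly increasing with >= 2 points")
            if not np.allclose(d, d[0], rtol=1e-6):
                raise ValueError("axes must be uniformly spaced")
        if self.dose.shape != (len(self.x_axis), len(self.z_axis)):
            raise ValueError("dose shape must be (len(x_axis), len(z_axis))")
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise ValueError("dose must be finite and non-negative")

    @property
    def spacing(self) -> tuple[float, float]:
        return (
            float(self.x_axis[1] - self.x_axis[0]),
            float(self.z_axis[1] - self.z_axis[0]),
        )


@dataclass
class DeliverySegments:
    """Beam-on sub-intervals with the longitudinal displacement in each."""

    dt: np.ndarray  # s, > 0
    dz: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.dt = np.asarray(self.dt, dtype=float)
        self.dz = np.asarray(self.dz, dtype=float)
        if np.any(self.dt <= 0):
            raise ValueError("segment durations must be positive")
        if self.dt.shape != self.dz.shape:
            raise ValueError("dt and dz must have equal length")

    @property
    def total_time(self) -> float:
        return float(np.sum(self.dt))

    def __len__(self) -> int:
        return len(self.dt)


@dataclass(frozen=True)
class FieldSpec:
    """Synthetic collimated static field: size per axis, penumbra, centre."""

    field_size: tuple[float, float] = (100.0, 100.0)  # (x, z) mm
    penumbra_sigma: float = 3.0  # mm
    center: tuple[float, float] = (0.0, 0.0)  # (x, z) mm
    peak: float = 1.0

    def __post_init__(self) -> None:
        if min(self.field_size) <= 0:
            raise ValueError("field_size must be positive")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be positive")


def _edge_profile(u: np.ndarray, center: float, width: float, sigma: float) -> np.ndarray:
    lo, hi = center - width / 2.0, center + width / 2.0
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((u - lo) / s) - (erf((u - hi) / s)))


def synthetic_static_field(
    spec: FieldSpec,
    x_axis: np.ndarray,
    z_axis: np.ndarray,
) -> DoseDistribution2D:
    """Separable erf-edged field; dose is ``peak`` at centre and ``peak/2``
    at the nominal field edges.

    The grid must extend at least 5 penumbra sigmas beyond each field edge
    so the profile decays to (numerically) zero inside the grid.
    """
    x_axis = np.asarray(x_axis, dtype=float)
    z_axis = np.asarray(z_axis, dtype=float)
    margin = 5.0 * spec.penumbra_sigma
    for axis, size, c in (
        (x_axis, spec.field_size[0], spec.center[0]),
        (z_axis, spec.field_size[1], spec.center[1]),
    ):
        if axis[0] > c - size / 2 - margin or axis[-1] < c + size / 2 + margin:
            raise ValueError("grid must cover the field plus a 5-sigma margin")
    fx = _edge_profile(x_axis, spec.center[0], spec.field_size[0], spec.penumbra_sigma)
    fz = _edge_profile(z_axis, spec.center[1], spec.field_size[1], spec.penumbra_sigma)
    dose = spec.peak * np.outer(fx, fz)
    return DoseDistribution2D(x_axis=x_axis, z_axis=z_axis, dose=np.clip(dose, 0.0, None))


def build_segments(motion: MotionTrace, beam: BeamSignal) -> DeliverySegments:
    """One segment per beam-on sample interval of the beam signal.

    Each on-interval contributes its sample period as dt and the motion's
    longitudinal displacement, linearly interpolated at the interval
    midpoint, as dz.  Requires the beam sampled at least as fast as the
    motion and a common time span.
    """
    if beam.fs < motion.fs - 1e-9:
        raise ValueError("beam must be sampled at least as fast as the motion")
    if beam.t[0] < motion.t[0] - 1e-9 or beam.t[-1] > motion.t[-1] + 1e-9:
        raise ValueError("beam signal extends beyond the motion trace")
    on = beam.state[:-1] == 1  # state over interval [t_j, t_{j+1})
    mids = (beam.t[:-1] + beam.t[1:])[on] / 2.0
    dz = np.interp(mids, motion.t, motion.z)
    dt = np.full(len(dz), 1.0 / beam.fs)
    return DeliverySegments(dt=dt, dz=dz)


def _shift_sample(dose: np.ndarray, z_axis: np.ndarray, dz: float) -> np.ndarray:
    """Sample ``dose`` at ``z + dz`` along the z axis (linear, zero-fill)."""
    step = z_axis[1] - z_axis[0]
    pos = (z_axis + dz - z_axis[0]) / step
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    out = np.zeros_like(dose)
    valid = (i0 >= 0) & (i0 <= len(z_axis) - 2)
    iv = i0[valid]
    out[:, valid] = dose[:, iv] * (1.0 - frac[valid]) + dose[:, iv + 1] * frac[valid]
    # exact upper boundary (pos == n-1)
    top = np.isclose(pos, len(z_axis) - 1.0) & ~valid
    if top.any():
        out[:, top] = dose[:, [len(z_axis) - 1]]
    return out


def convolve_reference(
    static: DoseDistribution2D,
    segments: DeliverySegments,
    window: tuple[float, float] | None = (0.0, 15.0),
    dz_bin_mm: float | None = None,
) -> DoseDistribution2D:
    """Time-weighted convolution of the static field with the recorded motion.

    Each segment shifts the static distribution by its displacement (the
    static dose is sampled at ``z + dz_i``, linear interpolation, zero
    outside the grid) and contributes weight ``dt_i / sum(dt)``.
    Displacements outside ``window`` are clamped to the nearest bound —
    the gating window confines the spatial range of the convolution; pass
    ``window=None`` to convolve at the raw displacements (e.g. to model the
    dose actually accumulated by a latency-affected delivery).

    ``dz_bin_mm`` optionally quantizes displacements to that bin width so
    that long 2 kHz deliveries collapse to a few hundred unique shifts; the
    default (None) is exact.
    """
    if len(segments) == 0:
        raise ValueError("empty delivery segments: the beam was never on")
    dz = segments.dz.copy()
    if window is not None:
        lo, hi = window
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("window bounds must be finite")
        dz = np.clip(dz, lo, hi)
    if dz_bin_mm is not None and dz_bin_mm > 0:
        dz = np.round(dz / dz_bin_mm) * dz_bin_mm
    weights = segments.dt / segments.total_time
    out = np.zeros_like(static.dose)
    for dz_u in np.unique(dz):
        w = float(np.sum(weights[dz == dz_u]))
        out += w * _shift_sample(static.dose, static.z_axis, float(dz_u))
    return DoseDistribution2D(
        x_axis=static.x_axis.copy(),
        z_axis=static.z_axis.copy(),
        dose=np.clip(out, 0.0, None),
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_dose_txt(dist: DoseDistribution2D, path: str | Path) -> None:
    """Plain-text grid: two axis-header comment lines, then one dose row per
    x position (columns follow z_axis)."""
    with open(path, "w") as f:
        f.write("# x_mm: " + " ".join(f"{v:.6g}" for v in dist.x_axis) + "\n")
        f.write("# z_mm: " + " ".join(f"{v:.6g}" for v in dist.z_axis) + "\n")
        np.savetxt(f, dist.dose, fmt="%.8g")


def read_dose_txt(path: str | Path) -> DoseDistribution2D:
    with open(path) as f:
        x_line = f.readline()
        z_line = f.readline()
        if not x_line.startswith("# x_mm:") or not z_line.startswith("# z_mm:"):
            raise ValueError("not a dose grid file (missing axis headers)")
        x_axis = np.array([float(v) for v in x_line.split(":", 1)[1].split()])
        z_axis = np.array([float(v) for v in z_line.split(":", 1)[1].split()])
        dose = np.loadtxt(f, ndmin=2)
    return DoseDistribution2D(x_axis=x_axis, z_axis=z_axis, dose=dose)


def read_dicom_dose(path: str | Path) -> DoseDistribution2D:
    """Convenience import of a single-frame DICOM RT dose grid.

    The DICOM row axis maps to z (in-plane) and the column axis to x
    (cross-plane); dose is scaled by DoseGridScaling and treated as
    relative downstream.
    """
    import pydicom  # optional dependency

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float) * float(getattr(ds, "DoseGridScaling", 1.0))
    if arr.ndim != 2:
        raise ValueError("only single-frame RT dose grids are supported")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    x_axis = float(origin[0]) + np.arange(arr.shape[1]) * col_sp
    z_axis = float(origin[1]) + np.arange(arr.shape[0]) * row_sp
    return DoseDistribution2D(x_axis=x_axis, z_axis=z_axis, dose=arr.T)
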