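"""Film-scan preprocessing, rigid point registration, profile extraction
and beam-profile constancy metrics.

Radiochromic-film workflows read the scanner's red channel (where the dye's
absorption change is largest), median-filter impulse noise from dust and
pinpricks, and register the scan to the reference dose grid from manually
identified fiducial marks.  1D profiles are taken as the mean over a narrow
band of rows/columns, and summarized by the standard constancy metrics:
central-axis dose (CAX), field size (50%-of-CAX width), 80%-20% penumbra,
flatness and symmetry over the central 80% of the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import EuclideanTransform

from .dose import DoseDistribution2D

__all__ = [
    "ScanImage",
    "Profile1D",
    "ProfileMetrics",
    "RigidTransform",
    "read_scan_image",
    "preprocess_scan",
    "register_points",
    "extract_profile",
    "profile_metrics",
    "profile_constancy",
    "write_constancy_report",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass
class ScanImage:
    """Raster scan with physical pixel spacing and fiducial marks.

    ``pixels`` is (rows, cols) grayscale or (rows, cols, 3) RGB; rows map to
    the in-plane (z) axis and columns to the cross-plane (x) axis.
    ``fiducials`` are (row, col) pixel coordinates of pinprick marks.
    """

    pixels: np.ndarray
    pixel_spacing: float  # mm
    fiducials: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D grayscale or 3-channel RGB")
        if self.fiducials:
            rows, cols = self.pixels.shape[:2]
            for r, c in self.fiducials:
                if not (0 <= r < rows and 0 <= c < cols):
                    raise ValueError("fiducials must lie within the image")

    def fiducials_mm(self) -> np.ndarray:
        """Fiducial coordinates in mm as (z, x) = (row, col) * spacing."""
        if not self.fiducials:
            return np.empty((0, 2))
        return np.asarray(self.fiducials, dtype=float) * self.pixel_spacing


@dataclass
class Profile1D:
    position: np.ndarray  # mm, strictly increasing
    value: np.ndarray  # relative dose
    axis: str  # 'cross-plane' | 'in-plane'
    band_center: float = 0.0
    band_width: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if not np.all(np.diff(self.position) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class ProfileMetrics:
    cax: float  # dose at field centre
    field_size: float  # mm between 50%-of-CAX crossings
    penumbra_left: float  # mm, 80% -> 20% lateral distance
    penumbra_right: float
    flatness: float  # %
    symmetry: float  # %


@dataclass
class RigidTransform:
    """2D rotation + translation mapping src points onto dst points."""

    rotation_rad: float
    translation: np.ndarray  # (2,) mm
    residual_rms: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        R = np.array([[c, -s], [s, c]])
        return np.atleast_2d(points) @ R.T + self.translation


def read_scan_image(
    path: str | Path,
    pixel_spacing: float,
    fiducials: list[tuple[float, float]] | None = None,
) -> ScanImage:
    """Read an 8/16-bit grayscale or RGB raster file as a ScanImage."""
    import imageio.v3 as iio

    return ScanImage(pixels=iio.imread(path), pixel_spacing=pixel_spacing, fiducials=fiducials)


def preprocess_scan(
    img: ScanImage,
    channel: str = "red",
    median_window: int = 3,
) -> DoseDistribution2D:
    """Channel extraction + square median filter, mapped to a dose grid.

    Values pass through unchanged (relative dosimetry — no calibration
    curve); the grid axes come from the pixel spacing, with the column axis
    as x (cross-plane) and the row axis as z (in-plane).
    """
    if median_window < 1 or median_window % 2 == 0:
        raise ValueError("median_window must be an odd positive integer")
    if img.pixels.ndim == 3:
        if channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {sorted(_CHANNELS)}")
        plane = img.pixels[:, :, _CHANNELS[channel]].astype(float)
    else:
        plane = img.pixels.astype(float)
    if median_window > 1:
        plane = ndimage.median_filter(plane, size=median_window, mode="nearest")
    rows, cols = plane.shape
    x_axis = np.arange(cols) * img.pixel_spacing
    z_axis = np.arange(rows) * img.pixel_spacing
    return DoseDistribution2D(x_axis=x_axis, z_axis=z_axis, dose=plane.T)


def register_points(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid (rotation + translation, no scaling) registration.

    Minimizes the mean squared distance between transformed src points and
    dst points; returns the transform and the residual RMS.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or len(src) < 2:
        raise ValueError("need >= 2 point pairs of equal count")
    if np.allclose(src, src[0]) or np.allclose(dst, dst[0]):
        raise ValueError("points must not be coincident")
    if hasattr(EuclideanTransform, "from_estimate"):
        tf = EuclideanTransform.from_estimate(src, dst)
        if not tf:
            raise ValueError("rigid registration failed")
    else:  # scikit-image < 0.26
        tf = EuclideanTransform()
        if not tf.estimate(src, dst):
            raise ValueError("rigid registration failed")
    mapped = tf(src)
    rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return RigidTransform(
        rotation_rad=float(tf.rotation),
        translation=np.asarray(tf.translation, dtype=float),
        residual_rms=rms,
    )


def extract_profile(
    dose: DoseDistribution2D,
    axis: str,
    band_center: float = 0.0,
    band_width: float = 5.0,
) -> Profile1D:
    """Mean profile over a narrow perpendicular band.

    'cross-plane' profiles run along x, averaged over the z band centred at
    ``band_center``; 'in-plane' profiles run along z, averaged over the x
    band.  The band must lie within the grid.
    """
    lo, hi = band_center - band_width / 2.0, band_center + band_width / 2.0
    if axis == "cross-plane":
        perp = dose.z_axis
    elif axis == "in-plane":
        perp = dose.x_axis
    else:
        raise ValueError("axis must be 'cross-plane' or 'in-plane'")
    if lo < perp[0] - 1e-9 or hi > perp[-1] + 1e-9:
        raise ValueError("band lies outside the dose grid")
    sel = (perp >= lo) & (perp <= hi)
    if not sel.any():
        sel = np.zeros_like(sel)
        sel[np.argmin(np.abs(perp - band_center))] = True  # band narrower than spacing
    if axis == "cross-plane":
        value = dose.dose[:, sel].mean(axis=1)
        position = dose.x_axis
    else:
        value = dose.dose[sel, :].mean(axis=0)
        position = dose.z_axis
    return Profile1D(
        position=position.copy(),
        value=value,
        axis=axis,
        band_center=band_center,
        band_width=band_width,
    )


def _crossings(position: np.ndarray, value: np.ndarray, level: float) -> list[float]:
    """All linear-interpolated positions where the profile crosses `level`."""
    out = []
    v = value - level
    for i in range(len(v) - 1):
        if v[i] == 0.0:
            out.append(float(position[i]))
        elif v[i] * v[i + 1] < 0:
            f = v[i] / (v[i] - v[i + 1])
            out.append(float(position[i] + f * (position[i + 1] - position[i])))
    if len(v) and v[-1] == 0.0:
        out.append(float(position[-1]))
    return out


def _edge_position(position, value, level, side: str) -> float:
    """Outermost crossing of `level` on the requested edge."""
    xs = _crossings(position, value, level)
    if not xs:
        raise ValueError(f"profile never crosses {level:.4g}")
    return min(xs) if side == "left" else max(xs)


def profile_metrics(p: Profile1D) -> ProfileMetrics:
    """Constancy metrics of a single beam profile.

    CAX is the value at the midpoint between the 50%-of-CAX crossings
    (fixed-point iterated from 50%-of-max); field size is the distance
    between those crossings; the penumbrae are the 80%->20%-of-CAX lateral
    distances per edge; flatness is 100*(max-min)/(max+min) and symmetry
    the maximum mirrored left/right difference in % of CAX, both over the
    central 80% of the field.
    """
    pos, val = p.position, p.value
    interp = lambda x: float(np.interp(x, pos, val))
    cax = float(np.max(val))
    center = float(pos[np.argmax(val)])
    for _ in range(4):  # fixed point: crossings at 50% of CAX define centre
        half = 0.5 * cax
        xs = _crossings(pos, val, half)
        if len(xs) < 2:
            raise ValueError("profile must cross 50% of CAX at least twice")
        left50, right50 = min(xs), max(xs)
        center = 0.5 * (left50 + right50)
        cax = interp(center)
    field_size = right50 - left50
    pen_l = abs(
        _edge_position(pos, val, 0.8 * cax, "left") - _edge_position(pos, val, 0.2 * cax, "left")
    )
    pen_r = abs(
        _edge_position(pos, val, 0.8 * cax, "right") - _edge_position(pos, val, 0.2 * cax, "right")
    )
    half_flat = 0.4 * field_size  # central 80% of the field
    d = np.linspace(0.0, half_flat, 201)
    left_vals = np.interp(center - d, pos, val)
    right_vals = np.interp(center + d, pos, val)
    central = np.concatenate([left_vals, right_vals])
    flatness = 100.0 * (central.max() - central.min()) / (central.max() + central.min())
    symmetry = 100.0 * float(np.max(np.abs(left_vals - right_vals))) / cax
    return ProfileMetrics(
        cax=cax,
        field_size=float(field_size),
        penumbra_left=float(pen_l),
        penumbra_right=float(pen_r),
        flatness=float(flatness),
        symmetry=float(symmetry),
    )


def profile_constancy(ref: ProfileMetrics, gated: ProfileMetrics) -> dict[str, float]:
    """Per-metric deltas of a gated profile relative to the ungated one.

    CAX in % of the reference; field size and penumbrae in cm; flatness and
    symmetry in percentage points.
    """
    return {
        "cax_pct": 100.0 * (gated.cax - ref.cax) / ref.cax,
        "fs_cm": (gated.field_size - ref.field_size) / 10.0,
        "penumbra_left_cm": (gated.penumbra_left - ref.penumbra_left) / 10.0,
        "penumbra_right_cm": (gated.penumbra_right - ref.penumbra_right) / 10.0,
        "flatness_pct": gated.flatness - ref.flatness,
        "symmetry_pct": gated.symmetry - ref.symmetry,
    }


def write_constancy_report(
    deltas_by_window: dict[str, dict[str, dict[str, float]]],
    path: str | Path,
) -> pd.DataFrame:
    """CSV report: rows = gating windows, columns = per-axis metric deltas.

    ``deltas_by_window[window][axis]`` holds :func:`profile_constancy`
    output for axis in {'x', 'y'}.
    """
    rows = []
    for window, per_axis in deltas_by_window.items():
        row: dict[str, object] = {"gating_window": window}
        for axis, deltas in per_axis.items():
            for k, v in deltas.items():
                row[f"{axis}_{k}"] = round(v, 3)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
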