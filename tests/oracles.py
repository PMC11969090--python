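"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: dense-grid numeric
integration, exhaustive searches, Monte-Carlo sampling and step-by-step
re-computations that the implementation under test must reproduce.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def duty_fraction_dense(power: int, level_fraction: float, n: int = 2_000_001) -> float:
    """Fraction of one period with sin^{2p}(theta) <= level, by dense grid."""
    theta = np.linspace(0.0, np.pi, n)
    return float(np.mean(np.sin(theta) ** (2 * power) <= level_fraction))


def crossing_times_roots(
    amplitude: float, period: float, power: int, level: float, duration: float
) -> np.ndarray:
    """All times where A sin^{2p}(pi t / T) crosses `level`, via brentq."""
    from scipy.optimize import brentq

    f = lambda t: amplitude * np.sin(np.pi * t / period) ** (2 * power) - level
    grid = np.linspace(0.0, duration, int(duration * 1000) + 1)
    roots = []
    for a, b in zip(grid[:-1], grid[1:]):
        if f(a) == 0.0:
            roots.append(a)
        elif f(a) * f(b) < 0:
            roots.append(brentq(f, a, b, xtol=1e-12))
    return np.array(roots)


def overlap_monte_carlo(
    center: np.ndarray,
    radius: float,
    box: dict,
    n: int = 100_000,
    seed: int = 0,
) -> float:
    """Sphere/box overlap fraction by uniform point sampling in the sphere."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-radius, radius, size=(int(n * 2.5), 3))
    pts = pts[np.sum(pts**2, axis=1) <= radius**2][:n] + np.asarray(center)
    inside = np.ones(len(pts), dtype=bool)
    axes = {"x": 0, "y": 1, "z": 2}
    for axis, (lo, hi) in box.items():
        v = pts[:, axes[axis]]
        inside &= (v >= lo) & (v <= hi)
    return float(np.mean(inside))


def linear_extrapolation_replay(
    frame_t: np.ndarray, true_pos: np.ndarray, history: int, lookahead: float
) -> np.ndarray:
    """Step-by-step re-computation of the linear position predictor."""
    n = len(frame_t)
    out = true_pos.copy()
    for k in range(history - 1, n):
        tt = frame_t[k - history + 1 : k + 1] - frame_t[k]
        pp = true_pos[k - history + 1 : k + 1]
        # explicit least-squares line fit per axis
        A = np.column_stack([tt, np.ones_like(tt)])
        for ax in range(pp.shape[1]):
            slope, intercept = np.linalg.lstsq(A, pp[:, ax], rcond=None)[0]
            out[k, ax] = intercept + slope * lookahead
    return out


def brute_force_gamma(ref, ev, criteria, step_factor: int = 10) -> np.ndarray:
    """Exhaustive gamma search over a densely resampled evaluated grid."""
    d_max = ref.dose.max()
    tol = criteria.dose_tol / 100.0 * d_max
    thr = criteria.low_dose_threshold / 100.0 * d_max
    step = criteria.dta / step_factor
    xf = np.linspace(
        ev.x_axis[0], ev.x_axis[-1], int(np.ceil((ev.x_axis[-1] - ev.x_axis[0]) / step)) + 1
    )
    zf = np.linspace(
        ev.z_axis[0], ev.z_axis[-1], int(np.ceil((ev.z_axis[-1] - ev.z_axis[0]) / step)) + 1
    )
    rgi = RegularGridInterpolator((ev.x_axis, ev.z_axis), ev.dose)
    xx, zz = np.meshgrid(xf, zf, indexing="ij")
    d_fine = rgi(np.stack([xx.ravel(), zz.ravel()], axis=1)).reshape(xx.shape)
    gmap = np.full(ref.dose.shape, np.nan)
    for i, xr in enumerate(ref.x_axis):
        for j, zr in enumerate(ref.z_axis):
            dr = ref.dose[i, j]
            if dr < thr:
                continue
            g2 = ((xx - xr) ** 2 + (zz - zr) ** 2) / criteria.dta**2 + ((d_fine - dr) / tol) ** 2
            gmap[i, j] = np.sqrt(g2.min())
    return gmap


def brute_force_median(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel square median with edge-replicated borders."""
    pad = window // 2
    padded = np.pad(img, pad, mode="edge")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(padded[i : i + window, j : j + window])
    return out


def brute_force_rigid_residual(src: np.ndarray, dst: np.ndarray) -> float:
    """Best rigid-registration RMS residual by numeric optimization."""
    from scipy.optimize import minimize

    def cost(params):
        th, tx, ty = params
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d = src @ R.T + [tx, ty] - dst
        return np.mean(np.sum(d**2, axis=1))

    best = min(
        (minimize(cost, [th0, 0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000}) for th0 in (0.0, 1.5, -1.5, 3.0)),
        key=lambda r: r.fun,
    )
    return float(np.sqrt(best.fun))
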