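"""Global 2D gamma-index comparison of dose distributions.

The gamma index combines dose difference and distance-to-agreement: for a
reference point at r_ref with dose D_ref,

    gamma(r_ref) = min over r of sqrt( |r - r_ref|^2 / dta^2
                                     + (D_eval(r) - D_ref)^2 / tol^2 )

with tol the dose tolerance as a percentage of the global normalization
(the reference maximum).  Points below the low-dose threshold are excluded
from the analysis; a point passes when gamma <= 1.

The evaluated distribution is linearly resampled to a step of at most
dta/10 and the minimization searches only within the radius where the
distance term alone would exceed the best candidate found at the reference
position — an exact truncation, since any farther point cannot lower the
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .dose import DoseDistribution2D

__all__ = ["GammaCriteria", "GammaResult", "gamma_index", "pass_rate_table"]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria: dose tolerance (% of global max), DTA (mm), and the
    low-dose threshold (% of reference max) below which points are skipped."""

    dose_tol: float  # %
    dta: float  # mm
    low_dose_threshold: float = 10.0  # %

    def __post_init__(self) -> None:
        if self.dose_tol <= 0 or self.dta <= 0:
            raise ValueError("dose_tol and dta must be positive")
        if not (0 <= self.low_dose_threshold < 100):
            raise ValueError("low_dose_threshold must lie in [0, 100)")

    @property
    def label(self) -> str:
        return f"{self.dose_tol:g}%/{self.dta:g}mm"


@dataclass
class GammaResult:
    """Gamma map over the reference grid (NaN below threshold) + pass rate."""

    gamma_map: np.ndarray
    pass_rate: float  # % of evaluated points with gamma <= 1
    n_evaluated: int
    criteria: GammaCriteria

    @property
    def mean_gamma(self) -> float:
        vals = self.gamma_map[np.isfinite(self.gamma_map)]
        return float(np.mean(vals)) if len(vals) else float("nan")


def _fine_grid(axis: np.ndarray, step: float) -> np.ndarray:
    n = max(int(np.ceil((axis[-1] - axis[0]) / step)), 1)
    return np.linspace(axis[0], axis[-1], n + 1)


def gamma_index(
    reference: DoseDistribution2D,
    evaluated: DoseDistribution2D,
    c: GammaCriteria,
    resample_factor: int = 10,
) -> GammaResult:
    """Gamma map evaluated at reference grid points (searching the evaluated
    distribution), with global normalization to the reference maximum.

    Both grids must already be in a common frame (apply registration
    upstream) and overlap spatially.
    """
    if (
        reference.x_axis[-1] < evaluated.x_axis[0]
        or evaluated.x_axis[-1] < reference.x_axis[0]
        or reference.z_axis[-1] < evaluated.z_axis[0]
        or evaluated.z_axis[-1] < reference.z_axis[0]
    ):
        raise ValueError("reference and evaluated grids do not overlap")
    d_max = float(np.max(reference.dose))
    if d_max <= 0:
        raise ValueError("reference distribution has no dose")
    tol = c.dose_tol / 100.0 * d_max
    thr = c.low_dose_threshold / 100.0 * d_max

    step = c.dta / resample_factor
    xf = _fine_grid(evaluated.x_axis, step)
    zf = _fine_grid(evaluated.z_axis, step)
    spline = RectBivariateSpline(evaluated.x_axis, evaluated.z_axis, evaluated.dose, kx=1, ky=1)
    d_fine = spline(xf, zf)

    eval_mask = reference.dose >= thr
    gamma_map = np.full(reference.dose.shape, np.nan)
    if not eval_mask.any():
        import warnings

        warnings.warn("all reference points fall below the low-dose threshold")
        return GammaResult(gamma_map, float("nan"), 0, c)

    dta2 = c.dta**2
    for i, j in zip(*np.nonzero(eval_mask)):
        xr, zr = reference.x_axis[i], reference.z_axis[j]
        dr = reference.dose[i, j]
        # candidate at the fine point nearest the reference position
        i0 = int(np.clip(round((xr - xf[0]) / (xf[1] - xf[0])), 0, len(xf) - 1))
        j0 = int(np.clip(round((zr - zf[0]) / (zf[1] - zf[0])), 0, len(zf) - 1))
        g0 = np.sqrt(
            ((xf[i0] - xr) ** 2 + (zf[j0] - zr) ** 2) / dta2 + (d_fine[i0, j0] - dr) ** 2 / tol**2
        )
        radius = c.dta * g0  # beyond this the distance term alone exceeds g0
        ilo = int(np.searchsorted(xf, xr - radius))
        ihi = int(np.searchsorted(xf, xr + radius, side="right"))
        jlo = int(np.searchsorted(zf, zr - radius))
        jhi = int(np.searchsorted(zf, zr + radius, side="right"))
        dx2 = (xf[ilo:ihi] - xr) ** 2
        dz2 = (zf[jlo:jhi] - zr) ** 2
        g2 = dx2[:, None] / dta2 + dz2[None, :] / dta2 + (
            (d_fine[ilo:ihi, jlo:jhi] - dr) / tol
        ) ** 2
        gamma_map[i, j] = np.sqrt(min(float(g2.min()) if g2.size else np.inf, g0**2))

    vals = gamma_map[eval_mask]
    pass_rate = 100.0 * float(np.mean(vals <= 1.0 + 1e-9))
    return GammaResult(gamma_map, pass_rate, int(eval_mask.sum()), c)


def pass_rate_table(
    reference: DoseDistribution2D,
    evaluated: DoseDistribution2D,
    criteria_list: list[GammaCriteria],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """One gamma analysis per criteria; rows keyed by the criteria label."""
    if not criteria_list:
        raise ValueError("need at least one gamma criteria")
    rows = []
    for c in criteria_list:
        res = gamma_index(reference, evaluated, c)
        rows.append(
            {
                "criteria": c.label,
                "pass_rate_pct": round(res.pass_rate, 1),
                "mean_gamma": round(res.mean_gamma, 3),
                "n_evaluated": res.n_evaluated,
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
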