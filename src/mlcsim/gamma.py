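"""2D gamma-index analysis for planar dose comparisons.

The gamma index combines dose difference and distance-to-agreement:

    gamma(r) = min_e sqrt( |r - e|^2 / dta^2 + (D_e(e) - D_r(r))^2 / delta^2 )

with ``delta`` either a fixed fraction of the reference-distribution maximum
(global normalization) or of the local reference dose (local normalization).
The reference distribution is the measurement; the evaluated distribution is
the calculation, bilinearly resampled to a fine lattice (default 0.5 mm)
within the search region.  Points below a low-dose threshold (default 10% of
the reference maximum) are excluded.

``gamma_map`` searches a disc of radius ``search_radius_factor * dta`` and
then *expands* the search for any point whose current best gamma exceeds
``radius / dta`` -- beyond that radius the spatial term alone already exceeds
the current best, so the expansion terminates with the exact minimum.
``brute_force_gamma`` is an independent exhaustive oracle on small grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import AnalysisError, DataError
from .dose import DoseMap

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "gamma_map",
    "brute_force_gamma",
    "passing_rate_table",
]

# a gamma exactly at 1 (e.g. a uniform dose shift equal to the tolerance)
# must pass; this guard absorbs float representation error only
_PASS_TOL = 1e-9


@dataclass(frozen=True)
class GammaCriteria:
    """A criteria set such as 3%/3 mm global with a 10% dose threshold."""

    dose_tol: float            # percent
    dta: float                 # cm
    normalization: str = "global"   # 'global' or 'local'
    threshold: float = 0.10    # fraction of reference max
    search_radius_factor: float = 3.0
    resample_spacing: float = 0.05  # cm; evaluated-distribution lattice

    def __post_init__(self):
        if self.dose_tol <= 0 or self.dta <= 0:
            raise DataError("dose_tol and dta must be positive")
        if not 0.0 <= self.threshold < 1.0:
            raise DataError("threshold must be in [0, 1)")
        if self.normalization not in ("global", "local"):
            raise DataError("normalization must be 'global' or 'local'")

    @property
    def label(self) -> str:
        return (f"{self.dose_tol:g}%/{self.dta * 10:g}mm "
                f"{self.normalization}")


@dataclass(frozen=True)
class GammaResult:
    """Per-reference-point gamma values and the derived passing rate."""

    gamma: np.ndarray          # reference-shaped; NaN where not evaluable
    evaluable: np.ndarray      # boolean mask on the reference grid
    criteria: GammaCriteria

    @property
    def n_evaluable(self) -> int:
        return int(self.evaluable.sum())

    @property
    def passing_rate(self) -> float:
        n = self.n_evaluable
        if n == 0:
            return float("nan")
        passed = np.sum(self.gamma[self.evaluable] <= 1.0 + _PASS_TOL)
        return 100.0 * float(passed) / n


def _ref_points(dose: DoseMap):
    g = dose.grid
    xx, yy = np.meshgrid(g.x, g.y)
    return xx.ravel(), yy.ravel(), dose.values.ravel()


def _check_overlap(reference: DoseMap, evaluated: DoseMap):
    rg, eg = reference.grid, evaluated.grid
    if (rg.x[-1] < eg.x[0] or eg.x[-1] < rg.x[0]
            or rg.y[-1] < eg.y[0] or eg.y[-1] < rg.y[0]):
        raise DataError("reference and evaluated grids do not overlap")


def _delta(criteria: GammaCriteria, ref_vals: np.ndarray, ref_max: float):
    if criteria.normalization == "global":
        return np.full(ref_vals.shape, criteria.dose_tol / 100.0 * ref_max)
    return criteria.dose_tol / 100.0 * ref_vals


def _disc_offsets(radius: float, h: float):
    """Lattice offsets (dx, dy) with |offset| <= radius, spacing h, (0,0) first."""
    n = int(np.floor(radius / h + 1e-9))
    k = np.arange(-n, n + 1) * h
    dx, dy = np.meshgrid(k, k)
    d2 = dx**2 + dy**2
    keep = d2 <= radius**2 + 1e-12
    dx, dy, d2 = dx[keep], dy[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return dx[order], dy[order], d2[order]


def gamma_map(reference: DoseMap, evaluated: DoseMap,
              criteria: GammaCriteria) -> GammaResult:
    """Gamma index at every evaluable reference point.

    The evaluated distribution is resampled bilinearly on a
    ``resample_spacing`` lattice anchored at each reference point; candidates
    outside the evaluated extent are ignored.
    """
    _check_overlap(reference, evaluated)
    ref_x, ref_y, ref_v = _ref_points(reference)
    ref_max = float(ref_v.max())
    mask = ref_v >= criteria.threshold * ref_max
    delta = _delta(criteria, ref_v, ref_max)
    mask &= delta > 0
    if not mask.any():
        raise AnalysisError("no evaluable points above the dose threshold")

    eg = evaluated.grid
    interp = RegularGridInterpolator((eg.y, eg.x), evaluated.values,
                                     method="linear", bounds_error=False,
                                     fill_value=np.nan)
    px = ref_x[mask]
    py = ref_y[mask]
    pv = ref_v[mask]
    pdelta = delta[mask]
    dta2 = criteria.dta**2
    h = criteria.resample_spacing
    max_radius = float(np.hypot(eg.x[-1] - eg.x[0], eg.y[-1] - eg.y[0])) + h

    def search(idx, radius):
        dx, dy, d2 = _disc_offsets(radius, h)
        pts = np.empty((dx.size, idx.size, 2))
        pts[:, :, 0] = py[idx][None, :] + dy[:, None]
        pts[:, :, 1] = px[idx][None, :] + dx[:, None]
        vals = interp(pts.reshape(-1, 2)).reshape(dx.size, idx.size)
        with np.errstate(invalid="ignore"):
            g2 = d2[:, None] / dta2 + ((vals - pv[idx][None, :]) / pdelta[idx][None, :])**2
            g2 = np.where(np.isnan(g2), np.inf, g2)
        return np.sqrt(g2.min(axis=0))

    all_idx = np.arange(px.size)
    radius = criteria.search_radius_factor * criteria.dta
    best = search(all_idx, radius)
    # exact truncation guard: gamma cannot improve beyond |r-e|/dta once that
    # exceeds the current best, so only points with best > radius/dta need a
    # wider search
    for _ in range(32):
        pending = np.isfinite(best) & (best > radius / criteria.dta + 1e-12)
        pending |= np.isinf(best)
        if not pending.any() or radius >= max_radius:
            break
        radius = min(max(2.0 * radius,
                         np.nanmax(np.where(np.isinf(best), 0.0, best))
                         * criteria.dta + h), max_radius)
        best[pending] = search(all_idx[pending], radius)

    gamma = np.full(ref_v.shape, np.nan)
    gamma[mask] = best
    return GammaResult(gamma=gamma.reshape(reference.values.shape),
                       evaluable=mask.reshape(reference.values.shape),
                       criteria=criteria)


def brute_force_gamma(reference: DoseMap, evaluated: DoseMap,
                      criteria: GammaCriteria, oversample: int = 10) -> GammaResult:
    """Exhaustive gamma oracle on a finely oversampled evaluated distribution.

    The evaluated grid is bilinearly refined ``oversample``-fold (>= 10) and
    the minimization runs over every refined point, pruned only by the exact
    bound gamma(e) >= |r - e| / dta.  Deliberately slow; refuses reference
    grids larger than 50 x 50.
    """
    if oversample < 10:
        raise DataError("oracle requires oversampling >= 10x")
    if reference.values.size > 2500:
        raise DataError("oracle restricted to reference grids <= 50x50 points")
    _check_overlap(reference, evaluated)

    eg = evaluated.grid
    hf = eg.spacing / oversample
    nxf = (eg.nx - 1) * oversample + 1
    nyf = (eg.ny - 1) * oversample + 1
    fx = eg.origin_x + hf * np.arange(nxf)
    fy = eg.origin_y + hf * np.arange(nyf)
    interp = RegularGridInterpolator((eg.y, eg.x), evaluated.values,
                                     method="linear")
    gx, gy = np.meshgrid(fx, fy)
    fine = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(nyf, nxf)

    ref_x, ref_y, ref_v = _ref_points(reference)
    ref_max = float(ref_v.max())
    mask = ref_v >= criteria.threshold * ref_max
    delta = _delta(criteria, ref_v, ref_max)
    mask &= delta > 0
    if not mask.any():
        raise AnalysisError("no evaluable points above the dose threshold")

    dta = criteria.dta
    gamma = np.full(ref_v.shape, np.nan)
    for i in np.flatnonzero(mask):
        rx, ry, rv, dl = ref_x[i], ref_y[i], ref_v[i], delta[i]
        # upper bound from the candidate nearest the reference point
        jx = int(np.clip(round((rx - fx[0]) / hf), 0, nxf - 1))
        jy = int(np.clip(round((ry - fy[0]) / hf), 0, nyf - 1))
        d2c = (fx[jx] - rx) ** 2 + (fy[jy] - ry) ** 2
        ub = np.sqrt(d2c / dta**2 + ((fine[jy, jx] - rv) / dl) ** 2)
        r = ub * dta  # any candidate farther away is strictly worse
        x0 = int(np.clip(np.floor((rx - r - fx[0]) / hf), 0, nxf - 1))
        x1 = int(np.clip(np.ceil((rx + r - fx[0]) / hf), 0, nxf - 1)) + 1
        y0 = int(np.clip(np.floor((ry - r - fy[0]) / hf), 0, nyf - 1))
        y1 = int(np.clip(np.ceil((ry + r - fy[0]) / hf), 0, nyf - 1)) + 1
        wx = fx[x0:x1] - rx
        wy = fy[y0:y1] - ry
        d2 = wy[:, None] ** 2 + wx[None, :] ** 2
        g2 = d2 / dta**2 + ((fine[y0:y1, x0:x1] - rv) / dl) ** 2
        gamma[i] = np.sqrt(g2.min())
    return GammaResult(gamma=gamma.reshape(reference.values.shape),
                       evaluable=mask.reshape(reference.values.shape),
                       criteria=criteria)


def passing_rate_table(results: Mapping) -> pd.DataFrame:
    """Tabulate passing rates for a mapping of criteria (or labels) to results.

    Rows are sorted ascending by (dose tolerance, DTA, normalization); the
    rates echo ``GammaResult.passing_rate`` exactly.
    """
    rows = []
    for key, res in results.items():
        c = res.criteria
        rows.append({
            "label": key.label if isinstance(key, GammaCriteria) else str(key),
            "dose_tol_pct": c.dose_tol,
            "dta_cm": c.dta,
            "normalization": c.normalization,
            "threshold": c.threshold,
            "n_evaluable": res.n_evaluable,
            "passing_rate_pct": res.passing_rate,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["dose_tol_pct", "dta_cm", "normalization"],
                            kind="stable").reset_index(drop=True)
    return df
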