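"""Sequential derivation of MLC model parameters from measurements.

The workflow mirrors clinical TPS commissioning practice for a step-function
rounded-leaf-tip MLC model, in a fixed order of decreasing independence:

1. fit the leaf-tip offset polynomial to the vendor table;
2. select the leaf-tip width from transverse dose profiles of MLC-defined
   fields (FWHM agreement is the primary key -- FWHM depends on the tip width
   only -- with penumbra RMSE as tie-break);
3. select the average transmission factor by maximizing the mean gamma
   passing rate of planar QA comparisons over a printed candidate grid;
4. select the tongue-and-groove width the same way.

The "iterative" derivation is realized as exhaustive search over the small
candidate grids, which removes any initialization ambiguity.  Tie-breaks are
deterministic: among candidates within ``tie_tolerance`` percentage points of
the best mean passing rate, the smallest parameter value wins (transmission
values closer to published leaf-leakage measurements, and the physically
smaller tongue-and-groove, are preferred when the data cannot discriminate).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CommissioningError, ConfigError, DataError
from .dose import (BeamKernel, DoseMap, Profile, extract_profile,
                   fluence_to_dose, penumbra_widths, profile_fwhm, _crossing)
from .fluence import (Aperture, GridSpec, LeafGeometry, MLCParameters,
                      OffsetModel, Plan, compute_segment_fluence,
                      composite_fluence_components, fit_offset_model)
from .gamma import GammaCriteria, gamma_map
from .synth import profile_grid

__all__ = [
    "CommissionConfig",
    "CommissionReport",
    "ProfileScore",
    "score_profile_match",
    "select_leaf_tip_width",
    "select_transmission",
    "select_tng_width",
    "run_commissioning",
]


def _default_criteria():
    # first entry is the selection objective; the stricter criterion
    # discriminates between transmission candidates better
    return (GammaCriteria(dose_tol=2.0, dta=0.2, normalization="global"),
            GammaCriteria(dose_tol=3.0, dta=0.3, normalization="global"))


@dataclass(frozen=True)
class CommissionConfig:
    """Candidate grids, gamma criteria and tie tolerance for the workflow."""

    tip_width_candidates: tuple = (0.1, 0.2, 0.3, 0.4)
    transmission_candidates: tuple = (0.016, 0.018, 0.020, 0.025, 0.030)
    tng_candidates: tuple = (0.05, 0.10)
    criteria: tuple = field(default_factory=_default_criteria)
    tie_tolerance: float = 0.5   # percentage points on the mean passing rate
    seed: int = 0

    def __post_init__(self):
        for name in ("tip_width_candidates", "transmission_candidates",
                     "tng_candidates"):
            cand = tuple(getattr(self, name))
            object.__setattr__(self, name, cand)
            if not cand:
                raise ConfigError(f"{name} must be non-empty")
            if list(cand) != sorted(cand):
                raise ConfigError(f"{name} must be sorted ascending")
        object.__setattr__(self, "criteria", tuple(self.criteria))
        if not self.criteria:
            raise ConfigError("at least one gamma criteria set is required")
        if self.tie_tolerance < 0:
            raise ConfigError("tie_tolerance must be >= 0")

    @property
    def objective(self) -> GammaCriteria:
        return self.criteria[0]

    def digest(self) -> str:
        payload = json.dumps(
            {"tip": self.tip_width_candidates,
             "transmission": self.transmission_candidates,
             "tng": self.tng_candidates,
             "criteria": [asdict(c) for c in self.criteria],
             "tie_tolerance": self.tie_tolerance, "seed": self.seed},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ProfileScore:
    """Agreement metrics between a computed and a measured profile."""

    fwhm_diff: float        # cm, calc - meas
    penumbra_rmse: float    # relative dose units over the 20-80% edge regions
    tail_mean_diff: float   # relative dose units outside the field


def score_profile_match(calc: Profile, meas: Profile) -> ProfileScore:
    """Compare profiles after normalizing each to its own maximum.

    FWHM difference is the primary key; the RMSE is taken over the measured
    20--80% edge regions; the tail statistic is the mean difference where the
    measured dose is below 10% of its maximum.
    """
    lo = max(calc.positions[0], meas.positions[0])
    hi = min(calc.positions[-1], meas.positions[-1])
    if hi <= lo:
        raise DataError("profiles do not overlap in position")
    cv = calc.values / np.max(calc.values)
    mv = meas.values / np.max(meas.values)
    cnorm = Profile(calc.positions, cv, calc.axis, calc.offset)
    mnorm = Profile(meas.positions, mv, meas.axis, meas.offset)
    fwhm_diff = profile_fwhm(cnorm) - profile_fwhm(mnorm)

    edges = []
    for side in ("left", "right"):
        x20 = _crossing(mnorm, 0.2, side)
        x80 = _crossing(mnorm, 0.8, side)
        edges.append((min(x20, x80), max(x20, x80)))
    sel = np.zeros(meas.positions.shape, dtype=bool)
    for a, b in edges:
        sel |= (meas.positions >= a) & (meas.positions <= b)
    sel &= (meas.positions >= lo) & (meas.positions <= hi)
    if sel.any():
        ci = np.interp(meas.positions[sel], calc.positions, cv)
        rmse = float(np.sqrt(np.mean((ci - mv[sel]) ** 2)))
    else:
        rmse = 0.0

    tail = (mv < 0.1) & (meas.positions >= lo) & (meas.positions <= hi)
    if tail.any():
        ci = np.interp(meas.positions[tail], calc.positions, cv)
        tail_diff = float(np.mean(ci - mv[tail]))
    else:
        tail_diff = 0.0
    return ProfileScore(fwhm_diff=float(fwhm_diff), penumbra_rmse=rmse,
                        tail_mean_diff=tail_diff)


def select_leaf_tip_width(cfg: CommissionConfig, fields: Sequence[Aperture],
                          measurements: Sequence[Profile],
                          fixed: MLCParameters, model: OffsetModel,
                          kernel: BeamKernel,
                          geometry: LeafGeometry | None = None,
                          grid: GridSpec | None = None):
    """Grid search over tip-width candidates against measured profiles.

    Returns ``(width, table)`` where the table holds one row per candidate
    with the aggregate scores (mean absolute FWHM difference primary, mean
    penumbra RMSE tie-break).
    """
    if len(fields) != len(measurements):
        raise DataError("need exactly one measured profile per field")
    geometry = geometry or LeafGeometry.millennium120()
    grid = grid or profile_grid()
    rows = []
    for w in cfg.tip_width_candidates:
        params = replace(fixed, leaf_tip_width=w)
        scores = []
        for fld, meas in zip(fields, measurements):
            f = compute_segment_fluence(fld, params, model, geometry, grid)
            calc = extract_profile(fluence_to_dose(f, kernel), "x", 0.0)
            scores.append(score_profile_match(calc, meas))
        rows.append({
            "leaf_tip_width_cm": w,
            "mean_abs_fwhm_diff_cm": float(np.mean([abs(s.fwhm_diff)
                                                    for s in scores])),
            "mean_penumbra_rmse": float(np.mean([s.penumbra_rmse
                                                 for s in scores])),
            "mean_tail_diff": float(np.mean([s.tail_mean_diff
                                             for s in scores])),
        })
    table = pd.DataFrame(rows)
    order = table.sort_values(["mean_abs_fwhm_diff_cm", "mean_penumbra_rmse",
                               "leaf_tip_width_cm"], kind="stable")
    return float(order.iloc[0]["leaf_tip_width_cm"]), table


def _plan_grid_for(meas: DoseMap, margin: float = 2.0,
                   spacing: float = 0.2) -> GridSpec:
    g = meas.grid
    x0 = g.origin_x - margin
    y0 = g.origin_y - margin
    nx = int(round((g.x[-1] + margin - x0) / spacing)) + 1
    ny = int(round((g.y[-1] + margin - y0) / spacing)) + 1
    return GridSpec(origin_x=x0, origin_y=y0, spacing=spacing, nx=nx, ny=ny)


def _passing_grid(cfg: CommissionConfig, candidates, param_name: str,
                  build_params, plans, measurements, model, kernel, geometry):
    """Gamma passing rates for every (candidate, plan, criteria) combination.

    Dose maps reuse the affine fluence decomposition F = A + B*T + C*sqrt(T):
    the three component maps (and their convolutions) are computed once per
    plan for fixed band widths, then every transmission candidate is a linear
    combination.
    """
    if len(plans) != len(measurements):
        raise DataError("need exactly one planar measurement per plan")
    rows = []
    for plan, meas in zip(plans, measurements):
        grid = _plan_grid_for(meas)
        comps = {}
        for cand in candidates:
            params = build_params(cand)
            key = (params.leaf_tip_width, params.tng_width)
            if key not in comps:
                A, B, C = composite_fluence_components(
                    plan, params.leaf_tip_width, params.tng_width, model,
                    geometry, grid)
                comps[key] = tuple(
                    fluence_to_dose(_as_fluence(grid, m), kernel).values
                    for m in (A, B, C))
            dA, dB, dC = comps[key]
            dose = DoseMap(grid, dA + params.transmission * dB
                           + np.sqrt(params.transmission) * dC)
            for crit in cfg.criteria:
                res = gamma_map(meas, dose, crit)
                rows.append({param_name: cand, "plan": plan.name,
                             "criteria": crit.label,
                             "passing_rate_pct": res.passing_rate,
                             "n_evaluable": res.n_evaluable})
    return pd.DataFrame(rows)


def _as_fluence(grid, values):
    from .fluence import FluenceMap
    return FluenceMap(grid, np.ascontiguousarray(values))


def _select_from_grid(cfg: CommissionConfig, table: pd.DataFrame,
                      param_name: str) -> float:
    """Maximize the mean objective passing rate; break ties toward the
    smallest candidate within ``tie_tolerance`` percentage points."""
    objective = cfg.objective.label
    means = (table[table["criteria"] == objective]
             .groupby(param_name)["passing_rate_pct"].mean())
    best = means.max()
    eligible = means[means >= best - cfg.tie_tolerance]
    return float(sorted(eligible.index)[0])


def select_transmission(cfg: CommissionConfig, plans: Sequence[Plan],
                        measurements: Sequence[DoseMap],
                        fixed: MLCParameters, model: OffsetModel,
                        kernel: BeamKernel,
                        geometry: LeafGeometry | None = None):
    """Grid search over average-transmission candidates scored by QA gamma."""
    geometry = geometry or LeafGeometry.millennium120()
    table = _passing_grid(
        cfg, cfg.transmission_candidates, "transmission",
        lambda t: replace(fixed, transmission=t),
        plans, measurements, model, kernel, geometry)
    return _select_from_grid(cfg, table, "transmission"), table


def select_tng_width(cfg: CommissionConfig, plans: Sequence[Plan],
                     measurements: Sequence[DoseMap],
                     fixed: MLCParameters, model: OffsetModel,
                     kernel: BeamKernel,
                     geometry: LeafGeometry | None = None):
    """Grid search over tongue-and-groove widths scored by QA gamma."""
    geometry = geometry or LeafGeometry.millennium120()
    table = _passing_grid(
        cfg, cfg.tng_candidates, "tng_width",
        lambda w: replace(fixed, tng_width=w),
        plans, measurements, model, kernel, geometry)
    return _select_from_grid(cfg, table, "tng_width"), table


@dataclass(frozen=True)
class CommissionReport:
    """Selected parameters plus the full per-candidate score tables."""

    offset_model: OffsetModel
    offset_r_squared: float
    parameters: MLCParameters
    tip_table: pd.DataFrame
    transmission_table: pd.DataFrame
    tng_table: pd.DataFrame
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "offset_model": asdict(self.offset_model),
            "offset_r_squared": self.offset_r_squared,
            "parameters": asdict(self.parameters),
            "tables": {
                "leaf_tip_width": self.tip_table.to_dict(orient="records"),
                "transmission": self.transmission_table.to_dict(orient="records"),
                "tng_width": self.tng_table.to_dict(orient="records"),
            },
            "provenance": self.provenance,
        }


def run_commissioning(cfg: CommissionConfig, dataset) -> CommissionReport:
    """Execute the four stages in order, each consuming prior selections.

    ``dataset`` provides ``offset_table``, ``profile_fields`` /
    ``profile_measurements``, ``plans`` / ``planar_measurements``, plus the
    ``geometry`` and beam ``kernel`` (the beam model is commissioned before
    the MLC).  Any stage failure aborts with a stage-labeled error.
    """
    geometry = dataset.geometry
    kernel = dataset.kernel

    try:
        fit = fit_offset_model(dataset.offset_table)
    except Exception as exc:
        raise CommissioningError("leaf_tip_offset", str(exc)) from exc
    model = fit.model

    # band widths are not yet known here: fix transmission mid-grid and T&G at
    # its smallest candidate; FWHM, the primary key, is insensitive to both
    t_mid = cfg.transmission_candidates[len(cfg.transmission_candidates) // 2]
    fixed = MLCParameters(leaf_tip_width=cfg.tip_width_candidates[0],
                          transmission=t_mid, tng_width=cfg.tng_candidates[0])
    try:
        tip_width, tip_table = select_leaf_tip_width(
            cfg, dataset.profile_fields, dataset.profile_measurements,
            fixed, model, kernel, geometry)
    except Exception as exc:
        raise CommissioningError("leaf_tip_width", str(exc)) from exc

    fixed = replace(fixed, leaf_tip_width=tip_width)
    try:
        transmission, t_table = select_transmission(
            cfg, dataset.plans, dataset.planar_measurements, fixed, model,
            kernel, geometry)
    except Exception as exc:
        raise CommissioningError("transmission", str(exc)) from exc

    fixed = replace(fixed, transmission=transmission)
    try:
        tng, tng_table = select_tng_width(
            cfg, dataset.plans, dataset.planar_measurements, fixed, model,
            kernel, geometry)
    except Exception as exc:
        raise CommissioningError("tng_width", str(exc)) from exc

    params = MLCParameters(leaf_tip_width=tip_width, transmission=transmission,
                           tng_width=tng)
    provenance = {"config_digest": cfg.digest(), "seed": cfg.seed,
                  "n_plans": len(dataset.plans),
                  "n_profile_fields": len(dataset.profile_fields)}
    return CommissionReport(offset_model=model,
                            offset_r_squared=fit.r_squared,
                            parameters=params, tip_table=tip_table,
                            transmission_table=t_table, tng_table=tng_table,
                            provenance=provenance)
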