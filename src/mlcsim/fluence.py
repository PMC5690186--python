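"""MLC geometry and relative energy-fluence computation.

This module implements a step-function model of transmission through a
rounded-leaf-end multileaf collimator, as used by treatment planning systems
that parameterize the leaf end with a *leaf-tip width* rather than a
dosimetric leaf gap or tip radius:

* inside the aperture the relative fluence is 1;
* under the leaf body it is the average transmission factor ``T`` (a single
  factor subsuming intra- and inter-leaf leakage);
* in a band of width ``leaf_tip_width`` adjacent to each leaf tip -- the
  rounded end, modeled as having half the leaf thickness -- it is ``sqrt(T)``;
* tongue-and-groove is modeled as ``sqrt(T)`` bands of width ``tng_width``
  along cross-leaf boundaries, only where a leaf edge forms the aperture
  periphery (never where opposing leaf ends abut).

Leaf travel is along ``x`` (cm, isocenter projection); the cross-leaf axis is
``y``.  Planned leaf positions are *leaf-end* positions; the *leaf-tip*
position actually used for fluence is related to it by a fitted quadratic
offset polynomial (the vendor light-field offset table).

Fluence maps are rasterized with exact per-cell area averaging so that
sub-cell band widths have graded, monotone effects on a 2 mm grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

from .errors import AnalysisError, DataError

__all__ = [
    "OffsetModel",
    "OffsetFit",
    "MLCParameters",
    "LeafGeometry",
    "Jaws",
    "Aperture",
    "Segment",
    "Beam",
    "Plan",
    "GridSpec",
    "FluenceMap",
    "evaluate_tip_position",
    "fit_offset_model",
    "point_transmission",
    "segment_fluence_components",
    "compute_segment_fluence",
    "compute_plan_fluence",
    "compute_composite_fluence",
]


# ---------------------------------------------------------------------------
# leaf-tip offset model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OffsetModel:
    """Quadratic light-field offset between leaf-end and leaf-tip projections.

    ``offset_magnitude(x_end) = offset + gain * x_end + curvature * x_end**2``

    Parameters are in cm (offset), dimensionless (gain) and 1/cm (curvature).
    For a Varian-style rounded leaf end the fitted magnitude stays within
    0--0.35 cm over the +/-20 cm travel range.
    """

    offset: float = 0.0
    gain: float = 0.0
    curvature: float = 0.0

    def offset_magnitude(self, x_end):
        x = np.asarray(x_end, dtype=float)
        return self.offset + self.gain * x + self.curvature * x * x


def evaluate_tip_position(model: OffsetModel, x_end, travel_range=(-20.0, 20.0)):
    """Leaf-tip position for a leaf-end position, in the machine coordinate.

    This is the vendor-table convention: the offset magnitude is *added* to
    the leaf-end coordinate.  Fluence computation applies the magnitude
    toward the field opening per bank; see :func:`segment_fluence_components`.
    """
    x = np.asarray(x_end, dtype=float)
    lo, hi = travel_range
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise DataError(f"leaf-end position outside travel range [{lo}, {hi}] cm")
    out = x + model.offset_magnitude(x)
    return float(out) if np.isscalar(x_end) else out


@dataclass(frozen=True)
class OffsetFit:
    """Result of fitting the offset polynomial to a vendor-style table."""

    model: OffsetModel
    r_squared: float
    residuals: np.ndarray
    rmse: float


def fit_offset_model(table) -> OffsetFit:
    """Least-squares quadratic fit of geometric offset vs leaf-end position.

    ``table`` is a pandas DataFrame with columns ``x_end_cm`` / ``offset_cm``,
    or any iterable of ``(x_end, offset)`` pairs.  At least three distinct
    abscissae are required.
    """
    if hasattr(table, "columns"):
        x = np.asarray(table["x_end_cm"], dtype=float)
        y = np.asarray(table["offset_cm"], dtype=float)
    else:
        arr = np.asarray(list(table), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise DataError("offset table must be (x_end, offset) pairs")
        x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 3:
        raise DataError("offset fit needs at least 3 distinct leaf-end positions")
    c2, c1, c0 = np.polyfit(x, y, 2)
    model = OffsetModel(offset=float(c0), gain=float(c1), curvature=float(c2))
    pred = model.offset_magnitude(x)
    resid = y - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:  # constant table: perfect fit iff residuals vanish
        r2 = 1.0 if ss_res < 1e-18 else 0.0
    return OffsetFit(model=model, r_squared=r2, residuals=resid,
                     rmse=math.sqrt(ss_res / x.size))


# ---------------------------------------------------------------------------
# MLC parameters and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLCParameters:
    """The commissioned triple: tip-band width, average transmission, T&G width.

    ``transmission`` is a fraction in (0, 1); the half-thickness tip band
    transmits ``sqrt(transmission)``, which always exceeds it.
    """

    leaf_tip_width: float = 0.3   # cm
    transmission: float = 0.025   # fraction
    tng_width: float = 0.05       # cm

    def __post_init__(self):
        if not 0.0 < self.transmission < 1.0:
            raise DataError("transmission must be a fraction in (0, 1)")
        if self.leaf_tip_width < 0 or self.tng_width < 0:
            raise DataError("band widths must be non-negative")

    @property
    def tip_transmission(self) -> float:
        return math.sqrt(self.transmission)


@dataclass(frozen=True)
class LeafGeometry:
    """Projected leaf-pair widths along the cross-leaf axis, centered on 0."""

    pair_widths: tuple = ()
    travel_range: tuple = (-20.0, 20.0)

    def __post_init__(self):
        if not self.pair_widths:
            object.__setattr__(self, "pair_widths", self._millennium_widths())
        if any(w <= 0 for w in self.pair_widths):
            raise DataError("leaf widths must be positive")

    @staticmethod
    def _millennium_widths():
        # 120-leaf Millennium layout: 10 outer 1.0 cm, 40 central 0.5 cm, 10 outer
        return tuple([1.0] * 10 + [0.5] * 40 + [1.0] * 10)

    @classmethod
    def millennium120(cls) -> "LeafGeometry":
        return cls()

    @property
    def n_pairs(self) -> int:
        return len(self.pair_widths)

    @cached_property
    def boundaries(self) -> np.ndarray:
        """Cross-leaf boundary positions, length ``n_pairs + 1``."""
        edges = np.concatenate([[0.0], np.cumsum(self.pair_widths)])
        return edges - edges[-1] / 2.0

    @property
    def extent(self) -> float:
        return float(sum(self.pair_widths))

    def pair_of(self, y) -> np.ndarray:
        """Index of the pair covering each y (-1 outside the leaf bank)."""
        y = np.asarray(y, dtype=float)
        b = self.boundaries
        idx = np.searchsorted(b, y, side="right") - 1
        idx = np.where((y < b[0]) | (y >= b[-1]), -1, np.clip(idx, 0, self.n_pairs - 1))
        return idx


@dataclass(frozen=True)
class Jaws:
    """Secondary jaw openings (cm): the field spans [-x1, x2] x [-y1, y2]."""

    x1: float = 20.0
    x2: float = 20.0
    y1: float = 20.0
    y2: float = 20.0


@dataclass(frozen=True)
class Aperture:
    """Per-pair leaf-end positions for both banks, plus jaws.

    ``bank_a`` holds the left (negative-x side) leaf ends, ``bank_b`` the
    right; for every pair ``bank_a <= bank_b`` (abutted allowed).
    """

    bank_a: np.ndarray
    bank_b: np.ndarray
    jaws: Jaws = field(default_factory=Jaws)

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.bank_a, dtype=float))
        b = np.atleast_1d(np.asarray(self.bank_b, dtype=float))
        object.__setattr__(self, "bank_a", a)
        object.__setattr__(self, "bank_b", b)
        if a.shape != b.shape:
            raise DataError("bank_a and bank_b must have the same length")
        if np.any(b < a - 1e-9):
            raise DataError("every pair must satisfy bank_a <= bank_b")

    @property
    def n_pairs(self) -> int:
        return self.bank_a.size

    @classmethod
    def rectangle(cls, x1: float, x2: float, geometry: LeafGeometry | None = None,
                  jaws: Jaws | None = None) -> "Aperture":
        """MLC-defined rectangular field ``(X1, X2)``: bank A at ``-x1``, bank B at ``+x2``.

        A negative value means the corresponding bank travels over the central
        axis, e.g. ``(15, -5)`` spans x in [-15, -5].
        """
        geometry = geometry or LeafGeometry.millennium120()
        n = geometry.n_pairs
        if -x1 > x2:
            raise DataError("field (X1, X2) must satisfy -X1 <= X2")
        return cls(bank_a=np.full(n, -x1), bank_b=np.full(n, x2),
                   jaws=jaws or Jaws())

    def mirrored(self) -> "Aperture":
        """Reflection about the central axis x = 0."""
        j = self.jaws
        return Aperture(bank_a=-self.bank_b, bank_b=-self.bank_a,
                        jaws=Jaws(x1=j.x2, x2=j.x1, y1=j.y1, y2=j.y2))


@dataclass(frozen=True)
class Segment:
    aperture: Aperture
    mu: float  # monitor units

    def __post_init__(self):
        if self.mu < 0:
            raise DataError("MU weights must be non-negative")


@dataclass(frozen=True)
class Beam:
    segments: tuple
    name: str = ""

    def __post_init__(self):
        if not self.segments:
            raise DataError("a beam needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for s in self.segments))


@dataclass(frozen=True)
class Plan:
    beams: tuple
    name: str = ""
    energy: str = "6MV"

    def __post_init__(self):
        if not self.beams:
            raise DataError("a plan needs at least one beam")
        object.__setattr__(self, "beams", tuple(self.beams))

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))

    @property
    def n_segments(self) -> int:
        return sum(len(b.segments) for b in self.beams)

    def iter_segments(self):
        for beam in self.beams:
            yield from beam.segments


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Cell-centered 2D grid at the isocenter plane; ``origin`` is the first
    cell center and ``spacing`` applies to both axes (cm)."""

    origin_x: float
    origin_y: float
    spacing: float
    nx: int
    ny: int

    def __post_init__(self):
        if self.spacing <= 0:
            raise DataError("grid spacing must be positive")
        if self.nx < 1 or self.ny < 1:
            raise DataError("grid must have at least one cell per axis")

    @property
    def x(self) -> np.ndarray:
        return self.origin_x + self.spacing * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.origin_y + self.spacing * np.arange(self.ny)

    @property
    def shape(self):
        return (self.ny, self.nx)

    @classmethod
    def centered(cls, width: float, height: float, spacing: float = 0.2) -> "GridSpec":
        """Grid symmetric about the origin covering ``width x height`` cm."""
        nx = max(1, int(round(width / spacing)) + 1)
        ny = max(1, int(round(height / spacing)) + 1)
        return cls(origin_x=-(nx - 1) / 2.0 * spacing,
                   origin_y=-(ny - 1) / 2.0 * spacing,
                   spacing=spacing, nx=nx, ny=ny)


@dataclass(frozen=True)
class FluenceMap:
    """Relative energy fluence on a grid (open field = 1)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise DataError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# transmission / fluence
# ---------------------------------------------------------------------------

def _bank_tips(aperture: Aperture, model: OffsetModel):
    """Tip positions per pair, offset magnitude applied toward the opening."""
    tip_a = aperture.bank_a + model.offset_magnitude(aperture.bank_a)
    tip_b = aperture.bank_b - model.offset_magnitude(aperture.bank_b)
    return tip_a, tip_b


def point_transmission(aperture_row, params: MLCParameters, model: OffsetModel, x):
    """Transmission of a single leaf pair at position(s) ``x`` along travel.

    ``aperture_row`` is the ``(bank_a_end, bank_b_end)`` pair.  Returns 1 in
    the open interval between opposing tip positions, ``sqrt(T)`` in the tip
    band on the blocked side of each tip, and ``T`` deeper under the leaf.
    Half-open logic: the tip position itself belongs to the band, so abutted
    leaves expose no fully open point.
    """
    a, b = aperture_row
    tip_a = float(a + model.offset_magnitude(a))
    tip_b = float(b - model.offset_magnitude(b))
    w = params.leaf_tip_width
    xs = np.asarray(x, dtype=float)
    out = np.full(xs.shape, params.transmission)
    band = ((xs > tip_a - w) & (xs <= tip_a)) | ((xs >= tip_b) & (xs < tip_b + w))
    out[band] = params.tip_transmission
    out[(xs > tip_a) & (xs < tip_b)] = 1.0
    return float(out) if np.isscalar(x) else out


def _overlap(lo, hi, a, b):
    """Length of intersection of [lo, hi] with [a, b] (broadcasting)."""
    return np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None)


def segment_fluence_components(aperture: Aperture, leaf_tip_width: float,
                               tng_width: float, model: OffsetModel,
                               geometry: LeafGeometry, grid: GridSpec,
                               jaw_transmission: float = 0.0):
    """Area-averaged fluence decomposition ``F = A + B*T + C*sqrt(T)``.

    The step-function transmission is affine in ``(1, T, sqrt(T))`` for fixed
    band widths, which lets a transmission grid search reuse three component
    maps (and their dose convolutions) across candidates.
    """
    if aperture.n_pairs != geometry.n_pairs:
        raise DataError(
            f"aperture has {aperture.n_pairs} pairs, geometry {geometry.n_pairs}")
    lo, hi = geometry.travel_range
    if (np.any(aperture.bank_a < lo - 1e-9) or np.any(aperture.bank_b > hi + 1e-9)):
        raise DataError("leaf-end positions outside travel range")

    s = grid.spacing
    xl = grid.x - s / 2.0
    xr = grid.x + s / 2.0
    w = leaf_tip_width

    tip_a, tip_b = _bank_tips(aperture, model)
    ta = tip_a[:, None]
    tb = tip_b[:, None]

    # per-pair cell fractions along x  (n_pairs, nx)
    f_open = _overlap(xl, xr, ta, tb) / s
    ov1 = _overlap(xl, xr, ta - w, ta)
    ov2 = _overlap(xl, xr, tb, tb + w)
    # tip bands can overlap each other when leaves overtravel past one another
    ovi = _overlap(xl, xr, np.maximum(ta - w, tb), np.minimum(ta, tb + w))
    ovi = np.where(tip_a[:, None] > tip_b[:, None], ovi, 0.0)
    f_tip = np.clip((ov1 + ov2 - ovi) / s, 0.0, 1.0)
    f_tip = np.minimum(f_tip, 1.0 - f_open)

    idx = geometry.pair_of(grid.y)
    inside = idx >= 0
    fo = np.zeros((grid.ny, grid.nx))
    ft = np.zeros((grid.ny, grid.nx))
    fo[inside] = f_open[idx[inside]]
    ft[inside] = f_tip[idx[inside]]

    # tongue-and-groove: sqrt(T) bands inside the open region along cross-leaf
    # boundaries where the neighboring pair's leaf covers that x.  No band when
    # the neighbor's opposing leaves are closed on each other (abutted ends).
    tg = np.zeros((grid.ny, grid.nx))
    if tng_width > 0 and geometry.n_pairs > 1:
        yl = grid.y - s / 2.0
        yr = grid.y + s / 2.0
        bounds = geometry.boundaries
        open_width = tip_b - tip_a
        covered = 1.0 - f_open  # leaf (body or tip) covers this x-fraction
        for k in range(1, geometry.n_pairs):
            yb = bounds[k]
            for p_open, p_nb, b_lo, b_hi in (
                (k - 1, k, yb - tng_width, yb),
                (k, k - 1, yb, yb + tng_width),
            ):
                if open_width[p_nb] <= 1e-9:
                    continue  # closed neighbor: no interleaf leakage modeled
                if open_width[p_open] <= 1e-9:
                    continue
                fy = _overlap(yl, yr, b_lo, b_hi) / s
                if not np.any(fy > 0):
                    continue
                contrib = f_open[p_open] * covered[p_nb]
                tg += fy[:, None] * contrib[None, :]
        tg = np.minimum(tg, fo)

    # jaw shielding, area-weighted per axis
    j = aperture.jaws
    fx_in = _overlap(xl, xr, -j.x1, j.x2) / s
    fy_in = _overlap(grid.y - s / 2.0, grid.y + s / 2.0, -j.y1, j.y2) / s
    f_in = fy_in[:, None] * fx_in[None, :]

    A = f_in * (fo - tg) + (1.0 - f_in) * jaw_transmission
    B = f_in * (1.0 - fo - ft)
    C = f_in * (ft + tg)
    return A, B, C


def compute_segment_fluence(aperture: Aperture, params: MLCParameters,
                            model: OffsetModel, geometry: LeafGeometry,
                            grid: GridSpec, jaw_transmission: float = 0.0) -> FluenceMap:
    """Relative energy-fluence map of a single static aperture."""
    A, B, C = segment_fluence_components(
        aperture, params.leaf_tip_width, params.tng_width, model, geometry,
        grid, jaw_transmission)
    values = A + B * params.transmission + C * params.tip_transmission
    return FluenceMap(grid=grid, values=np.clip(values, 0.0, 1.0))


def compute_plan_fluence(plan: Plan, params: MLCParameters, model: OffsetModel,
                         geometry: LeafGeometry, grid: GridSpec,
                         jaw_transmission: float = 0.0) -> list[FluenceMap]:
    """MU-weighted, MU-normalized fluence map per beam."""
    out = []
    for beam in plan.beams:
        total = beam.total_mu
        if total <= 0:
            raise AnalysisError(f"beam {beam.name!r} has zero total MU")
        acc = np.zeros(grid.shape)
        for seg in beam.segments:
            f = compute_segment_fluence(seg.aperture, params, model, geometry,
                                        grid, jaw_transmission)
            acc += seg.mu * f.values
        out.append(FluenceMap(grid=grid, values=acc / total))
    return out


def compute_composite_fluence(plan: Plan, params: MLCParameters, model: OffsetModel,
                              geometry: LeafGeometry, grid: GridSpec,
                              jaw_transmission: float = 0.0) -> FluenceMap:
    """All beams collapsed to a single plane (gantry 0), normalized by plan MU."""
    total = plan.total_mu
    if total <= 0:
        raise AnalysisError("plan has zero total MU")
    acc = np.zeros(grid.shape)
    for seg in plan.iter_segments():
        f = compute_segment_fluence(seg.aperture, params, model, geometry,
                                    grid, jaw_transmission)
        acc += seg.mu * f.values
    return FluenceMap(grid=grid, values=acc / total)


def composite_fluence_components(plan: Plan, leaf_tip_width: float, tng_width: float,
                                 model: OffsetModel, geometry: LeafGeometry,
                                 grid: GridSpec, jaw_transmission: float = 0.0):
    """MU-weighted composite of :func:`segment_fluence_components` over a plan."""
    total = plan.total_mu
    if total <= 0:
        raise AnalysisError("plan has zero total MU")
    A = np.zeros(grid.shape)
    B = np.zeros(grid.shape)
    C = np.zeros(grid.shape)
    for seg in plan.iter_segments():
        a, b, c = segment_fluence_components(
            seg.aperture, leaf_tip_width, tng_width, model, geometry, grid,
            jaw_transmission)
        A += seg.mu * a
        B += seg.mu * b
        C += seg.mu * c
    return A / total, B / total, C / total
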