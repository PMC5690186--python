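"""Synthetic measurement generation with known ground truth.

Every input a clinic would obtain from hardware is emulated here so the full
commissioning chain is testable end to end: the vendor leaf-offset table, in-
water dmax transverse profiles of MLC-defined fields scanned with a small-
volume chamber, diode-array planar measurements of step-and-shoot plans, and
the plans themselves.  All generators are pure functions of their parameters
and a seed.

The packaged default truth is curvature 0.0008 /cm, leaf-tip width 0.3 cm,
average transmission 2.5%, tongue-and-groove width 0.05 cm -- a Varian
Millennium-120 style machine -- with 1% multiplicative measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter1d

from .errors import DataError
from .dose import BeamKernel, DoseMap, Profile, extract_profile, fluence_to_dose
from .fluence import (Aperture, Beam, GridSpec, Jaws, LeafGeometry,
                      MLCParameters, OffsetModel, Plan, Segment,
                      compute_composite_fluence, compute_segment_fluence)

__all__ = [
    "MachineTruth",
    "DetectorSpec",
    "CommissioningDataset",
    "make_offset_table",
    "paper_profile_fields",
    "profile_field_specs",
    "simulate_profile_measurement",
    "simulate_planar_measurement",
    "make_random_plan",
    "random_dose_pair",
    "make_commissioning_dataset",
    "write_commissioning_dataset",
    "load_commissioning_dataset",
    "profile_grid",
    "planar_grid",
]

# The six MLC-defined commissioning fields (X1, X2) in cm; a negative value
# means that bank travels over the central axis.  Cross-leaf extent 40 cm.
PROFILE_FIELD_SPECS = ((15.0, -5.0), (7.5, 7.5), (18.0, 0.0),
                       (5.0, 5.0), (-3.0, 10.0), (-10.0, 15.0))


@dataclass(frozen=True)
class MachineTruth:
    """Ground-truth machine model used to synthesize all measurements."""

    offset_model: OffsetModel = field(
        default_factory=lambda: OffsetModel(0.0, 0.0, 0.0008))
    mlc: MLCParameters = field(
        default_factory=lambda: MLCParameters(leaf_tip_width=0.3,
                                              transmission=0.025,
                                              tng_width=0.05))
    kernel: BeamKernel = field(default_factory=BeamKernel)
    noise_sigma: float = 0.01      # multiplicative measurement noise fraction
    detector_blur: float = 0.2     # cm; scanning-chamber volume averaging

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise DataError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class DetectorSpec:
    """Sampling, blur and noise model of a measurement device."""

    kind: str                      # 'scanning_chamber' or 'diode_array'
    sample_spacing: float          # cm
    blur_sigma: float = 0.0        # cm; aperture/volume averaging
    noise_fraction: float = 0.01   # multiplicative Gaussian fraction
    noise_floor: float = 0.001     # additive, as fraction of signal max
    extent: float = 26.0           # cm (square array side, diode arrays)

    def __post_init__(self):
        if self.sample_spacing <= 0:
            raise DataError("sample spacing must be positive")
        if self.kind not in ("scanning_chamber", "diode_array"):
            raise DataError("detector kind must be scanning_chamber or diode_array")

    @classmethod
    def chamber(cls, truth: MachineTruth) -> "DetectorSpec":
        # CC04-like: 4 mm collecting volume -> ~0.2 cm Gaussian blur
        return cls(kind="scanning_chamber", sample_spacing=0.1,
                   blur_sigma=truth.detector_blur,
                   noise_fraction=truth.noise_sigma)

    @classmethod
    def diode_array(cls, truth: MachineTruth) -> "DetectorSpec":
        # regular 0.5 cm grid over 26x26 cm (simplified planar diode array)
        return cls(kind="diode_array", sample_spacing=0.5, blur_sigma=0.0,
                   noise_fraction=truth.noise_sigma, extent=26.0)


def make_offset_table(model: OffsetModel, noise_sigma: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """Vendor-style table: offset vs leaf-end position, -20..+20 cm in 1 cm steps."""
    rng = np.random.default_rng(seed)
    x = np.arange(-20.0, 20.0 + 0.5, 1.0)
    offset = model.offset_magnitude(x)
    if noise_sigma > 0:
        offset = offset + rng.normal(0.0, noise_sigma, size=x.size)
    return pd.DataFrame({"x_end_cm": x, "offset_cm": offset})


def profile_field_specs():
    return PROFILE_FIELD_SPECS


def paper_profile_fields(geometry: LeafGeometry | None = None) -> list[Aperture]:
    """The six MLC-defined commissioning fields, jaws parked fully open."""
    geometry = geometry or LeafGeometry.millennium120()
    return [Aperture.rectangle(x1, x2, geometry, jaws=Jaws(20, 20, 20, 20))
            for x1, x2 in PROFILE_FIELD_SPECS]


def profile_grid(spacing: float = 0.2) -> GridSpec:
    """Narrow slab around the central row, wide enough in x for any field."""
    return GridSpec(origin_x=-22.0, origin_y=-7.0, spacing=spacing,
                    nx=int(round(44.0 / spacing)) + 1,
                    ny=int(round(14.0 / spacing)) + 1)


def planar_grid(det: DetectorSpec, margin: float = 2.0,
                spacing: float = 0.2) -> GridSpec:
    """Calculation grid covering a diode array with a convolution margin."""
    half = det.extent / 2.0 + margin
    n = int(round(2 * half / spacing)) + 1
    return GridSpec(origin_x=-half, origin_y=-half, spacing=spacing, nx=n, ny=n)


def _apply_noise(values: np.ndarray, det: DetectorSpec, rng) -> np.ndarray:
    noisy = values * (1.0 + rng.normal(0.0, det.noise_fraction, size=values.shape))
    floor = det.noise_floor * float(np.max(values))
    if floor > 0:
        noisy = noisy + rng.normal(0.0, floor, size=values.shape)
    return noisy


def simulate_profile_measurement(fld: Aperture, truth: MachineTruth,
                                 det: DetectorSpec, seed: int = 0,
                                 geometry: LeafGeometry | None = None,
                                 grid: GridSpec | None = None) -> Profile:
    """Scanned cross-field dose profile along leaf travel at the central axis.

    Dose is rendered from the truth parameters, blurred by the chamber volume,
    sampled at the scan spacing and degraded with multiplicative noise.
    """
    if det.kind != "scanning_chamber":
        raise DataError("profile scans require a scanning_chamber detector")
    rng = np.random.default_rng(seed)
    geometry = geometry or LeafGeometry.millennium120()
    grid = grid or profile_grid()
    f = compute_segment_fluence(fld, truth.mlc, truth.offset_model, geometry, grid)
    dose = fluence_to_dose(f, truth.kernel)
    line = extract_profile(dose, axis="x", offset=0.0)
    values = line.values
    if det.blur_sigma > 0:
        values = gaussian_filter1d(values, det.blur_sigma / grid.spacing,
                                   mode="nearest")
    lo, hi = grid.x[0] + 1.0, grid.x[-1] - 1.0
    n = int(np.floor((hi - lo) / det.sample_spacing)) + 1
    positions = lo + det.sample_spacing * np.arange(n)
    sampled = np.interp(positions, line.positions, values)
    return Profile(positions=positions, values=_apply_noise(sampled, det, rng),
                   axis="x", offset=0.0)


def simulate_planar_measurement(plan: Plan, truth: MachineTruth,
                                det: DetectorSpec, seed: int = 0,
                                geometry: LeafGeometry | None = None,
                                grid: GridSpec | None = None,
                                calibration_sigma: float = 0.003) -> DoseMap:
    """Gantry-collapsed composite planar dose on the diode-array grid.

    A per-session calibration factor drawn near 1 emulates the daily 10x10
    output normalization; diode noise is multiplicative plus a small floor.
    """
    if det.kind != "diode_array":
        raise DataError("planar measurements require a diode_array detector")
    rng = np.random.default_rng(seed)
    geometry = geometry or LeafGeometry.millennium120()
    grid = grid or planar_grid(det)
    f = compute_composite_fluence(plan, truth.mlc, truth.offset_model,
                                  geometry, grid)
    dose = fluence_to_dose(f, truth.kernel)
    n = int(round(det.extent / det.sample_spacing)) + 1
    coords = -det.extent / 2.0 + det.sample_spacing * np.arange(n)
    interp = RegularGridInterpolator((grid.y, grid.x), dose.values,
                                     method="linear")
    gx, gy = np.meshgrid(coords, coords)
    sampled = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(n, n)
    calibration = 1.0 + (rng.normal(0.0, calibration_sigma)
                         if calibration_sigma > 0 else 0.0)
    noisy = _apply_noise(sampled * calibration, det, rng)
    meas_grid = GridSpec(origin_x=coords[0], origin_y=coords[0],
                         spacing=det.sample_spacing, nx=n, ny=n)
    return DoseMap(grid=meas_grid, values=np.clip(noisy, 0.0, None))


def make_random_plan(n_beams: int = 7, n_segments: int = 40,
                     field_extent: float = 12.0, seed: int = 0,
                     geometry: LeafGeometry | None = None,
                     name: str = "") -> Plan:
    """Random step-and-shoot plan with connected, modulated apertures.

    Each segment opens a random-walk strip of 0.5--4 cm per leaf pair inside
    ``field_extent``, giving composite modulation typical of clinical IMRT
    (each point open for a minority of the delivered MU).  ``n_segments`` is
    the plan total, spread evenly over the beams.
    """
    if n_beams < 1 or n_segments < 1:
        raise DataError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    geometry = geometry or LeafGeometry.millennium120()
    half = field_extent / 2.0
    centers = 0.5 * (geometry.boundaries[:-1] + geometry.boundaries[1:])
    active = np.abs(centers) <= half
    jaws = Jaws(x1=half + 1.0, x2=half + 1.0,
                y1=min(half, geometry.extent / 2.0),
                y2=min(half, geometry.extent / 2.0))
    park_a = park_b = -half - 2.0  # abutted outside the x jaws

    per_beam = [n_segments // n_beams] * n_beams
    for i in range(n_segments - sum(per_beam)):
        per_beam[i] += 1

    beams = []
    for b in range(n_beams):
        segments = []
        for _ in range(max(1, per_beam[b])):
            left = np.full(geometry.n_pairs, park_a)
            right = np.full(geometry.n_pairs, park_b)
            gap = rng.uniform(0.5, 4.0)
            center = rng.uniform(-half + gap / 2.0 + 0.25, half - gap / 2.0 - 0.25)
            idxs = np.flatnonzero(active)
            for i in idxs:
                center += rng.normal(0.0, 0.4)
                gap = float(np.clip(gap + rng.normal(0.0, 0.4), 0.5, 4.0))
                center = float(np.clip(center, -half + gap / 2.0, half - gap / 2.0))
                left[i] = center - gap / 2.0
                right[i] = center + gap / 2.0
            segments.append(Segment(aperture=Aperture(left, right, jaws),
                                    mu=float(rng.uniform(2.0, 10.0))))
        beams.append(Beam(segments=tuple(segments), name=f"beam{b + 1}"))
    return Plan(beams=tuple(beams), name=name or f"random-{seed}")


def random_dose_pair(seed: int = 0, n: int = 30, spacing: float = 0.5,
                     perturbation: float = 0.02, shift: float = 0.1):
    """A smooth reference dose map and a slightly perturbed evaluated copy.

    The reference is a normalized sum of Gaussian blobs over a pedestal; the
    evaluated map is the same analytic field rigidly shifted by up to
    ``shift`` cm and modulated by a smooth multiplicative ripple of relative
    amplitude ``perturbation`` -- the disagreement structure (regional dose
    deviations plus a setup shift) typical of planar QA comparisons.  Grid
    origins land on a 0.5 mm lattice.
    """
    rng = np.random.default_rng(seed)
    g = GridSpec(origin_x=-(n - 1) / 2.0 * spacing,
                 origin_y=-(n - 1) / 2.0 * spacing,
                 spacing=spacing, nx=n, ny=n)
    half = (n - 1) / 2.0 * spacing
    blobs = [(rng.uniform(-half / 2, half / 2, 2), rng.uniform(1.5, 4.0),
              rng.uniform(0.2, 1.0)) for _ in range(6)]
    phases = rng.uniform(0.0, 2 * np.pi, 2)
    dx, dy = rng.uniform(-shift, shift, 2)

    def render(ox, oy):
        xx, yy = np.meshgrid(g.x, g.y)
        field = np.full((n, n), 0.1)
        for (cx, cy), s, a in blobs:
            field += a * np.exp(-(((xx - ox) - cx) ** 2
                                  + ((yy - oy) - cy) ** 2) / (2 * s * s))
        return field / field.max()

    ref = render(0.0, 0.0)
    xx, yy = np.meshgrid(g.x, g.y)
    ripple = 1.0 + perturbation * np.sin(xx / 2.0 + phases[0]) \
        * np.cos(yy / 3.0 + phases[1])
    ev = render(dx, dy) * ripple
    return DoseMap(g, ref), DoseMap(g, ev)


@dataclass(frozen=True)
class CommissioningDataset:
    """Everything the commissioning workflow consumes, with truth on the side."""

    offset_table: pd.DataFrame
    profile_fields: list
    profile_measurements: list
    plans: list
    planar_measurements: list
    geometry: LeafGeometry
    kernel: BeamKernel
    truth: MachineTruth
    seed: int = 0


def make_commissioning_dataset(truth: MachineTruth | None = None, seed: int = 0,
                               n_plans: int = 5,
                               geometry: LeafGeometry | None = None
                               ) -> CommissioningDataset:
    """Bundle the offset table, six profile scans and ``n_plans`` QA sessions.

    The offset table is noise-free (it emulates a digital vendor table);
    profile and planar measurements carry the truth's noise model.  Plan
    shapes straddle clinical step-and-shoot statistics (6--14 beams, 25--50
    segments per plan).
    """
    truth = truth or MachineTruth()
    geometry = geometry or LeafGeometry.millennium120()
    rng = np.random.default_rng(seed)

    offset_table = make_offset_table(truth.offset_model, noise_sigma=0.0,
                                     seed=int(rng.integers(2**31)))
    chamber = DetectorSpec.chamber(truth)
    fields = paper_profile_fields(geometry)
    profiles = [simulate_profile_measurement(
        fld, truth, chamber, seed=int(rng.integers(2**31)), geometry=geometry)
        for fld in fields]

    array = DetectorSpec.diode_array(truth)
    plans, measurements = [], []
    beam_counts = [7, 8, 6, 7, 14, 9, 11, 6]
    seg_counts = [25, 41, 50, 50, 50, 35, 30, 45]
    for i in range(n_plans):
        plan = make_random_plan(n_beams=beam_counts[i % len(beam_counts)],
                                n_segments=seg_counts[i % len(seg_counts)],
                                field_extent=12.0,
                                seed=int(rng.integers(2**31)),
                                geometry=geometry, name=f"plan{i + 1}")
        plans.append(plan)
        measurements.append(simulate_planar_measurement(
            plan, truth, array, seed=int(rng.integers(2**31)),
            geometry=geometry))
    return CommissioningDataset(offset_table=offset_table,
                                profile_fields=fields,
                                profile_measurements=profiles,
                                plans=plans,
                                planar_measurements=measurements,
                                geometry=geometry, kernel=truth.kernel,
                                truth=truth, seed=seed)


def write_commissioning_dataset(dataset: CommissioningDataset, out_dir) -> Path:
    """Write the bundle to disk in the package's CSV/JSON interchange formats."""
    from . import io as mio

    out = Path(out_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    (out / "plans").mkdir(exist_ok=True)
    (out / "measurements").mkdir(exist_ok=True)
    dataset.offset_table.to_csv(out / "offset_table.csv", index=False)
    manifest = {"schema_version": 1, "seed": dataset.seed,
                "offset_table": "offset_table.csv",
                "profiles": [], "plans": [], "measurements": [],
                "profile_fields": [list(spec) for spec in PROFILE_FIELD_SPECS]}
    for i, prof in enumerate(dataset.profile_measurements):
        rel = f"profiles/profile_{i:02d}.csv"
        mio.write_profile(out / rel, prof, meta={"field_index": i})
        manifest["profiles"].append(rel)
    for i, (plan, meas) in enumerate(zip(dataset.plans,
                                         dataset.planar_measurements)):
        prel = f"plans/plan_{i:02d}.json"
        mrel = f"measurements/meas_{i:02d}.csv"
        mio.write_plan(out / prel, plan)
        mio.write_grid(out / mrel, meas)
        manifest["plans"].append(prel)
        manifest["measurements"].append(mrel)
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    truth = {"offset_model": asdict(dataset.truth.offset_model),
             "mlc": asdict(dataset.truth.mlc),
             "kernel": asdict(dataset.truth.kernel),
             "noise_sigma": dataset.truth.noise_sigma,
             "detector_blur": dataset.truth.detector_blur}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out


def load_commissioning_dataset(data_dir) -> CommissioningDataset:
    """Load a dataset written by :func:`write_commissioning_dataset`."""
    from . import io as mio

    data = Path(data_dir)
    manifest = json.loads((data / "MANIFEST.json").read_text())
    offset_table = pd.read_csv(data / manifest["offset_table"])
    geometry = LeafGeometry.millennium120()
    fields = [Aperture.rectangle(x1, x2, geometry, jaws=Jaws(20, 20, 20, 20))
              for x1, x2 in manifest["profile_fields"]]
    profiles = [mio.read_profile(data / rel) for rel in manifest["profiles"]]
    plans = [mio.read_plan(data / rel) for rel in manifest["plans"]]
    measurements = [mio.read_grid(data / rel, kind="dose")
                    for rel in manifest["measurements"]]
    truth = MachineTruth()
    tpath = data / "truth.json"
    if tpath.exists():
        t = json.loads(tpath.read_text())
        truth = MachineTruth(offset_model=OffsetModel(**t["offset_model"]),
                             mlc=MLCParameters(**t["mlc"]),
                             kernel=BeamKernel(**t["kernel"]),
                             noise_sigma=t["noise_sigma"],
                             detector_blur=t["detector_blur"])
    return CommissioningDataset(offset_table=offset_table,
                                profile_fields=fields,
                                profile_measurements=profiles,
                                plans=plans, planar_measurements=measurements,
                                geometry=geometry, kernel=truth.kernel,
                                truth=truth,
                                seed=int(manifest.get("seed", 0)))
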