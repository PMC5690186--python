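"""Readers and writers for the package's plain-text interchange formats.

* Plans: JSON -- beams -> segments -> {mu_weight, bank_a, bank_b, jaws};
  leaf positions are leaf-END positions (the planned/stored coordinate), in
  cm at the isocenter plane.
* Fluence/dose grids: CSV with a 4-line ``#``-prefixed header carrying
  origin, spacing and shape, followed by row-major values.
* Profiles: two-column CSV (position_cm, value) with ``#`` metadata lines.
* Offset tables: two-column CSV (x_end_cm, offset_cm) with a header row,
  mirroring the vendor table content.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .dose import DoseMap, Profile
from .fluence import (Aperture, Beam, FluenceMap, GridSpec, Jaws, Plan,
                      Segment)

__all__ = [
    "read_plan", "write_plan",
    "read_grid", "write_grid",
    "read_profile", "write_profile",
    "read_offset_table", "write_offset_table",
]

PLAN_SCHEMA_VERSION = 1


def write_plan(path, plan: Plan) -> None:
    doc = {
        "schema_version": PLAN_SCHEMA_VERSION,
        "name": plan.name,
        "energy": plan.energy,
        "beams": [
            {
                "name": beam.name,
                "segments": [
                    {
                        "mu_weight": seg.mu,
                        "bank_a": [float(v) for v in seg.aperture.bank_a],
                        "bank_b": [float(v) for v in seg.aperture.bank_b],
                        "jaws": {"x1": seg.aperture.jaws.x1,
                                 "x2": seg.aperture.jaws.x2,
                                 "y1": seg.aperture.jaws.y1,
                                 "y2": seg.aperture.jaws.y2},
                    }
                    for seg in beam.segments
                ],
            }
            for beam in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _require(cond: bool, where: str, message: str) -> None:
    if not cond:
        raise DataError(f"{where}: {message}")


def read_plan(path, n_pairs: int = 60) -> Plan:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"{path}: not valid JSON ({exc})") from exc
    _require(doc.get("schema_version") == PLAN_SCHEMA_VERSION, "schema_version",
             f"expected {PLAN_SCHEMA_VERSION}")
    _require(bool(doc.get("beams")), "beams", "plan must contain beams")
    beams = []
    for bi, b in enumerate(doc["beams"]):
        segs = []
        _require(bool(b.get("segments")), f"beams[{bi}].segments",
                 "beam must contain segments")
        for si, s in enumerate(b["segments"]):
            where = f"beams[{bi}].segments[{si}]"
            mu = s.get("mu_weight")
            _require(isinstance(mu, (int, float)) and mu >= 0, where + ".mu_weight",
                     "must be a non-negative number")
            for bank in ("bank_a", "bank_b"):
                _require(isinstance(s.get(bank), list)
                         and len(s[bank]) == n_pairs, where + f".{bank}",
                         f"must hold exactly {n_pairs} leaf positions")
            jaws = s.get("jaws", {})
            _require(all(k in jaws for k in ("x1", "x2", "y1", "y2")),
                     where + ".jaws", "must define x1, x2, y1, y2")
            try:
                ap = Aperture(bank_a=np.array(s["bank_a"], dtype=float),
                              bank_b=np.array(s["bank_b"], dtype=float),
                              jaws=Jaws(**{k: float(jaws[k]) for k in
                                           ("x1", "x2", "y1", "y2")}))
            except DataError as exc:
                raise DataError(f"{where}: {exc}") from exc
            segs.append(Segment(aperture=ap, mu=float(mu)))
        beams.append(Beam(segments=tuple(segs), name=b.get("name", f"beam{bi + 1}")))
    return Plan(beams=tuple(beams), name=doc.get("name", ""),
                energy=doc.get("energy", "6MV"))


def write_grid(path, grid_map) -> None:
    g = grid_map.grid
    header = (f"# origin_x_cm: {g.origin_x:.12g}\n"
              f"# origin_y_cm: {g.origin_y:.12g}\n"
              f"# spacing_cm: {g.spacing:.12g}\n"
              f"# shape: {g.ny} {g.nx}\n")
    body = "\n".join(",".join(f"{v:.12g}" for v in row)
                     for row in grid_map.values)
    Path(path).write_text(header + body + "\n")


def read_grid(path, kind: str = "dose"):
    lines = Path(path).read_text().splitlines()
    if len(lines) < 5:
        raise DataError(f"{path}: grid file too short")
    meta = {}
    for line in lines[:4]:
        if not line.startswith("# ") or ":" not in line:
            raise DataError(f"{path}: malformed grid header line {line!r}")
        key, _, val = line[2:].partition(":")
        meta[key.strip()] = val.strip()
    try:
        ny, nx = (int(v) for v in meta["shape"].split())
        grid = GridSpec(origin_x=float(meta["origin_x_cm"]),
                        origin_y=float(meta["origin_y_cm"]),
                        spacing=float(meta["spacing_cm"]), nx=nx, ny=ny)
    except (KeyError, ValueError) as exc:
        raise DataError(f"{path}: invalid grid header ({exc})") from exc
    values = np.array([[float(v) for v in line.split(",")]
                       for line in lines[4:] if line.strip()])
    if values.shape != (ny, nx):
        raise DataError(f"{path}: payload shape {values.shape} does not match "
                        f"header shape {(ny, nx)}")
    cls = DoseMap if kind == "dose" else FluenceMap
    return cls(grid=grid, values=values)


def write_profile(path, profile: Profile, meta: dict | None = None) -> None:
    lines = [f"# axis: {profile.axis}", f"# offset_cm: {profile.offset:.12g}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("position_cm,value")
    lines.extend(f"{p:.12g},{v:.12g}"
                 for p, v in zip(profile.positions, profile.values))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> Profile:
    axis, offset = "x", 0.0
    positions, values = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key = key.strip()
            if key == "axis":
                axis = val.strip()
            elif key == "offset_cm":
                offset = float(val)
            continue
        if not line.strip() or line.startswith("position_cm"):
            continue
        p, v = line.split(",")
        positions.append(float(p))
        values.append(float(v))
    if not positions:
        raise DataError(f"{path}: empty profile")
    return Profile(positions=np.array(positions), values=np.array(values),
                   axis=axis, offset=offset)


def write_offset_table(path, table: pd.DataFrame) -> None:
    table[["x_end_cm", "offset_cm"]].to_csv(path, index=False)


def read_offset_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"x_end_cm", "offset_cm"}.issubset(df.columns):
        raise DataError(f"{path}: offset table needs columns x_end_cm, offset_cm")
    return df
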