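"""Static 3D point-cloud scenes: cells with markers plus reference geometry.

A :class:`SceneFrame` is the substrate for density, nearest-neighbour and
label-fraction analyses.  Cell positions are in micrometres, (x, y, z) order.
Regions are closed sets: a point exactly on the boundary is inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CELL_COLUMNS = ("cell_id", "x_um", "y_um", "z_um")


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sphere:
    """Closed ball with center (x, y, z) in µm and radius in µm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(points - np.asarray(self.center), axis=1)
        return d <= self.radius

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def translated(self, offset) -> "Sphere":
        c = tuple(np.asarray(self.center, dtype=float) + np.asarray(offset, dtype=float))
        return Sphere(c, self.radius)

    def to_dict(self) -> dict:
        return {"type": "sphere", "center": list(map(float, self.center)),
                "radius": float(self.radius)}


@dataclass(frozen=True)
class Box:
    """Closed axis-aligned box [lo, hi] in µm, (x, y, z) order."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        if not np.all(np.asarray(self.hi) > np.asarray(self.lo)):
            raise ValueError("box must have hi > lo on every axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((points >= lo) & (points <= hi), axis=1)

    @property
    def volume(self) -> float:
        return float(np.prod(np.asarray(self.hi) - np.asarray(self.lo)))

    def translated(self, offset) -> "Box":
        off = np.asarray(offset, dtype=float)
        return Box(tuple(np.asarray(self.lo) + off), tuple(np.asarray(self.hi) + off))

    def to_dict(self) -> dict:
        return {"type": "box", "lo": list(map(float, self.lo)),
                "hi": list(map(float, self.hi))}


@dataclass(frozen=True)
class MaskRegion:
    """Voxelised region: boolean mask in (z, y, x) axis order with voxel size.

    ``origin`` is the world coordinate (x, y, z) of the corner of voxel
    (0, 0, 0); a point maps to the voxel containing it.
    """

    mask: np.ndarray
    voxel_size: tuple[float, float, float]  # (z, y, x) µm / voxel
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z) µm

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        vz, vy, vx = self.voxel_size
        rel = points - np.asarray(self.origin)
        idx = np.floor(rel / np.array([vx, vy, vz])).astype(int)  # (x,y,z) indices
        nz, ny, nx = self.mask.shape
        ok = ((idx[:, 0] >= 0) & (idx[:, 0] < nx) & (idx[:, 1] >= 0)
              & (idx[:, 1] < ny) & (idx[:, 2] >= 0) & (idx[:, 2] < nz))
        out = np.zeros(len(points), dtype=bool)
        out[ok] = self.mask[idx[ok, 2], idx[ok, 1], idx[ok, 0]]
        return out

    @property
    def volume(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.voxel_size))


Region = Sphere | Box | MaskRegion


def region_from_dict(d: dict) -> Region:
    kind = d.get("type")
    if kind == "sphere":
        return Sphere(tuple(d["center"]), float(d["radius"]))
    if kind == "box":
        return Box(tuple(d["lo"]), tuple(d["hi"]))
    raise ValueError(f"unknown region type {kind!r}")


# ---------------------------------------------------------------------------
# SceneFrame
# ---------------------------------------------------------------------------


@dataclass
class SceneFrame:
    """A static point cloud of cell centers with categorical markers.

    ``cells`` holds one row per cell with columns ``cell_id, x_um, y_um, z_um``;
    any further boolean column is a marker, and columns prefixed ``intensity_``
    are per-cell channel intensities.
    """

    cells: pd.DataFrame
    regions: dict[str, Region] = field(default_factory=dict)
    dc_center: tuple[float, float, float] | None = None
    bead: Sphere | None = None
    placode_mesh: tuple[np.ndarray, np.ndarray] | None = None  # vertices, faces

    def __post_init__(self):
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cells table missing columns: {missing}")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell ids must be unique")
        pos = self.positions
        if len(pos) and not np.all(np.isfinite(pos)):
            raise ValueError("cell positions must be finite")

    @property
    def positions(self) -> np.ndarray:
        return self.cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    @property
    def marker_names(self) -> list[str]:
        skip = set(CELL_COLUMNS)
        return [c for c in self.cells.columns
                if c not in skip and not c.startswith("intensity_")
                and self.cells[c].dtype == bool]

    def with_marker(self, marker: str) -> pd.DataFrame:
        if marker not in self.cells.columns:
            raise KeyError(f"unknown marker {marker!r}")
        return self.cells[self.cells[marker].astype(bool)]

    def in_region(self, region: str | Region) -> np.ndarray:
        """Boolean mask over cells for a named or explicit region."""
        if isinstance(region, str):
            try:
                region = self.regions[region]
            except KeyError:
                raise KeyError(f"scene has no region named {region!r}") from None
        return region.contains(self.positions)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        cells = []
        for _, row in self.cells.iterrows():
            rec = {"id": row["cell_id"],
                   "position": [float(row["x_um"]), float(row["y_um"]), float(row["z_um"])]}
            markers = {m: bool(row[m]) for m in self.marker_names}
            if markers:
                rec["markers"] = markers
            intens = {c[len("intensity_"):]: float(row[c])
                      for c in self.cells.columns if c.startswith("intensity_")}
            if intens:
                rec["intensity"] = intens
            cells.append(rec)
        doc = {"cells": cells,
               "regions": {k: r.to_dict() for k, r in self.regions.items()
                           if not isinstance(r, MaskRegion)},
               "references": {}}
        if self.dc_center is not None:
            doc["references"]["dc_center"] = list(map(float, self.dc_center))
        if self.bead is not None:
            doc["references"]["bead"] = self.bead.to_dict()
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneFrame":
        doc = json.loads(Path(path).read_text())
        rows = []
        for rec in doc["cells"]:
            row = {"cell_id": rec["id"], "x_um": rec["position"][0],
                   "y_um": rec["position"][1], "z_um": rec["position"][2]}
            for m, v in rec.get("markers", {}).items():
                row[m] = bool(v)
            for ch, v in rec.get("intensity", {}).items():
                row[f"intensity_{ch}"] = float(v)
            rows.append(row)
        cells = pd.DataFrame(rows)
        for c in cells.columns:
            if c not in CELL_COLUMNS and not c.startswith("intensity_"):
                cells[c] = cells[c].fillna(False).astype(bool)
        regions = {k: region_from_dict(d) for k, d in doc.get("regions", {}).items()}
        refs = doc.get("references", {})
        dc_center = tuple(refs["dc_center"]) if "dc_center" in refs else None
        bead = None
        if "bead" in refs:
            b = refs["bead"]
            bead = Sphere(tuple(b["center"]), float(b["radius"]))
        return cls(cells=cells, regions=regions, dc_center=dc_center, bead=bead)
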