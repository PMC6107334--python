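"""3D morphometry on segmented-nucleus label volumes.

Volumes are voxel counts scaled by the physical voxel size; surface areas come
from a triangulated isosurface: the binary object is lightly smoothed (1-voxel
Gaussian) and triangulated by marching cubes at the 0.5 level with anisotropic
voxel spacing applied before triangulation.  This is far more accurate than
voxel-face counting — face counting overestimates sphere areas by ~1.5x, and
even a raw binary marching-cubes surface by ~9%, which would corrupt
sphericity.  Sphericity follows Wadell:

    psi = pi^(1/3) * (6 V)^(2/3) / A

which is 1 for a perfect sphere and decreases with elongation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .results import TestResult

# Estimator tolerance: the triangulated isosurface of a rasterized object can
# exceed/undershoot the true area by a few percent at moderate radii, so
# digital-sphere sphericities may slightly exceed 1.
SPHERICITY_EPS = 0.05

__all__ = ["LabelVolume", "ShapeReport", "sphericity", "measure_objects",
           "region_mean_intensity", "compare_shape_groups"]


@dataclass
class LabelVolume:
    """Integer label volume in (z, y, x) axis order with physical voxel size.

    0 is background; labels are positive integers.  ``voxel_size`` is
    (z, y, x) in µm/voxel.  ``meta`` may record border-touching labels and
    provenance.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z) µm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label volume must be 3D (z, y, x)")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive on all axes")

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.voxels)
        return lab[lab > 0]


@dataclass
class ShapeReport:
    """Per-object morphometry: volume (µm^3), surface area (µm^2), Wadell
    sphericity, centroid (x, y, z µm) and border/exclusion flags."""

    table: pd.DataFrame

    def included(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]


def sphericity(volume_um3: float, area_um2: float) -> float:
    """Wadell sphericity pi^(1/3) (6V)^(2/3) / A; 1 for a perfect sphere."""
    if volume_um3 <= 0 or area_um2 <= 0:
        raise ValueError("volume and area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_um3) ** (2.0 / 3.0)
                 / area_um2)


def measure_objects(
    volume: LabelVolume,
    include_border: bool = False,
    min_extent_voxels: int = 2,
) -> ShapeReport:
    """Measure volume, surface area and sphericity of every labeled object.

    Objects touching the volume border have undefined surface area and are
    flagged (and excluded from group statistics) unless ``include_border`` is
    set; objects narrower than ``min_extent_voxels`` on any axis are
    sub-resolution and always excluded.
    """
    labels = volume.labels
    if len(labels) == 0:
        raise ValueError("label volume has no foreground objects")
    vz, vy, vx = volume.voxel_size
    aniso = max(volume.voxel_size) / min(volume.voxel_size)
    if aniso > 5:
        warnings.warn(f"voxel anisotropy ratio {aniso:.1f} > 5; surface-area "
                      "estimation degrades", stacklevel=2)
    voxel_vol = vz * vy * vx
    slices = ndimage.find_objects(volume.voxels)
    shape = np.array(volume.voxels.shape)

    rows = []
    for lab in labels:
        sl = slices[int(lab) - 1]
        if sl is None:
            continue
        sub = volume.voxels[sl] == lab
        n_vox = int(sub.sum())
        vol_um3 = n_vox * voxel_vol
        com = ndimage.center_of_mass(sub)
        centroid_zyx = [com[i] + sl[i].start + 0.5 for i in range(3)]
        centroid_um = (centroid_zyx[2] * vx + volume.origin[0],
                       centroid_zyx[1] * vy + volume.origin[1],
                       centroid_zyx[0] * vz + volume.origin[2])
        border = any(sl[i].start == 0 or sl[i].stop == shape[i] for i in range(3))
        sub_res = any(s < min_extent_voxels for s in sub.shape)
        area = np.nan
        sph = np.nan
        reason = ""
        if sub_res:
            reason = "sub_resolution"
        else:
            padded = ndimage.gaussian_filter(np.pad(sub, 2).astype(float),
                                             sigma=1.0)
            verts, faces, _, _ = measure.marching_cubes(
                padded, level=0.5, spacing=(vz, vy, vx))
            area = float(measure.mesh_surface_area(verts, faces))
            sph = sphericity(vol_um3, area)
            if border and not include_border:
                reason = "border_touching"
        rows.append({"label": int(lab), "n_voxels": n_vox,
                     "volume_um3": vol_um3, "surface_area_um2": area,
                     "sphericity": sph,
                     "centroid_x_um": centroid_um[0],
                     "centroid_y_um": centroid_um[1],
                     "centroid_z_um": centroid_um[2],
                     "border_touching": border,
                     "excluded": bool(reason), "exclusion_reason": reason})
    return ShapeReport(table=pd.DataFrame(rows))


def region_mean_intensity(
    intensity: np.ndarray,
    voxel_size: tuple[float, float, float],
    objects,
) -> pd.DataFrame:
    """Mean intensity inside each labeled object or named region.

    ``objects`` is a :class:`LabelVolume` congruent with the intensity grid,
    or a mapping name -> region (sphere/box, evaluated at voxel centers).
    Supports the paired design where a condensate region is cloned onto a
    control interfollicular location: simply pass both regions.
    """
    intensity = np.asarray(intensity, dtype=float)
    if isinstance(objects, LabelVolume):
        if objects.voxels.shape != intensity.shape:
            raise ValueError("label and intensity grids are not congruent")
        labels = objects.labels
        means = ndimage.mean(intensity, labels=objects.voxels, index=labels)
        return pd.DataFrame({"object": labels.astype(int),
                             "mean_intensity": means})
    vz, vy, vx = voxel_size
    nz, ny, nx = intensity.shape
    zc = (np.arange(nz) + 0.5) * vz
    yc = (np.arange(ny) + 0.5) * vy
    xc = (np.arange(nx) + 0.5) * vx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rows = []
    for name, region in objects.items():
        mask = region.contains(pts).reshape(intensity.shape)
        if not mask.any():
            raise ValueError(f"region {name!r} contains no voxels")
        rows.append({"object": name,
                     "mean_intensity": float(intensity[mask].mean())})
    return pd.DataFrame(rows)


def compare_shape_groups(report: ShapeReport, grouping: dict) -> TestResult:
    """Two-group comparison of sphericity (e.g. condensate vs interfollicular
    nuclei) via the normality-gated adaptive location test."""
    from .assays import adaptive_location_test

    tab = report.included()
    tab = tab[tab["label"].isin(grouping.keys())]
    groups = tab.assign(group=tab["label"].map(grouping)).groupby("group")
    values = {g: sub["sphericity"].to_numpy(dtype=float) for g, sub in groups}
    if len(values) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(values)}")
    (ga, xa), (gb, xb) = sorted(values.items())
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 objects per group")
    res = adaptive_location_test(xa, xb)
    res.extra.update({
        f"median_{ga}": float(np.median(xa)),
        f"median_{gb}": float(np.median(xb)),
        "median_difference": float(np.median(xa) - np.median(xb)),
    })
    return res
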