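"""Density, distance, nearest-neighbour and label-fraction analyses over
point-cloud scenes.

Densities are reported in cells per 10^4 µm^3 (volumes) or per 10^4 µm^2
(optical-slice mode); all geometry is in micrometres.  Regions are closed:
boundary points count as inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .results import TestResult
from .scene import MaskRegion, Region, SceneFrame, Sphere

DENSITY_UNIT = 1e4  # densities are per 10^4 µm^3 (or µm^2 in slice mode)

__all__ = [
    "DensityReport",
    "NeighborReport",
    "region_density",
    "shell_density",
    "distances_to_surface",
    "distances_to_point",
    "nearest_neighbor_labels",
    "neighbor_randomness_test",
    "label_fraction",
    "fucci_fractions",
    "marker_enrichment_test",
]


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------


@dataclass
class DensityReport:
    """Per-region cell counts, volumes/areas and densities, with pairwise
    density ratios keyed ``"a/b"``."""

    table: pd.DataFrame  # region, count, volume, density
    ratios: dict[str, float] = field(default_factory=dict)
    unit: str = f"cells per {DENSITY_UNIT:.0f} um^3"

    def density(self, region: str) -> float:
        row = self.table[self.table["region"] == region]
        if len(row) == 0:
            raise KeyError(f"no region {region!r} in report")
        return float(row["density"].iloc[0])


def region_density(
    scene: SceneFrame,
    region_names: list[str],
    marker_filter: str | None = None,
    paired_clone: tuple[str, tuple[float, float, float]] | None = None,
) -> DensityReport:
    """Count cells inside named regions and report densities and ratios.

    ``marker_filter`` restricts the count to cells bearing that marker.
    ``paired_clone=(region, offset)`` clones the named region's exact shape at
    an offset (e.g. a condensate sphere copied onto interfollicular dermis) so
    that the comparison uses identical volumes; the clone is reported as
    ``"<region>_paired"``.
    """
    if not region_names:
        raise ValueError("no regions requested")
    regions: dict[str, Region] = {}
    for name in region_names:
        if name not in scene.regions:
            raise KeyError(f"scene has no region named {name!r}")
        regions[name] = scene.regions[name]
    if paired_clone is not None:
        src, offset = paired_clone
        base = scene.regions[src]
        if isinstance(base, MaskRegion):
            raise ValueError("paired cloning of mask regions is not supported")
        regions[f"{src}_paired"] = base.translated(offset)

    cells = scene.cells
    if marker_filter is not None:
        cells = scene.with_marker(marker_filter)
    pos = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    rows = []
    for name, region in regions.items():
        vol = region.volume
        if vol <= 0:
            raise ValueError(f"region {name!r} has zero volume")
        count = int(region.contains(pos).sum()) if len(pos) else 0
        rows.append({"region": name, "count": count, "volume_um3": vol,
                     "density": count / vol * DENSITY_UNIT})
    table = pd.DataFrame(rows)
    ratios = {}
    for _, a in table.iterrows():
        for _, b in table.iterrows():
            if a["region"] != b["region"] and b["density"] > 0:
                ratios[f"{a['region']}/{b['region']}"] = (
                    a["density"] / b["density"])
    return DensityReport(table=table, ratios=ratios)


def shell_density(
    scene: SceneFrame,
    bead: Sphere | None = None,
    shell_edges=(0.0, 15.0, 30.0),
    mode: str = "full_shell",
    slice_half_thickness: float = 0.5,
) -> DensityReport:
    """Cell density in concentric shells around a bead.

    Distances are measured from the *bead surface*, not its center; a cell on
    the surface has distance 0 and falls in the first shell (bins are
    left-closed).  ``full_shell`` reports volumetric densities over whole
    spherical shells; ``midplane_slice`` restricts to cells within
    ``slice_half_thickness`` µm of the bead's equatorial plane and reports
    areal densities over planar annuli, emulating quantification on a single
    optical slice at mid-bead.
    """
    if bead is None:
        bead = scene.bead
    if bead is None:
        raise ValueError("no bead in scene and none supplied")
    edges = np.asarray(shell_edges, dtype=float)
    if edges[0] != 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("shell_edges must start at 0 and strictly increase")
    if mode not in ("full_shell", "midplane_slice"):
        raise ValueError(f"unknown mode {mode!r}")

    pos = scene.positions
    center = np.asarray(bead.center, dtype=float)
    if mode == "midplane_slice":
        keep = np.abs(pos[:, 2] - center[2]) <= slice_half_thickness
        pos = pos[keep]
    d = np.linalg.norm(pos - center, axis=1) - bead.radius
    d = d[d >= 0]  # cells inside the bead volume are artefacts; drop

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        count = int(np.sum((d >= lo) & (d < hi)))
        if mode == "full_shell":
            measure = 4.0 / 3.0 * np.pi * ((bead.radius + hi) ** 3
                                           - (bead.radius + lo) ** 3)
        else:
            measure = np.pi * ((bead.radius + hi) ** 2 - (bead.radius + lo) ** 2)
        rows.append({"region": f"shell_{lo:g}-{hi:g}um", "count": count,
                     "volume_um3": measure,
                     "density": count / measure * DENSITY_UNIT})
    table = pd.DataFrame(rows)
    ratios = {}
    names = table["region"].tolist()
    for a in names:
        for b in names:
            db = table.set_index("region").loc[b, "density"]
            if a != b and db > 0:
                ratios[f"{a}/{b}"] = (
                    table.set_index("region").loc[a, "density"] / db)
    unit = (f"cells per {DENSITY_UNIT:.0f} um^3" if mode == "full_shell"
            else f"cells per {DENSITY_UNIT:.0f} um^2 (midplane slice)")
    return DensityReport(table=table, ratios=ratios, unit=unit)


# ---------------------------------------------------------------------------
# Distances to a surface
# ---------------------------------------------------------------------------


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Pairwise distances (P, T) between points and triangles.

    Projects each point onto each triangle's plane; if the projection falls
    inside (barycentric test) the plane distance is used, otherwise the
    minimum distance to the three edges.
    """
    p = points[:, None, :]            # (P,1,3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)              # (T,3)
    nn = np.einsum("td,td->t", n, n)
    ap = p - a                        # (P,T,3)
    # barycentric coordinates of in-plane projection
    d00 = np.einsum("td,td->t", ab, ab)
    d01 = np.einsum("td,td->t", ab, ac)
    d11 = np.einsum("td,td->t", ac, ac)
    d20 = np.einsum("ptd,td->pt", ap, ab)
    d21 = np.einsum("ptd,td->pt", ap, ac)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    plane_dist = np.abs(np.einsum("ptd,td->pt", ap, n)) / np.sqrt(nn)

    def seg_dist(p0, p1):
        d = p1 - p0                   # (T,3)
        t = np.einsum("ptd,td->pt", p - p0, d) / np.einsum("td,td->t", d, d)
        t = np.clip(t, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        return np.linalg.norm(p - closest, axis=-1)

    edge_dist = np.minimum.reduce([seg_dist(a, b), seg_dist(b, c), seg_dist(c, a)])
    return np.where(inside, np.minimum(plane_dist, edge_dist), edge_dist)


def distances_to_surface(points, surface) -> np.ndarray:
    """Shortest Euclidean distance from each point to a surface.

    ``surface`` may be a ``(vertices, faces)`` triangle mesh (point-to-triangle
    minimum, exact), or a :class:`MaskRegion` / boolean voxel mask (Euclidean
    distance transform sampled at each point's voxel, resolution-limited).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(surface, MaskRegion):
        mask, voxel_size, origin = surface.mask, surface.voxel_size, surface.origin
    elif isinstance(surface, tuple) and len(surface) == 2:
        vertices, faces = (np.asarray(surface[0], dtype=float),
                           np.asarray(surface[1], dtype=int))
        if len(faces) == 0:
            raise ValueError("empty surface mesh")
        tri = vertices[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        good = areas > 1e-12
        if not np.all(good):
            warnings.warn(f"skipping {int((~good).sum())} degenerate triangles",
                          stacklevel=2)
            tri = tri[good]
        if len(tri) == 0:
            raise ValueError("surface mesh has no non-degenerate triangles")
        return _point_triangle_distances(points, tri).min(axis=1)
    else:
        raise TypeError("surface must be a (vertices, faces) mesh or a MaskRegion")

    if not mask.any():
        raise ValueError("empty surface mask")
    vz, vy, vx = voxel_size
    edt = ndimage.distance_transform_edt(~mask, sampling=(vz, vy, vx))
    rel = points - np.asarray(origin)
    idx = np.floor(rel / np.array([vx, vy, vz])).astype(int)
    idx = np.clip(idx, 0, np.array(mask.shape)[::-1] - 1)
    return edt[idx[:, 2], idx[:, 1], idx[:, 0]]


def distances_to_point(points, target) -> np.ndarray:
    """Distance from each point to a single reference point (e.g. a manually
    designated point at the center of the placode surface)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return np.linalg.norm(points - np.asarray(target, dtype=float), axis=1)


# ---------------------------------------------------------------------------
# Nearest-neighbour label analysis
# ---------------------------------------------------------------------------


@dataclass
class NeighborReport:
    """Nearest-neighbour identities for labeled focal cells.

    ``per_cell`` has one row per focal cell (focal_id, neighbor_id,
    distance_um, neighbor_labeled); the summary holds the labeled-neighbour
    proportion and its random-assortment expectation.
    """

    per_cell: pd.DataFrame
    n_focal: int
    prop_labeled: float
    expected_prop: float
    n_ties: int = 0


def nearest_neighbor_labels(
    scene: SceneFrame,
    focal_marker: str,
    pool_marker: str,
    labeled_marker: str,
    expectation: str = "global",
) -> NeighborReport:
    """For each labeled focal cell, find its nearest neighbour within the pool
    and ask whether that neighbour is labeled.

    Focal cells bear both ``focal_marker`` and ``labeled_marker``; candidate
    neighbours are all *other* cells bearing ``pool_marker``.  The
    random-assortment expectation is the labeled fraction among the pool
    excluding the focal cell itself.  Exact distance ties are broken toward
    the lowest cell id and counted.
    """
    if expectation != "global":
        raise ValueError("only the global random-assortment expectation is "
                         "implemented; per-region expectations can be obtained "
                         "by subsetting the scene per region")
    pool = scene.with_marker(pool_marker).sort_values("cell_id").reset_index(drop=True)
    if len(pool) < 2:
        raise ValueError("need at least 2 cells bearing the pool marker")
    focal = scene.with_marker(focal_marker)
    focal = focal[focal[labeled_marker].astype(bool)]
    pool_pos = pool[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    pool_ids = pool["cell_id"].to_numpy()
    pool_lab = pool[labeled_marker].astype(bool).to_numpy()
    tree = cKDTree(pool_pos)
    n_pool_lab = int(pool_lab.sum())

    rows, n_ties = [], 0
    for _, row in focal.iterrows():
        p = np.array([row["x_um"], row["y_um"], row["z_um"]], dtype=float)
        k = min(len(pool), 4)
        dist, idx = tree.query(p, k=k)
        dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
        keep = pool_ids[idx] != row["cell_id"]  # exclude self by identity
        dist, idx = dist[keep], idx[keep]
        if len(dist) == 0:
            continue
        tied = np.isclose(dist, dist[0], rtol=0, atol=1e-12)
        if tied.sum() > 1:
            n_ties += 1
            cand = idx[tied]
            nb = cand[np.argsort(pool_ids[cand])[0]]
        else:
            nb = idx[0]
        rows.append({"focal_id": row["cell_id"], "neighbor_id": pool_ids[nb],
                     "distance_um": float(np.linalg.norm(p - pool_pos[nb])),
                     "neighbor_labeled": bool(pool_lab[nb])})
        if rows[-1]["distance_um"] <= 0:
            raise ValueError(
                f"coincident cells: {row['cell_id']!r} and {pool_ids[nb]!r}")
    per_cell = pd.DataFrame(rows)
    n_focal = len(per_cell)
    if n_focal == 0:
        raise ValueError("no focal cells bearing both focal and labeled markers")
    prop = float(per_cell["neighbor_labeled"].mean())
    # focal cells are labeled; if the focal cell is itself in the pool the
    # expectation excludes it from both numerator and denominator
    focal_in_pool = focal["cell_id"].isin(pool["cell_id"]).all()
    if focal_in_pool:
        expected = (n_pool_lab - 1) / (len(pool) - 1)
    else:
        expected = n_pool_lab / len(pool)
    return NeighborReport(per_cell=per_cell, n_focal=n_focal,
                          prop_labeled=prop, expected_prop=float(expected),
                          n_ties=n_ties)


def neighbor_randomness_test(report: NeighborReport) -> TestResult:
    """1-df chi-square test of labeled/unlabeled nearest-neighbour counts
    against the random-assortment expectation."""
    n = report.n_focal
    p0 = report.expected_prop
    if p0 <= 0 or p0 >= 1:
        raise ValueError("degenerate expectation: all (or no) pool cells "
                         "labeled; chi-square undefined")
    obs = np.array([report.prop_labeled * n, (1 - report.prop_labeled) * n])
    exp = np.array([p0 * n, (1 - p0) * n])
    if np.any(exp < 5):
        warnings.warn("expected count below 5 in a cell; chi-square "
                      "approximation is coarse", stacklevel=2)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(statistic_name="chi2_neighbor_randomness",
                      statistic=chi2, p_value=p, n=n,
                      method_note=f"1-df chi-square vs expectation {p0:.4f}",
                      extra={"observed_prop": report.prop_labeled,
                             "expected_prop": p0, "n_ties": report.n_ties})


# ---------------------------------------------------------------------------
# Label fractions
# ---------------------------------------------------------------------------


def label_fraction(
    scene_or_counts,
    marker: str | None = None,
    region: str | Region | None = None,
    denominator_marker: str | None = None,
    ci_level: float = 0.95,
) -> dict:
    """Fraction of cells bearing a marker, with a Wilson binomial CI.

    ``scene_or_counts`` is either a :class:`SceneFrame` or a ``(k, n)`` counts
    pair (e.g. counts printed in a figure legend).  With a scene,
    ``denominator_marker`` restricts the denominator population and ``region``
    restricts to a (named) region.
    """
    if isinstance(scene_or_counts, SceneFrame):
        scene = scene_or_counts
        cells = scene.cells
        if region is not None:
            cells = cells[scene.in_region(region)]
        if denominator_marker is not None:
            cells = cells[cells[denominator_marker].astype(bool)]
        if marker is None:
            raise ValueError("marker required when passing a scene")
        n = len(cells)
        if n == 0:
            raise ValueError("denominator population is empty")
        k = int(cells[marker].astype(bool).sum())
    else:
        k, n = scene_or_counts
        k, n = int(k), int(n)
        if n <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=ci_level,
                                             method="wilson")
    return {"count": k, "n": n, "fraction": k / n, "percent": 100.0 * k / n,
            "ci_low": float(ci.low), "ci_high": float(ci.high),
            "ci_level": ci_level}


def fucci_fractions(
    scene: SceneFrame,
    g1_marker: str = "fucci_g1",
    sgm_marker: str = "fucci_sgm",
    region: str | Region | None = None,
    denominator_marker: str | None = None,
) -> dict:
    """Four-way cell-cycle reporter scoring: G1-only, S/G2/M-only, both,
    neither.  Fractions sum to 1 over the denominator population."""
    cells = scene.cells
    if region is not None:
        cells = cells[scene.in_region(region)]
    if denominator_marker is not None:
        cells = cells[cells[denominator_marker].astype(bool)]
    n = len(cells)
    if n == 0:
        raise ValueError("denominator population is empty")
    g1 = cells[g1_marker].astype(bool).to_numpy()
    sgm = cells[sgm_marker].astype(bool).to_numpy()
    return {"n": n,
            "g1_only": float((g1 & ~sgm).mean()),
            "sgm_only": float((~g1 & sgm).mean()),
            "both": float((g1 & sgm).mean()),
            "neither": float((~g1 & ~sgm).mean())}


def marker_enrichment_test(
    scene: SceneFrame,
    marker: str,
    region: str | Region,
    denominator_marker: str | None = None,
    alternative: str = "greater",
) -> TestResult:
    """Is the marker-positive fraction inside a region different from outside?

    One-sided (default: inside > outside) two-proportion z-test; used to ask
    whether S/G2/M cells are enriched inside the condensate.
    """
    cells = scene.cells
    if denominator_marker is not None:
        cells = cells[cells[denominator_marker].astype(bool)]
    reg = scene.regions[region] if isinstance(region, str) else region
    inside = reg.contains(cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
    pos = cells[marker].astype(bool).to_numpy()
    n1, n2 = int(inside.sum()), int((~inside).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("need cells both inside and outside the region")
    p1, p2 = pos[inside].mean(), pos[~inside].mean()
    p_pool = pos.mean()
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else float((p1 - p2) / se)
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(statistic_name="two_proportion_z", statistic=z,
                      p_value=p, n=n1, m=n2,
                      method_note=f"pooled z-test, alternative={alternative}",
                      extra={"prop_inside": float(p1), "prop_outside": float(p2)})
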