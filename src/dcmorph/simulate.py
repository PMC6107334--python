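"""Agent-based generator of synthetic condensation data.

Three mechanisms have classically been proposed for mesenchymal condensation:
(i) a local increase in mitotic activity, (ii) active directed migration of
cells toward the condensation site, and (iii) failure of cells to disperse
once there (altered cell-cell / cell-matrix adhesion).  The simulator renders
each as a regime of a biased random walk so that the downstream analyses can
be exercised — and discriminated — on data of known ground truth:

* ``null`` — unbiased random walk, no trapping, no divisions.
* ``migration`` — cells outside the condensate radius step with a von
  Mises-Fisher directional bias toward the condensate center (concentration
  ``bias_kappa``); inside, speed is multiplied by ``trap_factor``.
* ``proliferation`` — unbiased walk, but cells divide as a Poisson process at
  ``division_rate_dc`` inside the condensate radius and ``division_rate_if``
  outside; cells that divided during the movie carry the S/G2/M cycle marker.
* ``nondispersal`` — unbiased walk with trapping inside the radius only.

Per-frame displacement is speed x frame_interval along a unit direction drawn
from a von Mises-Fisher distribution about the cell-to-center unit vector
(kappa = 0 is isotropic).  The domain box shapes only the initial placement:
by default walkers are unbounded thereafter, which keeps the isotropic null
exact (reflecting walls measurably bias net displacements toward the domain
interior, i.e. toward the condensate); set ``boundary="reflect"`` to confine
cells instead.  Reference (non-motile fiducial) cells are emitted as exactly
stationary tracks; optional global drift is injected afterwards so that drift
correction can be validated as a round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import Box, SceneFrame, Sphere
from .shapes import LabelVolume
from .tracks import CORE_COLUMNS, POSITION_COLUMNS

MODES = ("null", "migration", "proliferation", "nondispersal")

__all__ = ["SimulationConfig", "SceneSpec", "RegionSpec",
           "simulate_condensation", "generate_point_scene",
           "generate_label_volume", "rasterize_ellipsoids", "inject_drift",
           "sample_vmf"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Full parameterization of the agent-based condensation generator.

    Lengths in µm, times in minutes, division rates in events/cell/hour.
    Defaults reproduce the observed imaging conditions: 20-min sampling over a
    ~13 h movie, a 30 µm-diameter condensate (radius 15 µm), ~95% of
    condensate cells in G1 versus ~50% interfollicularly.  Fibroblast speeds
    are illustrative (no measured speed distribution is available), chosen so
    that track velocities fall in the 0.1-0.5 µm/min range typical of
    embryonic mesenchyme.
    """

    mode: str = "null"
    n_cells: int = 400
    domain_extent: tuple[float, float, float] = (200.0, 200.0, 120.0)
    dc_center: tuple[float, float, float] | None = None  # default: domain center
    dc_radius: float = 15.0
    bias_kappa: float = 0.0
    speed_mean: float = 0.10
    speed_sd: float = 0.04
    frame_interval: float = 20.0
    n_frames: int = 40
    division_rate_dc: float = 0.0
    division_rate_if: float = 0.0
    trap_factor: float = 0.2
    cycle_g1_fraction_dc: float = 0.95
    cycle_g1_fraction_if: float = 0.50
    label_fraction: float = 0.0
    label_clustering: float = 0.0
    n_reference_cells: int = 8
    if_fraction: float = 0.25         # fraction of cells that are IF controls
    dc_seed_fraction: float = 0.40    # fraction of DC candidates seeded inside
    nuclear_diameter: float = 7.0     # daughter-placement offset at division
    boundary: str = "unbounded"       # or "reflect"
    drift_per_frame: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        ext = np.asarray(self.domain_extent, dtype=float)
        if np.any(ext <= 0):
            raise ValueError("domain_extent must be positive")
        if self.dc_center is None:
            self.dc_center = tuple(ext / 2.0)
        c = np.asarray(self.dc_center, dtype=float)
        if np.any(c < 0) or np.any(c > ext):
            raise ValueError("dc_center lies outside the domain")
        if not 0 < self.dc_radius < min(ext) / 2:
            raise ValueError("need 0 < dc_radius < min(domain_extent)/2")
        for name in ("bias_kappa", "speed_mean", "speed_sd", "frame_interval",
                     "division_rate_dc", "division_rate_if", "nuclear_diameter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("trap_factor", "cycle_g1_fraction_dc",
                     "cycle_g1_fraction_if", "label_fraction",
                     "label_clustering", "if_fraction", "dc_seed_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_reference_cells < 0:
            raise ValueError("n_reference_cells must be >= 0")
        if self.boundary not in ("unbounded", "reflect"):
            raise ValueError("boundary must be 'unbounded' or 'reflect'")

    @classmethod
    def preset(cls, mode: str, **overrides) -> "SimulationConfig":
        """Study-condition presets for the three condensation mechanisms.

        ``migration`` biases DC candidates inward (kappa = 4) with the
        measured G1 enrichment; ``proliferation`` starts from equal cycle
        fractions and lets local divisions (cycle time ~8 h inside the
        condensate) generate the S/G2/M excess; ``nondispersal`` traps without
        bias; ``null`` is a plain random walk with no cycle contrast.
        """
        presets: dict[str, dict] = {
            "null": {"bias_kappa": 0.0, "cycle_g1_fraction_dc": 0.5},
            "migration": {"bias_kappa": 4.0},
            "proliferation": {"division_rate_dc": 0.12,
                              "division_rate_if": 0.01,
                              "cycle_g1_fraction_dc": 0.5},
            "nondispersal": {},
        }
        if mode not in presets:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        kwargs = {"mode": mode, **presets[mode], **overrides}
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# von Mises-Fisher sampling and reflection
# ---------------------------------------------------------------------------


def sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw unit vectors from a 3D von Mises-Fisher distribution.

    ``mu`` is (n, 3) of unit mean directions; kappa = 0 gives isotropic
    directions.  Uses the inverse-CDF form of Ulrich/Wood's method: for S2 the
    cosine w of the polar angle has density proportional to exp(kappa*w).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    n = len(mu)
    if kappa == 0.0:
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.uniform(size=n)
    # w ~ exp(kappa w) on [-1, 1]; stable inverse CDF
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # orthonormal frame around each mu
    helper = np.where(np.abs(mu[:, [0]]) < 0.9,
                      np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    return (w[:, None] * mu + s[:, None] * (np.cos(phi)[:, None] * e1
                                            + np.sin(phi)[:, None] * e2))


def _reflect(pos: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """Reflect positions off the walls of [0, extent] on each axis."""
    period = 2.0 * extent
    x = np.mod(pos, period)
    return np.where(x > extent, period - x, x)


# ---------------------------------------------------------------------------
# Condensation simulator
# ---------------------------------------------------------------------------


def _assign_labels(config: SimulationConfig, final_pos: np.ndarray,
                   classes: np.ndarray, divided: np.ndarray,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Cycle-state and lineage markers for the mobile cells."""
    n = len(final_pos)
    center = np.asarray(config.dc_center, dtype=float)
    inside = np.linalg.norm(final_pos - center, axis=1) <= config.dc_radius
    g1_prob = np.where(inside, config.cycle_g1_fraction_dc,
                       config.cycle_g1_fraction_if)
    g1 = rng.uniform(size=n) < g1_prob
    # a cell that went through mitosis during the movie was cycling
    g1[divided] = False
    markers = {"fucci_g1": g1, "fucci_sgm": ~g1}

    lineage = np.zeros(n, dtype=bool)
    if config.label_fraction > 0:
        dc_idx = np.flatnonzero(classes == "dc_candidate")
        k = int(round(config.label_fraction * len(dc_idx)))
        if k > 0 and len(dc_idx) > 0:
            if config.label_clustering > 0:
                # labeled cells preferentially the ones deepest in the
                # condensate: rank by distance, mix with uniform picks
                d = np.linalg.norm(final_pos[dc_idx] - center, axis=1)
                ranked = dc_idx[np.argsort(d)]
                n_clustered = rng.binomial(k, config.label_clustering)
                chosen = list(ranked[:n_clustered])
                rest = np.setdiff1d(dc_idx, chosen)
                if k - n_clustered > 0 and len(rest) > 0:
                    chosen.extend(rng.choice(rest, size=min(k - n_clustered,
                                                            len(rest)),
                                             replace=False))
            else:
                chosen = rng.choice(dc_idx, size=min(k, len(dc_idx)),
                                    replace=False)
            lineage[np.asarray(chosen, dtype=int)] = True
    markers["lineage"] = lineage
    return markers


def simulate_condensation(
    config: SimulationConfig,
    return_scenes: bool = True,
) -> tuple[pd.DataFrame, list[SceneFrame]]:
    """Run the agent-based simulator.

    Returns a track table (one track per cell, plus daughter tracks with
    ``.d<k>``-suffixed ids in proliferation mode, plus stationary reference
    tracks) and, unless ``return_scenes`` is false, one :class:`SceneFrame`
    per frame carrying the final cycle/lineage markers and the condensate
    sphere as a named region.  Identical configs give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    ext = np.asarray(config.domain_extent, dtype=float)
    center = np.asarray(config.dc_center, dtype=float)
    n_if = int(round(config.n_cells * config.if_fraction))
    n_dc = config.n_cells - n_if

    # initial placement: part of the DC cohort seeds the incipient condensate
    n_seed = int(round(config.dc_seed_fraction * n_dc))
    u = rng.uniform(size=(n_seed, 1))
    v = rng.normal(size=(n_seed, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    seeded = center + v * config.dc_radius * u ** (1.0 / 3.0)
    outsiders = rng.uniform(0.0, 1.0, size=(n_dc - n_seed, 3)) * ext
    if_pos = rng.uniform(0.0, 1.0, size=(n_if, 3)) * ext

    pos = np.vstack([seeded, outsiders, if_pos])
    classes = np.array(["dc_candidate"] * n_dc + ["interfollicular"] * n_if,
                       dtype=object)
    ids = [f"cell_{i:04d}" for i in range(config.n_cells)]
    birth_frame = np.zeros(config.n_cells, dtype=int)
    divided = np.zeros(config.n_cells, dtype=bool)
    history: list[np.ndarray] = [pos.copy()]

    dt_hours = config.frame_interval / 60.0
    for frame in range(1, config.n_frames):
        n_now = len(pos)
        speed = np.clip(rng.normal(config.speed_mean, config.speed_sd,
                                   size=n_now), 0.0, None)
        dist = np.linalg.norm(pos - center, axis=1)
        inside = dist <= config.dc_radius
        is_dc = classes == "dc_candidate"

        directions = sample_vmf(np.zeros((n_now, 3)) + [1.0, 0.0, 0.0], 0.0, rng)
        if config.mode == "migration" and config.bias_kappa > 0:
            biased = is_dc & ~inside & (dist > 1e-9)
            if biased.any():
                mu = (center - pos[biased]) / dist[biased, None]
                directions[biased] = sample_vmf(mu, config.bias_kappa, rng)
        step = speed * config.frame_interval
        if config.mode in ("migration", "nondispersal"):
            step = np.where(is_dc & inside, step * config.trap_factor, step)
        pos = pos + directions * step[:, None]
        if config.boundary == "reflect":
            pos = _reflect(pos, ext)

        if config.mode == "proliferation" and frame < config.n_frames - 1:
            # divisions on the final step would yield single-point daughter
            # tracks with no measurable movement
            rate = np.where(inside, config.division_rate_dc,
                            config.division_rate_if)
            p_div = 1.0 - np.exp(-rate * dt_hours)
            div = rng.uniform(size=n_now) < p_div
            if div.any():
                idx = np.flatnonzero(div)
                offsets = sample_vmf(np.zeros((len(idx), 3)) + [1.0, 0, 0],
                                     0.0, rng) * config.nuclear_diameter
                daughters = pos[idx] + offsets
                if config.boundary == "reflect":
                    daughters = _reflect(daughters, ext)
                for j, i in enumerate(idx):
                    ids.append(f"{ids[i]}.d{frame}")
                divided[idx] = True
                pos = np.vstack([pos, daughters])
                classes = np.concatenate([classes, classes[idx]])
                birth_frame = np.concatenate(
                    [birth_frame, np.full(len(idx), frame)])
                divided = np.concatenate([divided, np.ones(len(idx), bool)])
                # pad earlier history with NaN for the new cells
                for k in range(len(history)):
                    pad = np.full((len(idx), 3), np.nan)
                    history[k] = np.vstack([history[k], pad])
        history.append(pos.copy())

    n_total = len(pos)
    markers = _assign_labels(config, pos, classes, divided, rng)

    # reference (non-motile fiducial) cells: exactly stationary
    ref_pos = rng.uniform(0.0, 1.0, size=(config.n_reference_cells, 3)) * ext

    frames_idx = np.arange(config.n_frames)
    recs = []
    for i in range(n_total):
        f0 = birth_frame[i]
        for f in range(f0, config.n_frames):
            p = history[f][i]
            rec = {"track_id": ids[i], "frame": f,
                   "time_min": f * config.frame_interval,
                   "x_um": p[0], "y_um": p[1], "z_um": p[2],
                   "cell_class": classes[i]}
            recs.append(rec)
    for r in range(config.n_reference_cells):
        for f in frames_idx:
            recs.append({"track_id": f"ref_{r:03d}", "frame": int(f),
                         "time_min": f * config.frame_interval,
                         "x_um": ref_pos[r, 0], "y_um": ref_pos[r, 1],
                         "z_um": ref_pos[r, 2], "cell_class": "reference"})
    tracks = pd.DataFrame.from_records(recs, columns=CORE_COLUMNS)

    marker_map = {ids[i]: {m: bool(markers[m][i]) for m in markers}
                  for i in range(n_total)}
    for m in markers:
        tracks[m] = [marker_map.get(t, {}).get(m, False)
                     for t in tracks["track_id"]]

    if config.drift_per_frame is not None and \
            np.any(np.asarray(config.drift_per_frame) != 0):
        tracks = inject_drift(tracks, config.drift_per_frame)

    scenes: list[SceneFrame] = []
    if return_scenes:
        dc_region = Sphere(tuple(center), config.dc_radius)
        for f in frames_idx:
            sub = tracks[(tracks["frame"] == f)
                         & (tracks["cell_class"] != "reference")]
            cells = sub.rename(columns={"track_id": "cell_id"})[
                ["cell_id", "x_um", "y_um", "z_um", *markers.keys()]
            ].reset_index(drop=True)
            cells["dc_candidate"] = (
                sub["cell_class"].to_numpy() == "dc_candidate")
            scenes.append(SceneFrame(cells=cells, regions={"dc": dc_region},
                                     dc_center=tuple(center)))
    return tracks, scenes


def inject_drift(tracks: pd.DataFrame, drift_per_frame) -> pd.DataFrame:
    """Translate every position at frame k by k x drift_per_frame (µm)."""
    if len(tracks) == 0:
        raise ValueError("empty track table")
    drift = np.asarray(drift_per_frame, dtype=float)
    out = tracks.copy()
    shift = np.outer(out["frame"].to_numpy(dtype=float), drift)
    out[POSITION_COLUMNS] = out[POSITION_COLUMNS].to_numpy(dtype=float) + shift
    return out


# ---------------------------------------------------------------------------
# Static scene generator
# ---------------------------------------------------------------------------


@dataclass
class RegionSpec:
    """One region of a synthetic scene: geometry, target density
    (cells per 10^4 µm^3), marker probabilities and nuclear semi-axes (µm)."""

    region: Sphere | Box
    density: float
    marker_fractions: dict[str, float] = field(default_factory=dict)
    semi_axes: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("region density must be positive")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("nuclear semi-axes must be positive")
        for m, p in self.marker_fractions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marker fraction for {m!r} outside [0, 1]")


@dataclass
class SceneSpec:
    """Specification of a synthetic static scene (e.g. a dense condensate
    sphere inside a sparser interfollicular box)."""

    regions: dict[str, RegionSpec]
    label_clustering: float = 0.0
    clustering_marker: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.regions:
            raise ValueError("scene spec needs at least one region")
        if not 0.0 <= self.label_clustering <= 1.0:
            raise ValueError("label_clustering must lie in [0, 1]")


def _uniform_in_region(region, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(region, Sphere):
        v = rng.normal(size=(size, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = region.radius * rng.uniform(size=(size, 1)) ** (1.0 / 3.0)
        return np.asarray(region.center) + v * r
    if isinstance(region, Box):
        lo, hi = np.asarray(region.lo), np.asarray(region.hi)
        return lo + rng.uniform(size=(size, 3)) * (hi - lo)
    raise TypeError("scene generation supports sphere and box regions")


def generate_point_scene(spec: SceneSpec) -> SceneFrame:
    """Sample a synthetic scene: Poisson cell counts per region at the target
    density, uniform positions, independent marker assignment — except that
    with ``label_clustering`` > 0, cells carrying ``clustering_marker`` are
    preferentially placed within one mean nearest-neighbour distance of an
    already-labeled cell (non-random assortment)."""
    rng = np.random.default_rng(spec.seed)
    all_markers = sorted({m for rs in spec.regions.values()
                          for m in rs.marker_fractions})
    rows = []
    cid = 0
    for name, rs in spec.regions.items():
        mean_count = rs.density * rs.region.volume / 1e4
        if mean_count < 1:
            warnings.warn(f"region {name!r}: expected cell count "
                          f"{mean_count:.2f} < 1", stacklevel=2)
        n = int(rng.poisson(mean_count))
        if n == 0:
            continue
        pts = _uniform_in_region(rs.region, n, rng)
        marker_draws = {m: rng.uniform(size=n) < rs.marker_fractions.get(m, 0.0)
                        for m in all_markers}
        cm = spec.clustering_marker
        if cm is not None and spec.label_clustering > 0 and \
                rs.marker_fractions.get(cm, 0.0) > 0:
            # clustered placement: labeled cells near earlier labeled cells
            rho = rs.density / 1e4  # cells per µm^3
            nn_dist = 0.5539 * rho ** (-1.0 / 3.0)  # Poisson mean NN distance
            labeled_idx = np.flatnonzero(marker_draws[cm])
            placed: list[np.ndarray] = []
            for j in labeled_idx:
                if placed and rng.uniform() < spec.label_clustering:
                    anchor = placed[rng.integers(len(placed))]
                    for _ in range(50):
                        v = rng.normal(size=3)
                        v /= np.linalg.norm(v)
                        cand = anchor + v * rng.uniform(0, nn_dist)
                        if rs.region.contains(cand[None, :])[0]:
                            pts[j] = cand
                            break
                placed.append(pts[j])
        for i in range(n):
            row = {"cell_id": f"{name}_{cid:05d}", "x_um": pts[i, 0],
                   "y_um": pts[i, 1], "z_um": pts[i, 2]}
            for m in all_markers:
                row[m] = bool(marker_draws[m][i])
            rows.append(row)
            cid += 1
    cells = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "z_um",
                                        *all_markers])
    for m in all_markers:
        cells[m] = cells[m].astype(bool)
    return SceneFrame(cells=cells,
                      regions={k: rs.region for k, rs in spec.regions.items()})


# ---------------------------------------------------------------------------
# Label-volume generator
# ---------------------------------------------------------------------------


def rasterize_ellipsoids(
    centers: np.ndarray,
    semi_axes,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> LabelVolume:
    """Rasterize filled ellipsoids into a (z, y, x) label grid.

    ``centers`` are (x, y, z) µm; ``semi_axes`` one (ax, ay, az) triple per
    object (or a single shared triple).  Overlapping ellipsoids raise, since
    the shape analyses assume separated nuclei.  Labels are consecutive
    positive integers in input order; border-touching labels are recorded in
    the metadata.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    axes = np.atleast_2d(np.asarray(semi_axes, dtype=float))
    if len(axes) == 1:
        axes = np.repeat(axes, len(centers), axis=0)
    vz, vy, vx = voxel_size
    vol = np.zeros(shape, dtype=np.int32)
    zc = (np.arange(shape[0]) + 0.5) * vz
    yc = (np.arange(shape[1]) + 0.5) * vy
    xc = (np.arange(shape[2]) + 0.5) * vx
    border_labels = []
    for lab, (c, ax) in enumerate(zip(centers, axes), start=1):
        if np.any(ax < 2 * np.array([vx, vy, vz])):
            raise ValueError(
                f"object {lab}: semi-axes must span >= 2 voxels per axis")
        dz = (zc - c[2]) / ax[2]
        dy = (yc - c[1]) / ax[1]
        dx = (xc - c[0]) / ax[0]
        mask = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
                + dx[None, None, :] ** 2) <= 1.0
        if np.any(vol[mask] != 0):
            raise ValueError(f"object {lab} overlaps a previous object")
        vol[mask] = lab
        zz, yy, xx = np.nonzero(mask)
        if len(zz) and (zz.min() == 0 or zz.max() == shape[0] - 1
                        or yy.min() == 0 or yy.max() == shape[1] - 1
                        or xx.min() == 0 or xx.max() == shape[2] - 1):
            border_labels.append(lab)
    return LabelVolume(voxels=vol, voxel_size=voxel_size,
                       meta={"border_labels": border_labels})


def generate_label_volume(
    spec: SceneSpec,
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    max_tries: int = 200,
) -> LabelVolume:
    """Generate a segmented-nuclei label volume matching a scene spec.

    Nuclear centers are sampled like :func:`generate_point_scene` but with
    rejection so that no two ellipsoids overlap; each nucleus is a filled
    ellipsoid with its region's semi-axes.  An empty spec region simply
    contributes no objects.
    """
    rng = np.random.default_rng(spec.seed)
    los, his = [], []
    for rs in spec.regions.values():
        r = rs.region
        margin = max(rs.semi_axes)
        if isinstance(r, Sphere):
            c = np.asarray(r.center)
            los.append(c - r.radius - margin)
            his.append(c + r.radius + margin)
        else:
            los.append(np.asarray(r.lo) - margin)
            his.append(np.asarray(r.hi) + margin)
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    if np.any(lo < 0):
        raise ValueError("regions (plus nuclear margin) must lie in the "
                         "positive octant for rasterization")
    vz, vy, vx = voxel_size
    shape = (int(np.ceil(hi[2] / vz)) + 1, int(np.ceil(hi[1] / vy)) + 1,
             int(np.ceil(hi[0] / vx)) + 1)

    centers, axes = [], []
    for name, rs in spec.regions.items():
        mean_count = rs.density * rs.region.volume / 1e4
        if mean_count < 1:
            warnings.warn(f"region {name!r}: expected cell count "
                          f"{mean_count:.2f} < 1", stacklevel=2)
        n = int(rng.poisson(mean_count))
        sep = 2.0 * max(rs.semi_axes)  # conservative: bounding spheres
        for _ in range(n):
            for _ in range(max_tries):
                cand = _uniform_in_region(rs.region, 1, rng)[0]
                if all(np.linalg.norm(cand - c) >= sep for c in centers):
                    centers.append(cand)
                    axes.append(rs.semi_axes)
                    break
            else:
                warnings.warn(f"region {name!r}: could not place all nuclei "
                              "without overlap; some omitted", stacklevel=2)
                break
    if not centers:
        return LabelVolume(voxels=np.zeros(shape, dtype=np.int32),
                           voxel_size=voxel_size, meta={"border_labels": []})
    return rasterize_ellipsoids(np.asarray(centers), np.asarray(axes),
                                shape, voxel_size)
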