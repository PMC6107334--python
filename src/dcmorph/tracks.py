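"""Per-track motility metrics and escape angles for 4D cell tracking data.

A track table is a tidy :class:`pandas.DataFrame` with one row per cell per
frame and columns::

    track_id, frame, time_min, x_um, y_um, z_um, cell_class, <marker columns>

``cell_class`` is one of ``dc_candidate`` (condensate-forming fibroblast),
``interfollicular`` (control fibroblast away from any condensate) and
``reference`` (non-motile cell used for translational drift correction).
Frames are 0-based and strictly increasing within a track; positions are in
micrometres and times in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CORE_COLUMNS = ["track_id", "frame", "time_min", "x_um", "y_um", "z_um", "cell_class"]
POSITION_COLUMNS = ["x_um", "y_um", "z_um"]
CELL_CLASSES = ("dc_candidate", "interfollicular", "reference")

MIN_REFERENCE_CELLS = 7  # fewer non-motile cells degrades drift estimation

__all__ = [
    "validate_tracks",
    "correct_drift",
    "escape_angle",
    "signed_planar_angle",
    "compute_track_metrics",
    "group_by_initial_distance",
]


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Check the track-table contract; returns the table unchanged."""
    missing = [c for c in CORE_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing required columns: {missing}")
    if len(tracks) == 0:
        raise ValueError("track table is empty")
    pos = tracks[POSITION_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("track positions must be finite")
    bad_class = set(tracks["cell_class"].unique()) - set(CELL_CLASSES)
    if bad_class:
        raise ValueError(f"unknown cell_class values: {sorted(bad_class)}")
    for tid, sub in tracks.groupby("track_id", sort=False):
        f = sub["frame"].to_numpy()
        if np.any(np.diff(f) <= 0):
            raise ValueError(f"track {tid!r}: frames not strictly increasing")
    return tracks


def correct_drift(tracks: pd.DataFrame) -> pd.DataFrame:
    """Remove global translational tissue drift using reference cells.

    For each frame the mean displacement (relative to the first frame) of all
    ``reference``-class cells is subtracted from every position at that frame,
    mirroring fiducial-based registration of time-lapse stacks.  Reference
    tracks must span every frame present in the table.
    """
    validate_tracks(tracks)
    refs = tracks[tracks["cell_class"] == "reference"]
    if len(refs) == 0:
        raise ValueError("drift correction requires at least one reference track")
    frames = np.sort(tracks["frame"].unique())
    ref_ids = refs["track_id"].unique()
    if len(ref_ids) < MIN_REFERENCE_CELLS:
        warnings.warn(
            f"only {len(ref_ids)} reference cells; at least "
            f"{MIN_REFERENCE_CELLS} non-motile cells are recommended",
            stacklevel=2)
    for tid, sub in refs.groupby("track_id", sort=False):
        if not np.array_equal(np.sort(sub["frame"].unique()), frames):
            raise ValueError(
                f"reference track {tid!r} does not span all frames "
                "(gap or late start)")
    # per-frame mean displacement of reference cells relative to frame 0
    wide = refs.pivot(index="frame", columns="track_id", values=POSITION_COLUMNS)
    disp = wide - wide.iloc[0]
    drift = pd.DataFrame(
        {c: disp[c].mean(axis=1) for c in POSITION_COLUMNS}).reindex(frames)
    out = tracks.copy()
    shift = drift.loc[out["frame"].to_numpy()].to_numpy()
    out[POSITION_COLUMNS] = out[POSITION_COLUMNS].to_numpy(dtype=float) - shift
    return out


def escape_angle(start, end, center) -> float:
    """Escape angle α in degrees between a cell's trajectory and the
    direction to a reference center.

    α = arccos( a·b / (|a||b|) ) with a = end - start (net displacement) and
    b = center - start.  0° is motion straight toward the center, 180°
    directly away; values are in [0, 180].
    """
    a = np.asarray(end, dtype=float) - np.asarray(start, dtype=float)
    b = np.asarray(center, dtype=float) - np.asarray(start, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0:
        raise ValueError("undefined escape angle: zero net displacement")
    if nb == 0.0:
        raise ValueError("undefined escape angle: start coincides with center")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def signed_planar_angle(start, end, center) -> float:
    """Signed xy-projection escape angle in degrees, in [0, 360).

    The sign distinguishes clockwise from counter-clockwise deviation in the
    imaging plane, as in 2D track plots; 0° is straight toward the center.
    """
    a = (np.asarray(end, dtype=float) - np.asarray(start, dtype=float))[:2]
    b = (np.asarray(center, dtype=float) - np.asarray(start, dtype=float))[:2]
    if np.linalg.norm(a) == 0.0 or np.linalg.norm(b) == 0.0:
        raise ValueError("undefined planar angle: degenerate projection")
    ang = np.arctan2(b[0] * a[1] - b[1] * a[0], np.dot(b, a))
    return float(np.degrees(ang) % 360.0)


def _truncate_at_entry(sub: pd.DataFrame, center: np.ndarray,
                       entry_radius: float) -> tuple[pd.DataFrame, bool]:
    """Cut a track at its first frame strictly inside the condensate.

    Entry means crossing the boundary after the start: a track whose first
    point is already inside is left whole (it never 'enters').
    """
    if entry_radius <= 0:
        return sub, False
    d = np.linalg.norm(sub[POSITION_COLUMNS].to_numpy(dtype=float) - center, axis=1)
    inside = np.flatnonzero(d < entry_radius)
    inside = inside[inside > 0]
    if inside.size == 0 or inside[0] == len(sub) - 1:
        return sub, inside.size > 0 and inside[0] == len(sub) - 1
    return sub.iloc[: inside[0] + 1], True


def compute_track_metrics(
    tracks: pd.DataFrame,
    center,
    entry_radius: float = 15.0,
    truncate: bool = False,
    threshold: float = 30.0,
    if_center=None,
) -> pd.DataFrame:
    """Compute per-track motility metrics and escape angles.

    Parameters
    ----------
    tracks : DataFrame
        Drift-corrected track table.
    center : 3-point, µm
        Condensate center for ``dc_candidate`` tracks.
    entry_radius : float, µm
        Radius defining condensate entry (half the ~30 µm condensate
        diameter).  Only used when ``truncate`` is set.
    truncate : bool
        If true, each dc_candidate track is cut at its first frame inside
        ``entry_radius`` before metrics are computed, so the metrics describe
        migration only up to condensate entry.
    threshold : float, µm
        Initial-distance threshold splitting dc_candidate tracks into
        ``dc_far`` (>) and ``dc_near`` (<=).
    if_center : 3-point, µm, optional
        Migration center for interfollicular tracks; defaults to the centroid
        of their starting positions (an arbitrary reference point).

    Returns
    -------
    DataFrame with one row per analyzable track: track_id, cell_class, group,
    track_length, displacement_length, duration, velocity, net_velocity,
    straightness, escape_angle_deg, escape_angle_planar_deg, initial_distance,
    truncated_at_entry.
    """
    validate_tracks(tracks)
    if truncate and entry_radius < 0:
        raise ValueError("entry_radius must be >= 0")
    center = np.asarray(center, dtype=float)
    mobile = tracks[tracks["cell_class"] != "reference"]
    if if_center is None:
        starts = (mobile[mobile["cell_class"] == "interfollicular"]
                  .sort_values("frame").groupby("track_id", sort=False).first())
        if len(starts):
            if_center = starts[POSITION_COLUMNS].to_numpy(dtype=float).mean(axis=0)
    if if_center is not None:
        if_center = np.asarray(if_center, dtype=float)

    rows = []
    for tid, sub in mobile.groupby("track_id", sort=False):
        sub = sub.sort_values("frame")
        cls = sub["cell_class"].iloc[0]
        grp_center = center if cls == "dc_candidate" else if_center
        truncated = False
        if truncate and cls == "dc_candidate":
            sub, truncated = _truncate_at_entry(sub, center, entry_radius)
        if len(sub) < 2:
            warnings.warn(f"track {tid!r}: fewer than 2 points; excluded",
                          stacklevel=2)
            continue
        pos = sub[POSITION_COLUMNS].to_numpy(dtype=float)
        t = sub["time_min"].to_numpy(dtype=float)
        duration = t[-1] - t[0]
        if duration <= 0:
            warnings.warn(f"track {tid!r}: zero duration; excluded", stacklevel=2)
            continue
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        track_length = float(seg.sum())
        displacement = float(np.linalg.norm(pos[-1] - pos[0]))
        if len(pos) == 2:
            # mathematically identical; share the value so straightness is
            # exactly 1 for single-segment tracks
            track_length = displacement
        straightness = displacement / track_length if track_length > 0 else np.nan
        init_dist = (float(np.linalg.norm(pos[0] - grp_center))
                     if grp_center is not None else np.nan)
        if displacement > 0 and grp_center is not None and \
                np.linalg.norm(grp_center - pos[0]) > 0:
            ang = escape_angle(pos[0], pos[-1], grp_center)
            try:
                ang2d = signed_planar_angle(pos[0], pos[-1], grp_center)
            except ValueError:
                ang2d = np.nan
        else:
            ang = np.nan
            ang2d = np.nan
        if cls == "dc_candidate":
            group = "dc_far" if init_dist > threshold else "dc_near"
        else:
            group = "interfollicular"
        rows.append({
            "track_id": tid, "cell_class": cls, "group": group,
            "track_length": track_length, "displacement_length": displacement,
            "duration": duration, "velocity": track_length / duration,
            "net_velocity": displacement / duration,
            "straightness": straightness, "escape_angle_deg": ang,
            "escape_angle_planar_deg": ang2d,
            "initial_distance": init_dist, "truncated_at_entry": truncated,
        })
    return pd.DataFrame(rows)


def group_by_initial_distance(
    metrics: pd.DataFrame, threshold: float = 30.0
) -> dict[str, pd.DataFrame]:
    """Partition track metrics by initial distance to the condensate center.

    dc_candidate tracks further than ``threshold`` µm at their first frame go
    to ``dc_far``, the rest (boundary inclusive) to ``dc_near``;
    interfollicular tracks pass through unchanged.  The partition is
    exhaustive and disjoint.
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    is_dc = metrics["cell_class"] == "dc_candidate"
    far = is_dc & (metrics["initial_distance"] > threshold)
    return {
        "dc_far": metrics[far],
        "dc_near": metrics[is_dc & ~far],
        "interfollicular": metrics[~is_dc],
    }
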