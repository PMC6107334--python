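"""Reading and writing track tables, label volumes and assay tables.

The native track dialect is comma-separated UTF-8 with a mandatory header::

    track_id,frame,time_min,x_um,y_um,z_um,cell_class,<marker columns>

Spot exports from other trackers (e.g. TrackMate) are imported through a
column-remapping dialect.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .shapes import LabelVolume
from .tracks import CORE_COLUMNS, validate_tracks

__all__ = ["read_tracks", "write_tracks", "TRACKMATE_DIALECT",
           "read_label_volume", "write_label_volume",
           "read_figure_source_table"]

# TrackMate spot-table column names -> native names.  time is rebuilt from
# the frame index and a frame interval because spot exports carry POSITION_T
# in seconds (or arbitrary units) depending on the calibration.
TRACKMATE_DIALECT = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x_um",
    "POSITION_Y": "y_um",
    "POSITION_Z": "z_um",
}


def read_tracks(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    frame_interval: float | None = None,
    default_cell_class: str = "dc_candidate",
) -> pd.DataFrame:
    """Read a track table, optionally remapping a foreign dialect.

    ``dialect`` maps source column names to native ones (see
    :data:`TRACKMATE_DIALECT`).  When the source lacks ``time_min`` it is
    rebuilt as frame x ``frame_interval``; when it lacks ``cell_class`` every
    track gets ``default_cell_class``.  Malformed rows (non-finite positions)
    are reported with their file line numbers.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
        df = df[[c for c in df.columns
                 if c in CORE_COLUMNS or c not in dialect.keys()]]
    if "time_min" not in df.columns:
        if frame_interval is None:
            raise ValueError("source table has no time_min column; supply "
                             "frame_interval to rebuild it")
        df["time_min"] = df["frame"] * frame_interval
    if "cell_class" not in df.columns:
        df["cell_class"] = default_cell_class
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path}: missing required column(s) "
                         f"{missing}")
    pos = df[["x_um", "y_um", "z_um"]].apply(pd.to_numeric, errors="coerce")
    bad = pos.isna().any(axis=1) | ~np.isfinite(pos).all(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(f"track file {path}: malformed position values on "
                         f"line(s) {lines[:20]}")
    df[["x_um", "y_um", "z_um"]] = pos
    df["frame"] = df["frame"].astype(int)
    extra = [c for c in df.columns if c not in CORE_COLUMNS]
    for c in extra:
        if df[c].dtype != bool:
            df[c] = df[c].map({True: True, False: False, "True": True,
                               "False": False, 1: True, 0: False}).astype(bool)
    df = df[CORE_COLUMNS + extra]
    df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
    return validate_tracks(df)


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    """Write a track table in the native CSV dialect (lossless round trip)."""
    validate_tracks(tracks)
    tracks.to_csv(path, index=False)


def read_label_volume(path: str | Path,
                      voxel_size: tuple[float, float, float] | None = None
                      ) -> LabelVolume:
    """Read a multi-page TIFF label stack; voxel size (z, y, x µm) comes from
    the ImageJ-style metadata written by :func:`write_label_volume` unless
    supplied explicitly."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if voxel_size is None:
            meta = tf.imagej_metadata or {}
            try:
                vz = float(meta["spacing"])
                tags = tf.pages[0].tags
                xres = tags["XResolution"].value
                yres = tags["YResolution"].value
                vx = xres[1] / xres[0]
                vy = yres[1] / yres[0]
                voxel_size = (vz, vy, vx)
            except (KeyError, TypeError):
                raise ValueError(f"{path}: no voxel size in metadata; pass "
                                 "voxel_size=(z, y, x)") from None
    return LabelVolume(voxels=np.asarray(data).astype(np.int32),
                       voxel_size=voxel_size)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    if volume.voxels.max() >= 2**16:
        raise ValueError("more than 65535 labels; ImageJ TIFF uses uint16")
    vz, vy, vx = volume.voxel_size
    tifffile.imwrite(
        str(path), volume.voxels.astype(np.uint16), imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"})


def read_figure_source_table(path: str | Path, sheet=0) -> pd.DataFrame:
    """Load a published figure source-data spreadsheet (xlsx or csv) for
    re-analysis (escape angles, nearest-neighbour identities, cycle scores).
    The column layout is publication-specific; this returns the raw table."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet)
    return pd.read_csv(path)
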