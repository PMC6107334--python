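import numpy as np
import pandas as pd
import pytest


def make_tracks(specs, frame_interval=20.0, markers=None):
    """Build a track table from {track_id: (cell_class, [positions...])}."""
    rows = []
    for tid, (cls, positions) in specs.items():
        for f, p in enumerate(positions):
            row = {"track_id": tid, "frame": f, "time_min": f * frame_interval,
                   "x_um": float(p[0]), "y_um": float(p[1]),
                   "z_um": float(p[2]), "cell_class": cls}
            if markers:
                for m, vals in markers.items():
                    row[m] = bool(vals.get(tid, False))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def three_point_track():
    """The worked 3-point trajectory: 7 µm path, 5 µm displacement."""
    return make_tracks({
        "t1": ("dc_candidate", [(0, 0, 0), (3, 0, 0), (3, 4, 0)]),
    })


@pytest.fixture
def toy_scene():
    """Deterministic scene: dense condensate sphere + sparse control box."""
    from dcmorph.scene import SceneFrame, Sphere

    rng = np.random.default_rng(42)
    dc = Sphere((50.0, 50.0, 50.0), 15.0)
    n_dc, n_if = 60, 30
    v = rng.normal(size=(n_dc, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    dc_pts = np.asarray(dc.center) + v * dc.radius * \
        rng.uniform(size=(n_dc, 1)) ** (1 / 3)
    if_sphere = Sphere((120.0, 50.0, 50.0), 15.0)
    v = rng.normal(size=(n_if, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if_pts = np.asarray(if_sphere.center) + v * if_sphere.radius * \
        rng.uniform(size=(n_if, 1)) ** (1 / 3)
    pts = np.vstack([dc_pts, if_pts])
    cells = pd.DataFrame({
        "cell_id": [f"c{i:03d}" for i in range(len(pts))],
        "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
        "sox2": [True] * n_dc + [False] * n_if,
    })
    return SceneFrame(cells=cells, regions={"dc": dc, "if": if_sphere},
                      dc_center=dc.center)
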