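"""Density, surface-distance, nearest-neighbour and label-fraction analyses."""

import numpy as np
import pandas as pd
import pytest
import trimesh

import dcmorph as dm
from dcmorph.scene import MaskRegion, SceneFrame, Sphere
from dcmorph.simulate import RegionSpec, SceneSpec, generate_point_scene
from dcmorph.spatial import (_point_triangle_distances, distances_to_point,
                             distances_to_surface, label_fraction,
                             nearest_neighbor_labels, neighbor_randomness_test,
                             region_density, shell_density)


def scene_from_points(points, **marker_cols):
    cells = pd.DataFrame({
        "cell_id": [f"c{i:03d}" for i in range(len(points))],
        "x_um": [p[0] for p in points],
        "y_um": [p[1] for p in points],
        "z_um": [p[2] for p in points],
    })
    for name, vals in marker_cols.items():
        cells[name] = list(map(bool, vals))
    return SceneFrame(cells=cells)


class TestRegionDensity:
    def test_constructed_two_to_one_ratio(self, toy_scene):
        rep = region_density(toy_scene, ["dc", "if"])
        assert rep.density("dc") / rep.density("if") == pytest.approx(2.0)
        assert rep.ratios["dc/if"] == pytest.approx(2.0)

    def test_counts_match_brute_force(self, toy_scene):
        rep = region_density(toy_scene, ["dc"])
        pos = toy_scene.positions
        d = np.linalg.norm(pos - np.array([50.0, 50.0, 50.0]), axis=1)
        assert rep.table.iloc[0]["count"] == int((d <= 15.0).sum())

    def test_empty_region_zero_density(self, toy_scene):
        toy_scene.regions["far"] = Sphere((500.0, 500.0, 500.0), 10.0)
        rep = region_density(toy_scene, ["far"])
        assert rep.table.iloc[0]["count"] == 0
        assert rep.density("far") == 0.0

    def test_paired_clone_uses_identical_volume(self, toy_scene):
        rep = region_density(toy_scene, ["dc"],
                             paired_clone=("dc", (70.0, 0.0, 0.0)))
        tab = rep.table.set_index("region")
        assert tab.loc["dc", "volume_um3"] == \
            pytest.approx(tab.loc["dc_paired", "volume_um3"])
        # the clone sits on the IF sphere of the fixture
        assert rep.ratios["dc/dc_paired"] == pytest.approx(2.0)

    def test_boundary_point_counts_as_inside(self):
        scene = scene_from_points([(10.0, 0.0, 0.0)])
        scene.regions["s"] = Sphere((0.0, 0.0, 0.0), 10.0)
        rep = region_density(scene, ["s"])
        assert rep.table.iloc[0]["count"] == 1

    def test_rigid_motion_invariance(self, toy_scene):
        from scipy.spatial.transform import Rotation

        rep1 = region_density(toy_scene, ["dc", "if"])
        rot = Rotation.from_euler("xyz", [0.4, 1.0, -0.2]).as_matrix()
        shift = np.array([12.0, -7.0, 30.0])
        cells = toy_scene.cells.copy()
        cells[["x_um", "y_um", "z_um"]] = toy_scene.positions @ rot.T + shift
        regions = {k: Sphere(tuple(rot @ np.asarray(r.center) + shift),
                             r.radius)
                   for k, r in toy_scene.regions.items()}
        rep2 = region_density(SceneFrame(cells=cells, regions=regions),
                              ["dc", "if"])
        pd.testing.assert_frame_equal(rep1.table, rep2.table)

    def test_poisson_scene_recovers_density(self):
        """Estimated density within 3 SE of the generating intensity over
        100 seeds."""
        lam = 6.0
        sphere = Sphere((50, 50, 50), 30)
        est = []
        for s in range(100):
            spec = SceneSpec(regions={"r": RegionSpec(sphere, density=lam)},
                             seed=s)
            scene = generate_point_scene(spec)
            est.append(region_density(scene, ["r"]).density("r"))
        n_expected = lam * sphere.volume / 1e4
        se = np.sqrt(n_expected / 100) / sphere.volume * 1e4
        assert abs(np.mean(est) - lam) < 3 * se


class TestShellDensity:
    def _bead_scene(self, points):
        scene = scene_from_points(points)
        scene.bead = Sphere((50.0, 50.0, 50.0), 10.0)
        return scene

    def test_cell_on_bead_surface_first_shell(self):
        scene = self._bead_scene([(60.0, 50.0, 50.0)])  # distance 0
        rep = shell_density(scene, mode="full_shell")
        assert rep.table.iloc[0]["count"] == 1
        assert rep.table.iloc[1]["count"] == 0

    def test_hand_placed_toy_scene_counts(self):
        # distances from surface: 0, 5, 14.9, 15, 29 -> shells [0,15): 3,
        # [15,30): 2
        pts = [(60, 50, 50), (65, 50, 50), (50, 50 + 24.9, 50),
               (50, 50, 75), (50 + 39, 50, 50)]
        rep = shell_density(self._bead_scene(pts), mode="full_shell")
        assert list(rep.table["count"]) == [3, 2]

    def test_uniform_scene_equal_shell_densities(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(40000, 3))
        scene = self._bead_scene(pts)
        rep = shell_density(scene, mode="full_shell")
        d = rep.table["density"].to_numpy()
        assert d[0] == pytest.approx(d[1], rel=0.15)

    def test_midplane_slice_areal_density(self):
        # 4 cells in the equatorial plane in the first annulus
        pts = [(62, 50, 50), (50, 62, 50), (38, 50, 50), (50, 38, 50),
               (62, 50, 70)]  # last far above midplane -> excluded
        rep = shell_density(self._bead_scene(pts), mode="midplane_slice",
                            slice_half_thickness=1.0)
        assert rep.table.iloc[0]["count"] == 4
        area = np.pi * (25.0**2 - 10.0**2)
        assert rep.table.iloc[0]["density"] == pytest.approx(4 / area * 1e4)

    def test_missing_bead_raises(self):
        scene = scene_from_points([(0, 0, 0)])
        with pytest.raises(ValueError, match="bead"):
            shell_density(scene)


class TestSurfaceDistances:
    def _sphere_mesh(self, center, radius, subdivisions=3):
        m = trimesh.creation.icosphere(subdivisions=subdivisions,
                                       radius=radius)
        return m.vertices + np.asarray(center), m.faces

    def test_point_on_surface_distance_zero(self):
        verts, faces = self._sphere_mesh((0, 0, 0), 10.0)
        p = verts[0]
        d = distances_to_surface([p], (verts, faces))
        assert d[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_outside_sphere_mesh(self):
        verts, faces = self._sphere_mesh((5, 5, 5), 10.0, subdivisions=4)
        p = np.array([5.0, 5.0, 5.0 + 17.0])
        d = distances_to_surface([p], (verts, faces))
        # 7 um outside; icosphere slightly inscribes the true sphere
        assert d[0] == pytest.approx(7.0, abs=0.05)

    def test_matches_exhaustive_triangle_brute_force(self):
        """Mesh distances equal the minimum over every triangle computed by
        an independent implementation (trimesh) to high precision."""
        rng = np.random.default_rng(3)
        verts, faces = self._sphere_mesh((0, 0, 0), 8.0, subdivisions=1)
        pts = rng.uniform(-15, 15, size=(50, 3))
        ours = distances_to_surface(pts, (verts, faces))
        mesh = trimesh.Trimesh(vertices=verts, faces=faces)
        closest, ref, _ = trimesh.proximity.closest_point_naive(mesh, pts)
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_pairwise_matrix_vs_per_triangle_loop(self):
        rng = np.random.default_rng(4)
        tri = rng.uniform(0, 10, size=(6, 3, 3))
        pts = rng.uniform(-5, 15, size=(10, 3))
        mat = _point_triangle_distances(pts, tri)
        for i, p in enumerate(pts):
            for j in range(len(tri)):
                single = _point_triangle_distances(p[None, :], tri[j:j + 1])
                assert mat[i, j] == pytest.approx(single[0, 0], abs=1e-12)

    def test_degenerate_triangles_skipped_with_warning(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]],
                         dtype=float)
        faces = np.array([[0, 1, 2], [0, 1, 3]])  # second is collinear
        with pytest.warns(UserWarning, match="degenerate"):
            d = distances_to_surface([[0.2, 0.2, 1.0]], (verts, faces))
        assert d[0] == pytest.approx(1.0)

    def test_mask_surface_distance(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[10, :, :] = True  # plane z = 10.5 voxel centers
        region = MaskRegion(mask, voxel_size=(1.0, 1.0, 1.0))
        d = distances_to_point([(5.0, 5.0, 3.0)], (5.0, 5.0, 3.0))
        assert d[0] == 0.0
        ds = distances_to_surface([(5.2, 5.2, 3.2)], region)
        assert ds[0] == pytest.approx(7.0, abs=1.0)  # voxel resolution

    def test_point_target_variant(self):
        d = distances_to_point([(0, 0, 0), (3, 4, 0)], (0, 0, 0))
        np.testing.assert_allclose(d, [0.0, 5.0])


class TestNearestNeighborLabels:
    def test_collinear_three_cells(self):
        scene = scene_from_points([(0, 0, 0), (1, 0, 0), (10, 0, 0)],
                                  pool=[1, 1, 1], lab=[1, 1, 0])
        rep = nearest_neighbor_labels(scene, "pool", "pool", "lab")
        row = rep.per_cell.set_index("focal_id").loc["c000"]
        assert row["neighbor_id"] == "c001"
        assert bool(row["neighbor_labeled"])

    def test_everyone_labeled_gives_proportion_one(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 50, size=(20, 3))
        scene = scene_from_points(pts, pool=[1] * 20, lab=[1] * 20)
        rep = nearest_neighbor_labels(scene, "pool", "pool", "lab")
        assert rep.prop_labeled == 1.0
        assert rep.expected_prop == 1.0

    def test_exact_ties_broken_by_lowest_id_and_counted(self):
        scene = scene_from_points([(0, 0, 0), (2, 0, 0), (-2, 0, 0)],
                                  pool=[1, 1, 1], lab=[1, 0, 1])
        rep = nearest_neighbor_labels(scene, "pool", "pool", "lab")
        row = rep.per_cell.set_index("focal_id").loc["c000"]
        assert row["neighbor_id"] == "c001"  # lowest id among the tie
        assert rep.n_ties >= 1

    def test_pool_restriction_removes_nonpool_influence(self):
        pts = [(0, 0, 0), (0.5, 0, 0), (5, 0, 0)]
        scene_all = scene_from_points(pts, pool=[1, 0, 1], lab=[1, 0, 1])
        rep = nearest_neighbor_labels(scene_all, "pool", "pool", "lab")
        row = rep.per_cell.set_index("focal_id").loc["c000"]
        assert row["neighbor_id"] == "c002"  # c001 not in pool

    def test_random_assortment_expectation(self):
        """Observed = expected counts gives chi2 = 0, p = 1."""
        rep = dm.NeighborReport(per_cell=pd.DataFrame(), n_focal=100,
                                prop_labeled=0.4, expected_prop=0.4)
        res = neighbor_randomness_test(rep)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # (90 labeled, 10 unlabeled) vs expectation 0.5: chi2 = 64
        rep = dm.NeighborReport(per_cell=pd.DataFrame(), n_focal=100,
                                prop_labeled=0.9, expected_prop=0.5)
        res = neighbor_randomness_test(rep)
        assert res.statistic == pytest.approx(64.0)
        assert res.p_value < 1e-10

    def test_degenerate_expectation_raises(self):
        rep = dm.NeighborReport(per_cell=pd.DataFrame(), n_focal=10,
                                prop_labeled=1.0, expected_prop=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            neighbor_randomness_test(rep)

    def test_chi_square_type_one_error_near_nominal(self):
        """Random assortment scenes: rejection at alpha=0.05 near 5% over
        many seeded scenes."""
        rejections = 0
        n_scenes = 300
        for s in range(n_scenes):
            spec = SceneSpec(regions={"r": RegionSpec(
                Sphere((60, 60, 60), 40), density=8.0,
                marker_fractions={"lab": 0.5, "all": 1.0})}, seed=s)
            scene = generate_point_scene(spec)
            rep = nearest_neighbor_labels(scene, "all", "all", "lab")
            res = neighbor_randomness_test(rep)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_scenes <= 0.09


class TestLabelFraction:
    def test_published_count_pair_to_percent(self):
        """53 of 82 lineage-labeled cells -> 64.6%, i.e. 65% at integer
        precision."""
        res = label_fraction((53, 82))
        assert res["percent"] == pytest.approx(100 * 53 / 82)
        assert round(res["percent"]) == 65

    def test_zero_of_n(self):
        res = label_fraction((0, 25))
        assert res["percent"] == 0.0
        assert res["ci_low"] == 0.0

    def test_scene_fraction_with_region_and_denominator(self, toy_scene):
        res = label_fraction(toy_scene, "sox2", region="dc")
        pos = toy_scene.positions
        d = np.linalg.norm(pos - np.array([50.0, 50.0, 50.0]), axis=1)
        inside = d <= 15.0
        expected = toy_scene.cells["sox2"].to_numpy()[inside].mean()
        assert res["fraction"] == pytest.approx(expected)

    def test_fucci_four_way_partition_sums_to_one(self):
        scene = scene_from_points(
            [(i, 0, 0) for i in range(8)],
            fucci_g1=[1, 1, 0, 0, 1, 0, 1, 0],
            fucci_sgm=[0, 1, 1, 0, 0, 1, 0, 0])
        frac = dm.fucci_fractions(scene)
        total = (frac["g1_only"] + frac["sgm_only"] + frac["both"]
                 + frac["neither"])
        assert total == pytest.approx(1.0)
        assert frac["both"] == pytest.approx(1 / 8)

    def test_empty_denominator_raises(self, toy_scene):
        with pytest.raises(ValueError, match="denominator"):
            label_fraction((5, 0))
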