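"""Agent-based generator: determinism, mode semantics, scene and label-volume
generation, drift round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dcmorph as dm
from dcmorph.scene import Box, Sphere
from dcmorph.simulate import (RegionSpec, SceneSpec, SimulationConfig,
                              generate_label_volume, generate_point_scene,
                              inject_drift, rasterize_ellipsoids, sample_vmf,
                              simulate_condensation)


def far_escape_angles(cfg, truncate=False):
    table, _ = simulate_condensation(cfg, return_scenes=False)
    corrected = dm.correct_drift(table)
    m = dm.compute_track_metrics(corrected, cfg.dc_center, truncate=truncate)
    g = dm.group_by_initial_distance(m)
    return g["dc_far"]["escape_angle_deg"].dropna().to_numpy()


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError, match="n_frames"):
            SimulationConfig(n_frames=1)
        with pytest.raises(ValueError, match="dc_center"):
            SimulationConfig(dc_center=(500, 0, 0))
        with pytest.raises(ValueError, match="dc_radius"):
            SimulationConfig(dc_radius=80, domain_extent=(100, 100, 100))
        with pytest.raises(ValueError, match="mode"):
            SimulationConfig(mode="teleportation")
        with pytest.raises(ValueError, match="trap_factor"):
            SimulationConfig(trap_factor=1.5)


class TestVonMisesFisher:
    def test_kappa_zero_isotropic_mean_cos(self):
        rng = np.random.default_rng(0)
        mu = np.tile([0.0, 0.0, 1.0], (20000, 1))
        v = sample_vmf(mu, 0.0, rng)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)
        assert abs(v[:, 2].mean()) < 0.02

    def test_concentration_matches_langevin_mean(self):
        # E[cos theta] = coth(kappa) - 1/kappa for the vMF on S2
        rng = np.random.default_rng(1)
        for kappa in (1.0, 4.0, 8.0):
            mu = np.tile([1.0, 0.0, 0.0], (20000, 1))
            v = sample_vmf(mu, kappa, rng)
            expected = 1.0 / np.tanh(kappa) - 1.0 / kappa
            assert v[:, 0].mean() == pytest.approx(expected, abs=0.02)


class TestSimulateCondensation:
    def test_seed_determinism_bit_identical(self):
        cfg = SimulationConfig(n_cells=40, n_frames=8, seed=9,
                               label_fraction=0.5)
        t1, s1 = simulate_condensation(cfg)
        t2, s2 = simulate_condensation(SimulationConfig(
            n_cells=40, n_frames=8, seed=9, label_fraction=0.5))
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1[-1].cells, s2[-1].cells)

    def test_cell_count_conserved_outside_proliferation(self):
        for mode in ("null", "migration", "nondispersal"):
            cfg = SimulationConfig.preset(mode, n_cells=50, n_frames=6,
                                          n_reference_cells=3, seed=2)
            table, _ = simulate_condensation(cfg, return_scenes=False)
            last = table[table["frame"] == cfg.n_frames - 1]
            assert last["track_id"].nunique() == 50 + 3

    def test_proliferation_adds_suffixed_daughters(self):
        cfg = SimulationConfig.preset("proliferation", n_cells=150,
                                      n_frames=30, seed=4)
        table, _ = simulate_condensation(cfg, return_scenes=False)
        ids = set(table["track_id"])
        daughters = [i for i in ids if ".d" in i]
        assert daughters, "expected division events"
        # each daughter's parent also exists and the daughter starts later
        starts = table.groupby("track_id")["frame"].min()
        for d in daughters:
            parent = d.rsplit(".d", 1)[0]
            assert parent in ids
            assert starts[d] > starts[parent]

    def test_null_mode_far_cells_isotropic(self):
        """Unbiased random walk: median escape angle of far cells ~ 90 deg
        and cos(angle) ~ Uniform(-1, 1)."""
        cfg = SimulationConfig.preset("null", n_cells=500, n_frames=40, seed=0)
        ang = far_escape_angles(cfg)
        assert len(ang) > 150
        se_median = 90.0 / (2 * 0.5 * np.sqrt(len(ang)))  # rough MC error
        assert abs(np.median(ang) - 90.0) < max(8.0, 3 * se_median / 10)

    def test_null_mode_cos_converges_to_uniform(self):
        cfg = SimulationConfig.preset("null", n_cells=3000, n_frames=40,
                                      seed=1)
        ang = far_escape_angles(cfg)
        assert len(ang) >= 1000
        cos = np.cos(np.deg2rad(ang))
        ks = stats.kstest(cos, stats.uniform(loc=-1, scale=2).cdf).statistic
        assert ks < 0.05

    def test_migration_mode_strong_inward_bias(self):
        """kappa=8 pulls far cells inward: median escape < 30 deg and the
        Watson test separates them from a null cohort."""
        cfg = SimulationConfig.preset("migration", bias_kappa=8.0, seed=0)
        ang = far_escape_angles(cfg, truncate=True)
        assert np.median(ang) < 30.0
        hits = 0
        for s in range(20):
            mig = far_escape_angles(SimulationConfig.preset(
                "migration", bias_kappa=8.0, n_cells=150, seed=s),
                truncate=True)
            nul = far_escape_angles(SimulationConfig.preset(
                "null", n_cells=150, seed=1000 + s), truncate=True)
            res = dm.watson_u2_test(
                dm.AngleSample(mig, "axial_magnitude"),
                dm.AngleSample(nul, "axial_magnitude"),
                n_permutations=499, seed=s)
            hits += res.p_value < 0.05
        assert hits >= 19

    def test_cycle_labels_follow_configured_fractions(self):
        cfg = SimulationConfig.preset("migration", n_cells=600, seed=3)
        _, scenes = simulate_condensation(cfg)
        scene = scenes[-1]
        frac = dm.fucci_fractions(scene, region="dc")
        assert frac["g1_only"] > 0.85            # configured 0.95 inside
        outside = scene.cells[~scene.in_region("dc")]
        assert 0.40 < outside["fucci_sgm"].mean() < 0.60  # configured 0.5

    def test_proliferation_enriches_sgm_inside(self):
        cfg = SimulationConfig.preset("proliferation", n_cells=400, seed=5)
        _, scenes = simulate_condensation(cfg)
        scene = scenes[-1]
        inside = scene.in_region("dc")
        sgm = scene.cells["fucci_sgm"].to_numpy()
        assert sgm[inside].mean() > sgm[~inside].mean()

    def test_reference_cells_exactly_stationary(self):
        cfg = SimulationConfig(n_cells=20, n_frames=10, n_reference_cells=5,
                               seed=6)
        table, _ = simulate_condensation(cfg, return_scenes=False)
        refs = table[table["cell_class"] == "reference"]
        for _, sub in refs.groupby("track_id"):
            pos = sub[["x_um", "y_um", "z_um"]].to_numpy()
            assert np.abs(pos - pos[0]).max() == 0.0


class TestDriftInjection:
    def test_zero_drift_is_identity(self):
        cfg = SimulationConfig(n_cells=10, n_frames=5, seed=7)
        table, _ = simulate_condensation(cfg, return_scenes=False)
        out = inject_drift(table, (0.0, 0.0, 0.0))
        pd.testing.assert_frame_equal(out, table)

    def test_linear_shift_per_frame(self):
        cfg = SimulationConfig(n_cells=5, n_frames=8, seed=8)
        table, _ = simulate_condensation(cfg, return_scenes=False)
        out = inject_drift(table, (1.0, 0.0, 0.0))
        at5 = out[out["frame"] == 5]
        orig = table[table["frame"] == 5]
        np.testing.assert_allclose(at5["x_um"], orig["x_um"] + 5.0)
        np.testing.assert_allclose(at5["y_um"], orig["y_um"])

    def test_round_trip_with_drift_correction(self):
        """inject_drift then correct_drift restores tracks to < 1e-9 um."""
        cfg = SimulationConfig(n_cells=30, n_frames=12, n_reference_cells=8,
                               seed=9)
        table, _ = simulate_condensation(cfg, return_scenes=False)
        drifted = inject_drift(table, (1.5, -0.75, 0.3))
        restored = dm.correct_drift(drifted)
        diff = np.abs(
            restored[["x_um", "y_um", "z_um"]].to_numpy()
            - table[["x_um", "y_um", "z_um"]].to_numpy())
        assert diff.max() < 1e-9


class TestPointScene:
    def test_density_contrast_recovered(self):
        """2:1 condensate/control density spec yields a measured ratio near
        2.0."""
        d0 = 8.0  # cells per 1e4 um^3
        spec = SceneSpec(regions={
            "dc": RegionSpec(Sphere((60, 60, 60), 25), density=2 * d0),
            "if": RegionSpec(Box((120, 20, 20), (220, 120, 120)), density=d0),
        }, seed=0)
        scene = generate_point_scene(spec)
        rep = dm.region_density(scene, ["dc", "if"])
        assert rep.ratios["dc/if"] == pytest.approx(2.0, rel=0.25)

    def test_poisson_counts_at_target_density(self):
        d = 5.0
        sphere = Sphere((50, 50, 50), 30)
        counts = []
        for s in range(100):
            spec = SceneSpec(regions={
                "r": RegionSpec(sphere, density=d)}, seed=s)
            counts.append(len(generate_point_scene(spec).cells))
        lam = d * sphere.volume / 1e4
        # mean of 100 Poisson(lam) draws within 3 SE
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / 100)

    def test_zero_marker_fraction_gives_no_positives(self):
        spec = SceneSpec(regions={"r": RegionSpec(
            Sphere((50, 50, 50), 30), density=5.0,
            marker_fractions={"sox2": 0.0})}, seed=1)
        scene = generate_point_scene(spec)
        assert not scene.cells["sox2"].any()

    def test_unclustered_label_assortment_is_random(self):
        """label_clustering=0, fraction p: labeled focal cells see a labeled
        nearest neighbour at rate ~ p over many seeds."""
        p = 0.4
        props = []
        for s in range(60):
            spec = SceneSpec(regions={"r": RegionSpec(
                Sphere((60, 60, 60), 40), density=6.0,
                marker_fractions={"lab": p, "all": 1.0})}, seed=s)
            scene = generate_point_scene(spec)
            rep = dm.nearest_neighbor_labels(scene, "all", "all", "lab")
            props.append(rep.prop_labeled)
        assert np.mean(props) == pytest.approx(p, abs=0.03)

    def test_clustered_labels_assort_nonrandomly(self):
        spec = SceneSpec(regions={"r": RegionSpec(
            Sphere((60, 60, 60), 40), density=8.0,
            marker_fractions={"lab": 0.4, "all": 1.0})},
            label_clustering=0.9, clustering_marker="lab", seed=2)
        scene = generate_point_scene(spec)
        rep = dm.nearest_neighbor_labels(scene, "all", "all", "lab")
        assert rep.prop_labeled > rep.expected_prop + 0.15

    def test_subunit_expected_count_warns(self):
        spec = SceneSpec(regions={"r": RegionSpec(
            Sphere((50, 50, 50), 3), density=1.0)}, seed=3)
        with pytest.warns(UserWarning, match="< 1"):
            generate_point_scene(spec)


class TestLabelVolume:
    def test_digital_ball_volume_within_one_percent(self):
        r = 20.0
        vol = rasterize_ellipsoids([(30, 30, 30)], [(r, r, r)],
                                   shape=(61, 61, 61),
                                   voxel_size=(1.0, 1.0, 1.0))
        measured = (vol.voxels == 1).sum()
        assert measured == pytest.approx(4 / 3 * np.pi * r**3, rel=0.01)

    def test_empty_spec_region_gives_empty_volume(self):
        spec = SceneSpec(regions={"r": RegionSpec(
            Sphere((30, 30, 30), 10), density=0.001, semi_axes=(3, 3, 3))},
            seed=4)
        with pytest.warns(UserWarning, match="< 1"):
            vol = generate_label_volume(spec, voxel_size=(1, 1, 1))
        assert vol.voxels.max() == 0

    def test_two_disjoint_ellipsoids_two_labels(self):
        vol = rasterize_ellipsoids([(15, 15, 15), (45, 15, 15)],
                                   [(5, 4, 3), (4, 4, 4)],
                                   shape=(31, 31, 61),
                                   voxel_size=(1.0, 1.0, 1.0))
        assert set(np.unique(vol.voxels)) == {0, 1, 2}

    def test_overlapping_ellipsoids_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            rasterize_ellipsoids([(15, 15, 15), (18, 15, 15)],
                                 [(5, 5, 5), (5, 5, 5)],
                                 shape=(31, 31, 31),
                                 voxel_size=(1.0, 1.0, 1.0))

    def test_border_touching_recorded(self):
        vol = rasterize_ellipsoids([(3, 15, 15)], [(4, 4, 4)],
                                   shape=(31, 31, 31),
                                   voxel_size=(1.0, 1.0, 1.0))
        assert vol.meta["border_labels"] == [1]
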