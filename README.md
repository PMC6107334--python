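# dcmorph

Quantitative analysis of **dermal condensate (DC) morphogenesis** — the local
aggregation of dermal fibroblasts beneath a nascent hair-follicle placode.

A condensate can in principle acquire its cells in three ways: (i) local
proliferation, (ii) directed migration of fibroblasts toward the site, or
(iii) failure of cells to disperse once there. Distinguishing these requires
a set of quantitative analyses over 4D cell tracks, 3D point clouds of cell
centers, and segmented-nucleus label volumes. `dcmorph` implements that
toolkit for developmental biologists working with time-lapse confocal data:

- **Trajectory analysis** — fiducial-based translational drift correction;
  per-track velocity (track length / duration), net velocity (displacement /
  duration), straightness (displacement / track length); the **escape angle**
  α = arccos(a·b / |a||b|) between a cell's net displacement **a** and the
  vector **b** from its start to the condensate center (0° = straight toward
  the condensate); grouping of tracks by initial distance at the 30 µm
  condensate diameter; optional truncation of tracks at condensate entry.
- **Circular statistics** — Rayleigh Z uniformity test, Watson two-sample U²
  with a permutation null, and a Monte-Carlo test against the 3D
  uniform-on-sphere null (cos α ~ U(−1, 1)), which is the correct null for
  unsigned 3D escape angles.
- **Spatial analysis** — per-region densities (cells per 10⁴ µm³) with a
  paired identical-volume control mode, radial shell densities around a
  protein-soaked bead, exact point-to-mesh distances, nearest-neighbour label
  composition with a χ² randomness test, and marker fractions (including
  four-way Fucci cell-cycle scoring) with binomial confidence intervals.
- **Shape analysis** — per-nucleus volume, surface area (smoothed marching
  cubes) and Wadell sphericity ψ = π^{1/3}(6V)^{2/3}/A from label volumes.
- **Assay statistics** — the Shapiro-Wilk-gated adaptive test policy
  (t-test/ANOVA vs Mann-Whitney/Wilcoxon/Kruskal), one-sample ratio tests,
  scratch-wound closure, transwell relative migration, and ΔΔCt fold changes.
- **Synthetic data** — an agent-based simulator that renders each of the
  three condensation mechanisms as a regime of a von-Mises-Fisher-biased
  random walk (divisions, trapping, cycle and lineage labels, stationary
  reference cells, injected drift), plus generators for point scenes and
  rasterized nuclear label volumes. Every analysis stage is therefore
  testable with no external data.

## Worked example

```python
import numpy as np
import dcmorph as dm
from dcmorph.simulate import SimulationConfig, simulate_condensation

cfg = SimulationConfig.preset("migration", seed=1)   # biased-walk regime
tracks, scenes = simulate_condensation(cfg)

corrected = dm.correct_drift(tracks)                 # fiducial registration
metrics = dm.compute_track_metrics(corrected, cfg.dc_center, truncate=True)
groups = dm.group_by_initial_distance(metrics)       # 30 um far/near split

far = groups["dc_far"]["escape_angle_deg"].dropna().to_numpy()
print("median escape angle (far cells):", round(float(np.median(far)), 1))
res = dm.sphere_uniformity_test(dm.AngleSample(far, "axial_magnitude"), seed=0)
print("mean cos(alpha):", round(res.statistic, 3), " p =", res.p_value)
```

prints

```
median escape angle (far cells): 4.3
mean cos(alpha): 0.996  p = 0.00019998000199980003
```

A median escape angle far below 90° with a mean inward cosine near 1 says the
far cohort moves almost straight at the condensate center; under the
unbiased (`"null"`) regime the same numbers come out as ≈ 90° and ≈ 0 with a
non-significant p. The same pipeline run end-to-end
(`dcmorph run --config run.yaml --out-dir out/`) writes per-track metrics,
a JSON summary with every test's method note and seed, and a plain-text
report flagging which mechanism signatures are present.

A command-line interface mirrors the library
(`dcmorph simulate|tracks|directionality|density|shape|neighbors|fractions|assays|run|report`).

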