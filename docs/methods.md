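# Methods

This note documents the models, estimators and design choices behind
`dcmorph`, in the spirit of a methods appendix: what each computation assumes,
which knobs matter, and what the synthetic data do and do not establish.

## Trajectory metrics and the escape angle

A track is a per-cell time series of 3D positions sampled at a fixed frame
interval (default 20 min, matching typical gentle live-confocal cadence for
embryonic skin explants). Metrics per track:

- track length `L` = Σ segment lengths (µm), displacement `D` = |end − start|
- duration `T` = last − first time (min)
- velocity = `L/T`, net velocity = `D/T`, straightness = `D/L` ∈ [0, 1].
  `velocity ≥ net_velocity` always (triangle inequality); for a
  single-segment track the two path measures are the same quantity, and the
  implementation shares the computed value so straightness is exactly 1.
- escape angle α = arccos(a·b/|a||b|) with `a` the net displacement and `b`
  the start→center vector, in degrees ∈ [0, 180]. `a` uses the endpoint of
  the (possibly truncated) track; there is no other defensible
  operationalization of "trajectory direction" at this sampling rate.

**Condensate center.** Fixed per movie; for simulated data it is the known
generator center, for real data the centroid of the condensate-marker signal
(configurable per-frame variant available). Interfollicular control tracks
are referred to an arbitrary migration center, defaulting to the centroid of
their own starting positions.

**Far/near grouping.** Condensate-candidate tracks split at an initial
distance of 30 µm — the average condensate diameter — with the boundary value
assigned to *near* (`>` is far, `≤` near; the convention is asserted in
tests). **Entry truncation** cuts a track at its first frame strictly inside
the entry radius (default 15 µm, half the condensate diameter), provided that
frame is after the start: a track born inside never "enters". Truncation can
only shorten a track, and with entry radius 0 it is a no-op.

**Drift correction.** Translational stage/tissue drift is estimated per frame
as the mean displacement (relative to frame 0) of designated non-motile
reference cells and subtracted from all positions. At least 7 reference cells
are recommended (a warning below that); reference tracks must span every
frame. `correct_drift ∘ inject_drift` is the identity to machine precision,
which the tests verify as a round trip.

## Circular statistics

Two frames of reference are kept explicit because they have different nulls:

- *planar signed* angles in [0, 360°): classical circular data. Rayleigh's
  Z = nR̄² tests uniformity against unimodal concentration; the p-value uses
  the standard series approximation
  p ≈ e^(−Z)[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
  accurate for n ≥ 10 (cross-checked in tests against an independent
  implementation).
- *axial magnitudes* in [0, 180°]: unsigned angles between 3D displacements
  and a fixed axis. Under isotropic 3D motion these are **not** uniform on
  the circle — cos α is Uniform(−1, 1) — so applying Rayleigh to them would
  reject isotropy almost surely. `rayleigh_test` therefore refuses axial
  input, and `sphere_uniformity_test` provides the correct null: statistic
  mean cos α, Monte-Carlo two-sided p against means of n U(−1, 1) draws
  (default 10⁴ draws, add-one smoothed, seeded). Signed 2D-projection angles
  are also computed per track for users who prefer the planar pathway; the
  axial pathway is the package default and every report records which was
  used.

**Watson two-sample U²** is computed from the pooled-rank interleaving with
tie groups advanced jointly (so identical samples give U² = 0 exactly), and
depends only on ranks — hence it applies unchanged to axial magnitudes and is
invariant to sample swap and common rotation. The default p-value is by label
permutation (9999 permutations, add-one smoothing, seeded); exact enumeration
of all pooled splits is available for small samples (verified against an
independent brute force at n = m = 5) and the classical asymptotic series as
a fast option. No multiple-testing correction is applied anywhere; raw
p-values are reported with their method notes.

## Spatial analyses

Densities are counts over closed regions (boundary points count as inside,
for determinism) divided by region volume, reported per 10⁴ µm³ — readable
magnitudes at tissue scale (a fibroblast-dense dermis is ~5–20 cells per
10⁴ µm³). Condensate-vs-control comparisons use a *paired clone*: the
condensate region's exact shape translated to a user-chosen interfollicular
offset, so both counts use identical volumes. Bead shell analysis measures
distances from the bead *surface* (left-closed bins starting at 0) and
supports a mid-bead optical-slice mode (areal density over planar annuli;
half-thickness defaults to 0.5 µm, one typical confocal z-step).

Point-to-surface distances are exact point-to-triangle minima for meshes
(vectorised barycentric clamping, tested against an exhaustive per-triangle
brute force) and distance-transform lookups for voxel masks
(resolution-limited, which the docstring states).

Nearest-neighbour label analysis takes labeled focal cells, finds each one's
nearest *other* pool cell (exact ties broken toward the lowest cell id and
counted), and compares the labeled-neighbour proportion against the
random-assortment expectation — the labeled fraction of the pool excluding
the focal cell; the global pool fraction is the default (a per-region
expectation is obtained by subsetting the scene). The 1-df χ² against that
expectation treats the n focal indicators as independent; nearest-neighbour
relations are weakly dependent (mutual pairs), so the test is mildly
anticonservative — measured ≈ 6% rejection at nominal 5% over 1000 simulated
random-assortment scenes. This matches how the test is used in practice and
is far smaller than the effects of interest (labeled-neighbour proportions of
~0.9 against expectations of ~0.5–0.65).

Marker fractions carry Wilson binomial confidence intervals; four-way
cell-cycle reporter scoring (G1-only / S-G2-M-only / both / neither) always
sums to 1 over the denominator population. Reporter positivity from raw
intensities requires a user threshold (an Otsu default is deliberately not
silently applied; manual cutoffs are not reproducible and the threshold used
is always recorded).

## Nuclear shape

Volume is the voxel count scaled by the physical voxel size (exact for
rasterized shapes up to rasterization error, <1% at radius ≥ 15 voxels).
Surface area comes from marching cubes at the 0.5 level after a 1-voxel
Gaussian smoothing of the padded binary object, with anisotropic voxel
spacing applied before triangulation. The smoothing matters: a raw binary
marching-cubes surface overestimates a sphere's area by ~9% (voxel-face
counting by ~50%), while the smoothed estimator is within ~0.5% at radius 20
voxels — so digital-ball sphericities land within ±3% of 1 and can slightly
exceed 1 (documented estimator tolerance ε = 0.05).

Sphericity is Wadell's ψ = π^{1/3}(6V)^{2/3}/A, the conventional definition
used by commercial 3D rendering suites (whose exact formula is otherwise
undocumented; reports state the Wadell assumption). Border-touching objects
have undefined area and are excluded from group statistics by default
(override available); objects narrower than 2 voxels on any axis are
sub-resolution and always excluded. Voxel anisotropy beyond 5:1 triggers a
warning because the area estimator degrades. Group comparisons of sphericity
go through the adaptive location test below.

## Assay statistics

The testing policy is gated on normality: Shapiro-Wilk at α = 0.05 per group;
all pass → two-tailed t-test (Welch by default for unpaired data, since equal
variances are the exception in these assays) or one-way ANOVA for >2 groups;
any fail → Mann-Whitney U / Wilcoxon signed-rank / Kruskal-Wallis. A
constant-valued group has undefined normality and falls to the nonparametric
branch with a warning. The chosen branch and the Shapiro p-values are always
recorded in the method note. Calibration of the *composite* procedure is a
property test: empirical type-I error stays within [0.03, 0.07] at nominal
0.05 under Gaussian and heavy-tailed nulls.

Ratio assays: wound closure = 100·(1 − open area at t / open area at 0 h),
negative values (wound widening) warned but allowed; transwell relative
migration = condition mean count / vehicle-baseline mean count, with nested
duplicate-insert × field structure averaged per replicate first — the only
reading compatible with testing the ratio against 1 by a one-sample t-test;
ΔΔCt fold change = 2^−ΔΔCt, invariant to adding a constant to all four Ct
values.

## The synthetic-data generator

The simulator renders the three classical condensation mechanisms as regimes
of one biased random walk, so that the full downstream pipeline can be run on
data whose generating mechanism is known:

| regime | bias | trapping | divisions | cycle labels |
|---|---|---|---|---|
| null | none | none | none | 50/50 everywhere |
| migration | vMF κ=4 toward center, outside r | speed ×0.2 inside r | none | 95% G1 inside, 50% outside |
| proliferation | none | none | 0.12 /cell/h inside r (cycle ~8 h), 0.01 outside | 50/50 baseline; divided cells S/G2/M |
| nondispersal | none | speed ×0.2 inside r | none | 95% G1 inside, 50% outside |

Step model: per-frame displacement = speed × frame interval along a unit
direction drawn from a von Mises-Fisher distribution about the cell→center
unit vector (κ = 0 isotropic; sampler verified against the Langevin mean
cos θ = coth κ − 1/κ). Speeds are drawn per cell per frame from a clipped
normal, mean 0.10 µm/min (sd 0.04) — *illustrative*, not fitted: no measured
embryonic-fibroblast speed distribution was available, and these values put
track velocities in the 0.1–0.5 µm/min range typical of mesenchyme while
keeping 13-h random walks well inside the simulated volume. Defaults: 400
cells (25% interfollicular controls), initial box 200 × 200 × 120 µm,
condensate radius 15 µm at the center, 40 frames at 20 min (~13 h), 8
stationary reference cells. 40% of condensate candidates are seeded inside
the condensate at t = 0, reflecting that imaging typically starts once an
incipient condensate is visible — and giving the proliferation regime a
population to amplify.

**Boundary handling.** The domain box shapes only the initial placement; by
default walkers are unbounded afterwards. Reflecting walls were implemented
and rejected as the default: because the condensate sits at the domain
center, reflection pushes net displacements toward it, biasing the isotropic
null (measured mean cos α ≈ +0.04..+0.06 and sphere-test type-I error of
7–20% at nominal 5% on 30-seed null calibration runs). The unbounded walk
makes the null exact (null-regime far cells: median escape 90.5°, KS distance
of cos α from U(−1,1) = 0.02 at n ≈ 1300) while still conserving cell count;
`boundary="reflect"` remains available for users who need a closed volume.

Divisions are a per-frame Bernoulli approximation of a Poisson process;
daughters appear one nuclear diameter (7 µm) away with id suffix `.d<frame>`
and move independently; divisions are suppressed on the final frame (a
single-point daughter track has no measurable movement). Cells that divided
carry the S/G2/M label, so proliferation-regime cycle enrichment *emerges*
from the division process rather than being painted on.

Lineage labels cover a configurable fraction of condensate candidates; with
`label_clustering` > 0 labeled cells are biased toward the condensate center
(tracks) or placed within one Poisson mean nearest-neighbour distance
(0.5539 ρ^{−1/3}) of an existing labeled cell (static scenes), emulating
non-random assortment of early-labeled cells.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analyses assume — directional bias, density
contrast, cycle-label composition, clustered labeling, rigid drift,
ellipsoidal nuclei — but not imaging physics (no PSF, noise, segmentation
errors, track breaks or misassignments), no mechanical crowding or
cell-cell adhesion, and no epithelial signaling dynamics. Pipeline
correctness on synthetic data therefore validates the estimators and the
inference logic, not robustness to tracking artefacts in real movies.

## Pipeline and mechanism signatures

`run_pipeline` executes stages in dependency order (drift correction →
metrics → grouping → circular tests; density / cycle fractions / neighbours
on the final scene), derives per-stage random streams independently from the
global seed (inserting a stage never perturbs another stage's randomness),
and emits a JSON summary plus a human-readable report listing every test
with its method note and seed. Identical config + seed ⇒ byte-identical
summaries.

Two mechanism signatures are called, each at a signature threshold of
α = 0.01 (stricter than 0.05 because two independent signatures are screened
per run and the discrimination claim is about joint correctness):

- *directed migration*: sphere-uniformity p < α with positive mean inward
  cosine, evaluated separately for far condensate candidates and for
  interfollicular controls (which must stay negative);
- *proliferation*: one-sided two-proportion z-test of S/G2/M fraction inside
  vs outside the condensate, p < α.

On 100 seeded runs per regime at default conditions the pipeline recovers
the correct signature pattern (migration: far-cell bias only; proliferation:
cycle enrichment only; non-dispersal: neither) in ≥ 95 runs per regime —
measured at 100/100, 100/100 and ≥ 95/100 respectively in the acceptance
suite.

## Numerical conventions

µm and minutes everywhere; angles in degrees; frames 0-based; scenes and
regions in (x, y, z) µm, voxel grids in (z, y, x) with per-axis voxel size;
closed regions; densities per 10⁴ µm³ (or µm² in slice mode); all
permutation/Monte-Carlo seeds recorded in method notes. Problem sizes in the
test and acceptance suites (e.g. 250–400 cells, 100 seeds per regime,
999–9999 permutations) were chosen as the smallest sizes at which the
Monte-Carlo error of each check is comfortably below its assertion margin.

## Known limitations

- The escape-angle statistic summarises a whole track by its endpoint; it is
  blind to within-track directional switching.
- The χ² neighbour test inherits the mild anticonservativeness discussed
  above; a permutation variant would remove it at some cost in speed.
- Mask-based surface distances are voxel-resolution-limited; use meshes when
  sub-voxel accuracy matters.
- The simulator's speed scale is illustrative; absolute velocity/net-velocity
  values from synthetic data should not be compared to real tissue, only
  their group contrasts.
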