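"""Circular statistics for cell-movement directions.

Two frames of reference are distinguished:

* ``planar_signed`` — signed directions on the circle, degrees in [0, 360).
  Suitable for the classical Rayleigh uniformity test and for Watson's
  two-sample U² test.
* ``axial_magnitude`` — unsigned angles between a 3D displacement and a fixed
  axis, degrees in [0, 180].  Under isotropic 3D motion these are *not*
  uniform on the circle (cos α is uniform on [-1, 1]), so uniformity must be
  tested against the uniform-on-sphere null (:func:`sphere_uniformity_test`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import comb

from .results import TestResult

__all__ = [
    "AngleSample",
    "rayleigh_test",
    "watson_u2_test",
    "sphere_uniformity_test",
]


@dataclass
class AngleSample:
    """A sample of angles in degrees with its declared frame of reference."""

    angles: np.ndarray
    frame_of_reference: str = "planar_signed"  # or "axial_magnitude"

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float).ravel()
        if self.angles.size < 1:
            raise ValueError("angle sample must contain at least one angle")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.frame_of_reference == "planar_signed":
            self.angles = np.mod(self.angles, 360.0)
        elif self.frame_of_reference == "axial_magnitude":
            if np.any(self.angles < 0) or np.any(self.angles > 180):
                raise ValueError("axial angles must lie in [0, 180] degrees")
        else:
            raise ValueError(
                f"unknown frame_of_reference {self.frame_of_reference!r}")

    @property
    def n(self) -> int:
        return self.angles.size


def _mean_resultant_length(angles_deg: np.ndarray) -> float:
    rad = np.deg2rad(angles_deg)
    return float(np.hypot(np.cos(rad).sum(), np.sin(rad).sum()) / rad.size)


def rayleigh_p(z: float, n: int) -> float:
    """Series approximation of the Rayleigh test p-value (Zar's correction)."""
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(np.clip(p, 0.0, 1.0))


def rayleigh_test(sample: AngleSample) -> TestResult:
    """Rayleigh Z test of circular uniformity against unimodal concentration.

    Z = n·R̄² with R̄ the mean resultant length.  Small p indicates a
    concentrated (directional) distribution.
    """
    if sample.frame_of_reference != "planar_signed":
        raise ValueError(
            "Rayleigh test requires signed planar angles in [0, 360); "
            "axial magnitudes in [0, 180] are not circularly uniform under "
            "isotropic 3D motion — use sphere_uniformity_test, or convert to "
            "signed 2D-projection angles first")
    n = sample.n
    if n < 4:
        raise ValueError("Rayleigh test needs n >= 4 angles")
    rbar = _mean_resultant_length(sample.angles)
    z = n * rbar**2
    return TestResult(
        statistic_name="rayleigh_Z",
        statistic=float(z),
        p_value=rayleigh_p(z, n),
        n=n,
        method_note="asymptotic series p-value (accurate for n >= 10)",
        extra={"mean_resultant_length": rbar},
    )


# ---------------------------------------------------------------------------
# Watson two-sample U²
# ---------------------------------------------------------------------------


def _watson_u2_stat(values: np.ndarray, in_first: np.ndarray) -> float:
    """Watson U² from a pooled sample and a first-sample membership mask.

    Ties across samples are handled by advancing both empirical CDFs over each
    tie group before recording the difference; tie-group sizes weight the sum.
    """
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    a = in_first[order]
    n = int(in_first.sum())
    m = in_first.size - n
    cum1 = np.cumsum(a) / n
    cum2 = np.cumsum(~a) / m
    d = cum1 - cum2
    # group ends: last index of each run of equal values
    last = np.r_[v[1:] != v[:-1], True]
    boundaries = np.flatnonzero(last)
    t = np.diff(np.r_[-1, boundaries]).astype(float)  # tie-group sizes
    dg = d[boundaries]
    N = n + m
    u2 = n * m / N**2 * float((t * dg**2).sum() - (t * dg).sum() ** 2 / N)
    return u2


def _watson_u2_stats_many(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Vectorised U² for many membership masks over one pooled sample.

    ``values`` must already be sorted ascending; ``masks`` is (P, N) boolean.
    """
    n = int(masks[0].sum())
    m = masks.shape[1] - n
    N = n + m
    cum1 = np.cumsum(masks, axis=1) / n
    cum2 = np.cumsum(~masks, axis=1) / m
    d = cum1 - cum2
    last = np.r_[values[1:] != values[:-1], True]
    boundaries = np.flatnonzero(last)
    t = np.diff(np.r_[-1, boundaries]).astype(float)
    dg = d[:, boundaries]
    return n * m / N**2 * ((t * dg**2).sum(axis=1) - (t * dg).sum(axis=1) ** 2 / N)


def _asymptotic_watson_p(u2: float, terms: int = 50) -> float:
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(np.clip(p, 0.0, 1.0))


def watson_u2_test(
    sample1: AngleSample,
    sample2: AngleSample,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
) -> TestResult:
    """Watson's two-sample U² test for a difference between two circular
    (or axial) angle distributions.

    The statistic depends only on the interleaving of the pooled ranks, so it
    applies unchanged to axial magnitudes.  The default p-value is obtained by
    label permutation of the pooled sample with add-one smoothing; ``method``
    may also be ``"exact"`` (full enumeration of pooled splits, small samples
    only) or ``"asymptotic"`` (classical series, valid without heavy ties).
    """
    if sample1.frame_of_reference != sample2.frame_of_reference:
        raise ValueError("samples must share a frame of reference")
    n, m = sample1.n, sample2.n
    if n < 8 or m < 8:
        warnings.warn(f"Watson U2 with small samples (n={n}, m={m}); "
                      "p-value may be coarse", stacklevel=2)
    pooled = np.concatenate([sample1.angles, sample2.angles])
    mask = np.zeros(n + m, dtype=bool)
    mask[:n] = True
    u2 = _watson_u2_stat(pooled, mask)

    n_cross_ties = int(np.isin(sample1.angles, sample2.angles).sum())
    if n_cross_ties > 0.25 * min(n, m):
        warnings.warn("heavy ties across the two angle samples; "
                      "tie-grouped statistic used", stacklevel=2)

    order = np.argsort(pooled, kind="mergesort")
    v = pooled[order]
    N = n + m
    if method == "permutation":
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_permutations, N), dtype=bool)
        for i in range(n_permutations):
            masks[i, rng.choice(N, size=n, replace=False)] = True
        stats = _watson_u2_stats_many(v, masks)
        p = (1.0 + np.sum(stats >= u2 - 1e-12)) / (n_permutations + 1.0)
        note = f"label permutation, {n_permutations} permutations, seed={seed}"
    elif method == "exact":
        total = comb(N, n, exact=True)
        if total > 200_000:
            raise ValueError(f"exact enumeration infeasible: C({N},{n})={total}")
        masks = np.zeros((total, N), dtype=bool)
        for i, idx in enumerate(combinations(range(N), n)):
            masks[i, list(idx)] = True
        stats = _watson_u2_stats_many(v, masks)
        p = float(np.mean(stats >= u2 - 1e-12))
        note = f"exact enumeration of all {total} pooled splits"
    elif method == "asymptotic":
        p = _asymptotic_watson_p(u2)
        note = "asymptotic series p-value"
    else:
        raise ValueError(f"unknown method {method!r}")

    return TestResult(
        statistic_name="watson_U2",
        statistic=float(u2),
        p_value=float(p),
        n=n,
        m=m,
        method_note=note,
        extra={"n_cross_sample_ties": n_cross_ties},
    )


# ---------------------------------------------------------------------------
# Uniform-on-sphere null for axial escape angles
# ---------------------------------------------------------------------------


def sphere_uniformity_test(
    sample: AngleSample,
    n_mc: int = 10000,
    seed: int | None = None,
) -> TestResult:
    """Test axial angles against the isotropic-3D-direction null.

    Statistic: mean of cos(angle).  Under isotropy the cosine of the angle
    between a random direction and a fixed axis is Uniform(-1, 1), so the null
    distribution of the statistic is a mean of n such uniforms, sampled by
    Monte Carlo.  Two-sided p with add-one smoothing.  A positive statistic
    with small p indicates net movement toward the reference axis target.
    """
    if sample.frame_of_reference != "axial_magnitude":
        raise ValueError("sphere uniformity test requires axial angles in [0, 180]")
    if n_mc < 1000:
        warnings.warn(f"n_mc={n_mc} < 1000 gives a coarse Monte-Carlo p-value",
                      stacklevel=2)
    n = sample.n
    stat = float(np.mean(np.cos(np.deg2rad(sample.angles))))
    rng = np.random.default_rng(seed)
    null = rng.uniform(-1.0, 1.0, size=(n_mc, n)).mean(axis=1)
    p_hi = (1.0 + np.sum(null >= stat - 1e-15)) / (n_mc + 1.0)
    p_lo = (1.0 + np.sum(null <= stat + 1e-15)) / (n_mc + 1.0)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return TestResult(
        statistic_name="mean_cos_alpha",
        statistic=stat,
        p_value=float(p),
        n=n,
        method_note=f"Monte-Carlo two-sided vs cos~U(-1,1), n_mc={n_mc}, seed={seed}",
    )
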