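"""Scalar assay quantifications and the normality-gated testing policy.

The testing policy mirrors common practice in developmental-biology papers:
Shapiro-Wilk at alpha = 0.05 on each group decides between the parametric
branch (t-test / one-way ANOVA) and the nonparametric branch (Mann-Whitney U /
Wilcoxon signed-rank / Kruskal-Wallis).  The chosen branch is always recorded
in the result's method note.  No multiple-testing correction is applied; raw
p-values are reported.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .results import TestResult

SHAPIRO_ALPHA = 0.05

__all__ = ["adaptive_location_test", "one_sample_ratio_test", "wound_closure",
           "relative_migration", "ddct_fold_change"]


def _is_normalish(x: np.ndarray) -> tuple[bool, float]:
    if np.ptp(x) == 0:
        return False, np.nan  # constant sample: normality undefined
    return (p := float(stats.shapiro(x).pvalue)) > SHAPIRO_ALPHA, p


def adaptive_location_test(*groups, paired: bool = False) -> TestResult:
    """Two-or-more-group location comparison with a Shapiro-Wilk gate.

    Each group passes Shapiro-Wilk (alpha 0.05) -> parametric branch:
    two-tailed t-test (paired or Welch unpaired) for 2 groups, one-way ANOVA
    for more.  Any group fails -> nonparametric branch: Mann-Whitney U
    (Wilcoxon signed-rank when paired) or Kruskal-Wallis.  A constant-valued
    group has undefined normality and falls to the nonparametric branch with
    a warning.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 3:
            raise ValueError("each group needs n >= 3")
    if paired and len(groups) != 2:
        raise ValueError("paired comparison requires exactly two groups")
    if paired and len(groups[0]) != len(groups[1]):
        raise ValueError("paired groups must have equal lengths")

    gate = [_is_normalish(g) for g in groups]
    if any(np.isnan(p) for _, p in gate):
        warnings.warn("constant-valued group: normality undefined; using "
                      "nonparametric branch", stacklevel=2)
    normal = all(ok for ok, _ in gate)
    sw_note = ", ".join(f"SW p={p:.3g}" for _, p in gate)

    if len(groups) == 2:
        x, y = groups
        if normal:
            if paired:
                if np.ptp(x - y) == 0:
                    stat, p, name = 0.0, 1.0, "paired_t"
                else:
                    r = stats.ttest_rel(x, y)
                    stat, p, name = r.statistic, r.pvalue, "paired_t"
            else:
                r = stats.ttest_ind(x, y, equal_var=False)
                stat, p, name = r.statistic, r.pvalue, "welch_t"
        else:
            if paired:
                d = x - y
                if np.ptp(d) == 0 and np.all(d == 0):
                    stat, p, name = 0.0, 1.0, "wilcoxon_signed_rank"
                else:
                    r = stats.wilcoxon(x, y)
                    stat, p, name = r.statistic, r.pvalue, "wilcoxon_signed_rank"
            else:
                r = stats.mannwhitneyu(x, y, alternative="two-sided")
                stat, p, name = r.statistic, r.pvalue, "mann_whitney_U"
    else:
        if paired:
            raise ValueError("paired comparison requires exactly two groups")
        if normal:
            r = stats.f_oneway(*groups)
            stat, p, name = r.statistic, r.pvalue, "one_way_anova_F"
        else:
            r = stats.kruskal(*groups)
            stat, p, name = r.statistic, r.pvalue, "kruskal_wallis_H"

    branch = "parametric" if normal else "nonparametric"
    return TestResult(
        statistic_name=name, statistic=float(stat), p_value=float(p),
        n=len(groups[0]), m=len(groups[1]) if len(groups) == 2 else None,
        method_note=f"{branch} branch via Shapiro-Wilk gate "
                    f"(alpha={SHAPIRO_ALPHA}); {sw_note}; paired={paired}",
    )


def one_sample_ratio_test(fold_changes, null_value: float = 1.0,
                          log_scale: bool = False) -> TestResult:
    """One-sample t-test of normalized values (e.g. qRT-PCR fold changes or
    relative migration ratios) against a null ratio, by default 1."""
    x = np.asarray(fold_changes, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("need n >= 3 values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: one-sample t statistic undefined")
    if log_scale:
        if np.any(x <= 0) or null_value <= 0:
            raise ValueError("log scale requires positive values")
        r = stats.ttest_1samp(np.log(x), np.log(null_value))
        note = f"one-sample t on log values vs log({null_value:g})"
    else:
        r = stats.ttest_1samp(x, null_value)
        note = f"one-sample t vs {null_value:g}"
    return TestResult(statistic_name="one_sample_t", statistic=float(r.statistic),
                      p_value=float(r.pvalue), n=len(x), method_note=note)


def wound_closure(open_area_t0: float, open_area_t) -> np.ndarray | float:
    """Scratch-wound closure in percent: 100 * (1 - open_t / open_t0).

    Accepts a scalar or a per-timepoint series of open areas.  A wound that
    widened gives a negative closure (warned, not an error).
    """
    if open_area_t0 <= 0:
        raise ValueError("initial open area must be positive")
    areas = np.asarray(open_area_t, dtype=float)
    if np.any(areas < 0):
        raise ValueError("open areas cannot be negative")
    if np.any(areas > open_area_t0):
        warnings.warn("open area exceeds its 0 h value (wound widening); "
                      "negative closure reported", stacklevel=2)
    closure = 100.0 * (1.0 - areas / open_area_t0)
    return float(closure) if np.isscalar(open_area_t) else closure


def relative_migration(counts_condition, counts_baseline) -> float:
    """Transwell relative migration: condition mean count / baseline (vehicle)
    mean count.

    Each entry may itself be a nested sequence (duplicate inserts x fields per
    membrane); nested entries are averaged per replicate before the grand
    mean, matching the replicate structure of the assay.
    """
    def replicate_means(values):
        out = []
        for v in values:
            out.append(float(np.mean(v)) if np.ndim(v) > 0 else float(v))
        return np.asarray(out)

    cond = replicate_means(counts_condition)
    base = replicate_means(counts_baseline)
    if base.mean() <= 0:
        raise ValueError("baseline mean count must be positive")
    return float(cond.mean() / base.mean())


def ddct_fold_change(ct_target_treated, ct_ref_treated,
                     ct_target_control, ct_ref_control) -> float:
    """Delta-delta-Ct qPCR fold change: 2^-(dCt_treated - dCt_control) with
    dCt = Ct_target - Ct_reference.  Replicate Ct arrays are averaged."""
    cts = [np.mean(np.asarray(c, dtype=float)) for c in
           (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)]
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))
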