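"""Statistical evaluation machinery for displacement studies.

Covers the comparisons used when evaluating displacement parameters across
groups and methods: exact/approximate Wilcoxon signed-rank and
Mann-Whitney U tests, percentile-bootstrap confidence intervals for group
medians, intraclass correlation ICC(A,1) (two-way model, absolute
agreement, single measurement) for inter-operator reliability, Bonferroni
alpha correction, and the significance labelling used in plots.

Exact p-values are computed by full enumeration below configurable size
cutoffs (2^n sign patterns for the signed-rank test, rank subsets for the
U test); above the cutoffs the normal approximation with continuity
correction takes over.  Zero differences are dropped before ranking and
ties receive mid-ranks — the classic Wilcoxon treatment; conventions
differ between tools, so this is fixed here and tested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CIResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bootstrap_median_ci",
    "icc_a1",
    "bonferroni_alpha",
    "report_level",
    "significance_label",
]

#: Largest n for which the signed-rank test enumerates all 2^n sign patterns.
EXACT_SIGNED_RANK_CUTOFF = 15
#: Largest pooled size for which the U test enumerates all rank subsets.
EXACT_MANN_WHITNEY_CUTOFF = 12


@dataclass(frozen=True)
class CIResult:
    """A point estimate with its confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def wilcoxon_signed_rank(values_a, values_b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped before ranking; tied absolute differences
    get mid-ranks.  ``mode='exact'`` enumerates all sign assignments
    (feasible for n <= 15 after dropping zeros); ``mode='approx'`` uses the
    normal approximation with continuity correction; ``'auto'`` picks
    exact below the cutoff.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if n <= EXACT_SIGNED_RANK_CUTOFF else "approx"

    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if mode == "exact":
        # Distribution of W+ over all 2^n equally likely sign assignments.
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        w_all = signs @ ranks
        p_le = np.mean(w_all <= w_plus + 1e-12)
        p_ge = np.mean(w_all >= w_plus - 1e-12)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    mean = n * (n + 1) / 4.0
    # Variance with the mid-rank tie correction.
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var == 0:
        raise ValueError("zero variance in signed-rank statistic")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> float:
    """Two-sided Mann-Whitney U p-value for two independent groups.

    ``mode='exact'`` enumerates all C(n_a + n_b, n_a) assignments of the
    pooled mid-ranks (feasible for n_a + n_b <= 12); ``'approx'`` is the
    normal approximation with continuity and tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(a), len(b)
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if na + nb <= EXACT_MANN_WHITNEY_CUTOFF else "approx"

    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)

    if mode == "exact":
        idx = range(na + nb)
        u_all = np.array(
            [sum(ranks[list(c)]) - na * (na + 1) / 2.0 for c in itertools.combinations(idx, na)]
        )
        p_le = np.mean(u_all <= u_a + 1e-12)
        p_ge = np.mean(u_all >= u_a - 1e-12)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def bootstrap_median_ci(
    values, reps: int = 1000, level: float = 0.95, seed: int | None = None
) -> CIResult:
    """Percentile-bootstrap confidence interval for the median.

    Resamples with replacement ``reps`` times (default R = 1000) and takes
    the percentile interval of the resampled medians.  Deterministic for a
    fixed seed.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    rng = np.random.default_rng(seed)
    medians = np.median(rng.choice(v, size=(reps, v.size), replace=True), axis=1)
    alpha = 1.0 - level
    lo, hi = np.percentile(medians, [100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)])
    est = float(np.median(v))
    return CIResult(estimate=est, ci_low=float(min(lo, est)), ci_high=float(max(hi, est)), level=level)


def icc_a1(table, level: float = 0.95) -> CIResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    ``table`` is an (n_subjects, k_raters) complete matrix.  The estimate
    comes from the two-way ANOVA mean squares

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the subject, rater and error mean squares.  The
    confidence interval uses the F-based approximation conventional for
    this ICC form.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("rater matrix must be at least 2 subjects x 2 raters")
    if np.any(~np.isfinite(t)):
        raise ValueError("rater matrix must be complete (no missing values)")
    n, k = t.shape
    grand = t.mean()
    row_means = t.mean(axis=1)
    col_means = t.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((t - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("zero total variance; ICC undefined")
    r = float((msr - mse) / denom)

    if mse <= 0 and msc <= 0:
        # Columns identical: perfect absolute agreement, no sampling noise.
        return CIResult(estimate=1.0, ci_low=1.0, ci_high=1.0, level=level)

    alpha = 1.0 - level
    a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1 else np.inf
    if not np.isfinite(a):
        return CIResult(estimate=r, ci_low=r, ci_high=r, level=level)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return CIResult(
        estimate=r,
        ci_low=float(min(lower, r)),
        ci_high=float(max(upper, r)),
        level=level,
    )


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison alpha: ``alpha / m``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def report_level(value: float, decimals: int = 3) -> float:
    """Round a level or p-value to the precision used in reports."""
    return float(round(value, decimals))


def significance_label(p: float, alpha_corrected: float) -> str:
    """Plot label: 'ns' for p >= 0.05, '*' below 0.05, '**' below the
    Bonferroni-corrected alpha."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if p < alpha_corrected:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
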