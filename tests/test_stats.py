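"""Statistical machinery against enumeration oracles, scipy and pingouin."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from implmotion.stats import (
    bonferroni_alpha,
    bootstrap_median_ci,
    icc_a1,
    mann_whitney_u,
    report_level,
    significance_label,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(d: np.ndarray) -> float:
    """Loop-based enumeration oracle, independent of the vectorised path."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_ten_all_positive_differences_prints_0002(self):
        a = np.arange(10, dtype=float)
        p = wilcoxon_signed_rank(a + 1.0, a, mode="exact")
        assert p == pytest.approx(2 / 1024)
        assert report_level(p) == 0.002

    def test_six_all_positive(self):
        a = np.arange(6, dtype=float)
        assert wilcoxon_signed_rank(a + 1.0, a, mode="exact") == pytest.approx(2 / 64)

    def test_balanced_mirror_gives_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])  # differences -1, +1, -1, +1
        assert wilcoxon_signed_rank(a, b, mode="exact") == 1.0

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))

    def test_exact_matches_scipy_no_ties(self, rng):
        for _ in range(10):
            a = rng.normal(size=7)
            b = rng.normal(size=7)
            ours = wilcoxon_signed_rank(a, b, mode="exact")
            ref = sps.wilcoxon(a, b, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_matches_loop_oracle_with_ties(self, rng):
        for _ in range(5):
            d = rng.integers(-3, 4, size=8).astype(float)
            if np.all(d == 0):
                continue
            a = np.cumsum(np.abs(d)) + 10.0
            b = a - d
            assert wilcoxon_signed_rank(a, b, mode="exact") == pytest.approx(
                brute_force_signed_rank_p(d), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        p1 = wilcoxon_signed_rank(a, b, mode="exact")
        # Any common strictly monotone transform preserves signs and
        # |difference| ordering here because we use a shared shift.
        p2 = wilcoxon_signed_rank(a + 100.0, b + 100.0, mode="exact")
        assert p1 == pytest.approx(p2)

    def test_approx_close_to_scipy_large_n(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(loc=0.4, size=40)
        ours = wilcoxon_signed_rank(a, b, mode="approx")
        ref = sps.wilcoxon(a, b, mode="approx", correction=True).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestMannWhitneyU:
    def test_fully_separated_small_groups(self):
        p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        assert mann_whitney_u([5.0, 5.0], [5.0, 5.0], mode="exact") == 1.0

    def test_single_observation_each(self):
        assert mann_whitney_u([1.0], [2.0], mode="exact") == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            ours = mann_whitney_u(a, b, mode="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        assert mann_whitney_u(a, b, mode="exact") == pytest.approx(
            mann_whitney_u(np.exp(a), np.exp(b), mode="exact")
        )


class TestBootstrapMedianCI:
    def test_constant_values_degenerate_ci(self):
        ci = bootstrap_median_ci(np.full(20, 3.5), seed=0)
        assert ci.estimate == ci.ci_low == ci.ci_high == 3.5

    def test_seeded_determinism(self, rng):
        v = rng.normal(size=30)
        a = bootstrap_median_ci(v, seed=42)
        b = bootstrap_median_ci(v, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        widths = {}
        for n in (20, 200):
            ws = []
            for rep in range(30):
                v = rng.normal(size=n)
                ci = bootstrap_median_ci(v, seed=rep)
                ws.append(ci.ci_high - ci.ci_low)
            widths[n] = np.median(ws)
        assert widths[200] < widths[20]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci([])


class TestICC:
    def test_identical_raters_perfect_agreement(self):
        t = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
        ci = icc_a1(t)
        assert ci.estimate == 1.0

    def test_bias_reduces_absolute_agreement(self, rng):
        subjects = rng.normal(scale=5.0, size=10)
        previous = 1.1
        for bias in (1.0, 3.0, 9.0):
            t = np.column_stack([subjects, subjects + bias])
            est = icc_a1(t).estimate
            assert est < previous
            previous = est

    def test_matches_mean_squares_oracle(self, rng):
        t = rng.normal(size=(6, 3))

        # Independent loop-based two-way ANOVA oracle.
        n, k = t.shape
        gm = t.mean()
        msr = k * sum((t[i].mean() - gm) ** 2 for i in range(n)) / (n - 1)
        msc = n * sum((t[:, j].mean() - gm) ** 2 for j in range(k)) / (k - 1)
        sse = sum(
            (t[i, j] - t[i].mean() - t[:, j].mean() + gm) ** 2
            for i in range(n)
            for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        assert icc_a1(t).estimate == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        t = rng.normal(size=(8, 4)) + np.arange(8)[:, None]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 4),
                "rater": np.tile(np.arange(4), 8),
                "score": t.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        ours = icc_a1(t)
        assert ours.estimate == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin reports the CI rounded to two decimals.
        assert ours.ci_low == pytest.approx(row[ci_col][0], abs=6e-3)
        assert ours.ci_high == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_shift_invariance(self, rng):
        t = rng.normal(size=(7, 3))
        assert icc_a1(t + 100.0).estimate == pytest.approx(icc_a1(t).estimate, abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            icc_a1(np.full((4, 3), 2.0))
        with pytest.raises(ValueError):
            icc_a1(np.zeros((1, 3)))


class TestBonferroniAndLabels:
    def test_printed_thresholds(self):
        assert report_level(bonferroni_alpha(0.05, 6)) == 0.008
        assert report_level(bonferroni_alpha(0.05, 24)) == 0.002
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 2)

    @pytest.mark.parametrize(
        "p,alpha,label",
        [
            (0.5, 0.008, "ns"),
            (0.05, 0.008, "ns"),
            (0.01, 0.008, "*"),
            (0.002, 0.008, "**"),
            (0.0079, 0.008, "**"),
        ],
    )
    def test_labelling_rule(self, p, alpha, label):
        assert significance_label(p, alpha) == label

    def test_p_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_label(1.2, 0.008)
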