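"""Statistical battery: exact enumerations, hand-computed ANOVAs, FDR, ROUT."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from dualfiber.stats import (
    bky_fdr,
    chi_square_counts,
    mann_whitney,
    paired_comparison,
    rm_anova_epochs,
    rout_outliers,
    two_way_anova,
    unpaired_comparison,
    variance_f_test,
    wilcoxon_signed_rank_vs_zero,
)


def wilcoxon_enumeration_p(values):
    """Brute-force two-sided p over all 2^n sign assignments (midranks)."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    ranks = sstats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = signs @ ranks
    lo = np.mean(w_all <= w_obs + 1e-9)
    hi = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def mann_whitney_enumeration_p(x, y):
    """Exact two-sided p by enumerating all group assignments (no ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = sstats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(pooled.size), n1):
        r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.array(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_all_positive_n6(self):
        """Six positive values: exact two-sided p = 2/64 = 0.03125."""
        res = wilcoxon_signed_rank_vs_zero([0.2, 0.5, 1.1, 0.7, 0.3, 0.9])
        assert res.p_value == pytest.approx(0.03125, abs=1e-12)

    def test_antisymmetric_pairs_p1(self):
        res = wilcoxon_signed_rank_vs_zero([-1.0, 1.0, -2.0, 2.0, -3.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_n15(self, rng):
        for _ in range(5):
            v = rng.standard_normal(15)
            res = wilcoxon_signed_rank_vs_zero(v)
            assert res.p_value == pytest.approx(wilcoxon_enumeration_p(v),
                                                abs=1e-12)

    def test_ties_handled_exactly(self, rng):
        v = np.array([0.5, -0.5, 1.0, 1.0, -1.0, 2.0, 0.25, -0.25, 3.0])
        res = wilcoxon_signed_rank_vs_zero(v)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(v), abs=1e-12)

    def test_zeros_removed_and_all_zero_rejected(self):
        r1 = wilcoxon_signed_rank_vs_zero([0.0, 1.0, 2.0, 0.0, 3.0, 1.5, 0.5, 2.5])
        r2 = wilcoxon_signed_rank_vs_zero([1.0, 2.0, 3.0, 1.5, 0.5, 2.5])
        assert r1.p_value == pytest.approx(r2.p_value)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_vs_zero([0.0, 0.0])

    def test_large_n_normal_approx_close_to_exact_enum(self, rng):
        v = rng.standard_normal(30) + 0.3
        res = wilcoxon_signed_rank_vs_zero(v)
        ref = sstats.wilcoxon(v, alternative="two-sided", correction=False,
                              method="approx")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)


class TestMannWhitney:
    def test_identical_groups_p1(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        res = mann_whitney(x, list(x))
        assert res.p_value > 0.95

    def test_complete_separation_4v4(self):
        """Disjoint n=m=4 groups: exact p = 2/70 = 0.02857."""
        res = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.p_value == pytest.approx(0.028571428, abs=1e-6)
        assert res.extra["method"] == "exact"

    def test_matches_enumeration_6v6(self, rng):
        for _ in range(5):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6) + 0.5
            res = mann_whitney(x, y)
            assert res.p_value == pytest.approx(
                mann_whitney_enumeration_p(x, y), abs=1e-9
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestVarianceF:
    def test_equal_variances_f1(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = variance_f_test(x, [10.0, 11.0, 12.0, 13.0])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_constructed_f4_df(self, rng):
        """SD ratio 2 with n=20 vs n=19 gives F=4, Dfn=19, Dfd=18."""
        base = rng.standard_normal(20)
        base = (base - base.mean()) / base.std(ddof=1)
        x = 2.0 * base                      # sample variance exactly 4
        y = rng.standard_normal(19)
        y = (y - y.mean()) / y.std(ddof=1)  # sample variance exactly 1
        res = variance_f_test(x, y)
        assert res.statistic == pytest.approx(4.0, abs=1e-9)
        assert res.extra["dfn"] == 19
        assert res.extra["dfd"] == 18

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRMAnova:
    def test_identical_epochs(self):
        m = np.tile([1.0, 2.0, 1.5, 1.0], (3, 1)).T
        res = rm_anova_epochs(m)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_shifted_loom_epoch_highly_significant(self, rng):
        base = rng.standard_normal((15, 3)) * 0.1
        base[:, 1] += 1.0
        res = rm_anova_epochs(base)
        assert res.p_value < 1e-6
        posthoc = {c["contrast"]: c for c in res.extra["posthoc"]}
        assert posthoc["baseline_vs_loom"]["significant"]

    def test_hand_computed_toy(self):
        """5 trials x 3 epochs; F frozen from a by-hand SS decomposition
        (SS_treat=19.6, SS_subj=16.2667, SS_err=1.7333 -> F=45.230769)."""
        m = np.array([[1, 2, 3], [2, 3, 5], [0, 1, 2], [1, 3, 4], [2, 4, 6]],
                     dtype=float)
        res = rm_anova_epochs(m)
        assert res.extra["ss"]["treatment"] == pytest.approx(19.6, abs=1e-9)
        assert res.extra["ss"]["subject"] == pytest.approx(16.266667, abs=1e-5)
        assert res.extra["ss"]["error"] == pytest.approx(1.733333, abs=1e-5)
        assert res.statistic == pytest.approx(45.230769, abs=1e-5)
        assert res.extra["df"] == (2, 8)

    def test_matches_pingouin(self, rng):
        """Cross-check F and p against pingouin's RM ANOVA."""
        import pandas as pd
        import pingouin as pg

        m = rng.standard_normal((12, 3)) + np.array([0.0, 0.4, 0.1])
        res = rm_anova_epochs(m)
        long = pd.DataFrame(
            {
                "y": m.ravel(),
                "epoch": np.tile(["b", "l", "p"], m.shape[0]),
                "subj": np.repeat(np.arange(m.shape[0]), 3),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="epoch", subject="subj")
        assert res.statistic == pytest.approx(float(ref.loc[0, "F"]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref.loc[0, "p_unc"]), rel=1e-9)

    def test_incomplete_trials_dropped(self):
        m = np.array([[1, 2, 3], [np.nan, 2, 3], [2, 3, 4], [1, 1, 1]])
        res = rm_anova_epochs(m)
        assert res.extra["n_dropped_incomplete"] == 1
        assert res.n == (3, 3)


class TestBKY:
    def test_single_small_p_rejected(self):
        q, rej, m0 = bky_fdr([0.01], alpha=0.05)
        assert rej[0]

    def test_all_ones_none_rejected(self):
        q, rej, m0 = bky_fdr([1.0] * 6)
        assert not rej.any()
        assert m0 == 6

    def test_vector_matches_statsmodels_reference(self):
        """The rejection set matches an independently coded two-stage
        procedure (statsmodels fdr_tsbky) on the 10-value example vector."""
        from statsmodels.stats.multitest import multipletests

        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        q, rej, m0 = bky_fdr(p, alpha=0.05)
        ref_rej, ref_q, _, _ = multipletests(p, alpha=0.05, method="fdr_tsbky")
        np.testing.assert_array_equal(rej, ref_rej)

    def test_random_vectors_match_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(3, 25))
            p[: p.size // 3] *= 0.05
            q, rej, _ = bky_fdr(p, alpha=0.05)
            ref_rej, *_ = multipletests(p, alpha=0.05, method="fdr_tsbky")
            np.testing.assert_array_equal(rej, ref_rej)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15),
           st.integers(0, 14))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, pvals, idx):
        """Lowering any p-value never shrinks the rejection set."""
        p = np.array(pvals)
        _, rej_before, _ = bky_fdr(p)
        p2 = p.copy()
        p2[idx % p.size] /= 2.0
        _, rej_after, _ = bky_fdr(p2)
        assert rej_after.sum() >= rej_before.sum()

    def test_q_threshold_consistent_with_rejection(self, rng):
        p = rng.uniform(0, 1, 12)
        p[:4] *= 0.02
        q, rej, _ = bky_fdr(p, alpha=0.05)
        if 0 < rej.sum() < p.size:
            np.testing.assert_array_equal(rej, q <= 0.05)


class TestRout:
    def test_gross_outlier_removed(self):
        kept, removed = rout_outliers([1.0, 1.1, 0.9, 50.0], q=0.01)
        assert list(removed) == [50.0]
        assert sorted(kept) == [0.9, 1.0, 1.1]

    def test_three_identical_noop(self):
        kept, removed = rout_outliers([2.0, 2.0, 2.0], q=0.01)
        assert removed.size == 0

    def test_small_n_noop(self):
        kept, removed = rout_outliers([1.0, 99.0], q=0.01)
        assert removed.size == 0

    def test_false_removal_rate_bounded(self, rng):
        """~1,000 clean normal datasets: per-dataset removal rate stays near Q
        (the 10,000-rep calibration lives in the acceptance suite)."""
        hits = 0
        for _ in range(1000):
            _, removed = rout_outliers(rng.standard_normal(20), q=0.01)
            hits += removed.size > 0
        assert hits / 1000 <= 0.03


class TestTwoWayAnova:
    def test_identical_values(self):
        y = np.ones(16)
        fa = np.repeat(["m", "f"], 8)
        fb = np.tile(np.repeat(["fam", "unf"], 4), 2)
        res = two_way_anova(y, fa, fb)
        for r in res.values():
            assert r.statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_balanced_toy(self):
        """2x2 cells [1,2],[3,4],[5,6],[11,12]: SS 72/32/8, F 144/64/16."""
        y = np.array([1, 2, 3, 4, 5, 6, 11, 12], dtype=float)
        fa = np.array(["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"])
        fb = np.array(["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"])
        res = two_way_anova(y, fa, fb, names=("A", "B"))
        assert res["A"].extra["ss"] == pytest.approx(72.0, abs=1e-9)
        assert res["B"].extra["ss"] == pytest.approx(32.0, abs=1e-9)
        assert res["interaction"].extra["ss"] == pytest.approx(8.0, abs=1e-9)
        assert res["A"].statistic == pytest.approx(144.0, abs=1e-9)
        assert res["B"].statistic == pytest.approx(64.0, abs=1e-9)
        assert res["interaction"].statistic == pytest.approx(16.0, abs=1e-9)

    def test_unbalanced_matches_statsmodels_type2(self, rng):
        """Type-II SS on unbalanced cells agrees with statsmodels anova_lm."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        sizes = {("m", "fam"): 4, ("m", "unf"): 7, ("f", "fam"): 5, ("f", "unf"): 3}
        rows = []
        for (a, b), n in sizes.items():
            for _ in range(n):
                rows.append(
                    {"y": rng.standard_normal() + (a == "m") * 0.5
                     + (b == "fam") * 0.2, "sex": a, "fam": b}
                )
        df = pd.DataFrame(rows)
        res = two_way_anova(df["y"].to_numpy(), df["sex"].to_numpy(),
                            df["fam"].to_numpy(), names=("sex", "fam"))
        model = ols("y ~ C(sex) * C(fam)", data=df).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        assert res["sex"].extra["ss"] == pytest.approx(
            float(ref.loc["C(sex)", "sum_sq"]), rel=1e-8
        )
        assert res["fam"].extra["ss"] == pytest.approx(
            float(ref.loc["C(fam)", "sum_sq"]), rel=1e-8
        )
        assert res["interaction"].p_value == pytest.approx(
            float(ref.loc["C(sex):C(fam)", "PR(>F)"]), rel=1e-8
        )

    def test_additive_effect_interaction_null(self, rng):
        n = 60
        fa = np.repeat(["m", "f"], 2 * n)
        fb = np.tile(np.repeat(["fam", "unf"], n), 2)
        y = (fa == "m") * 1.0 + rng.standard_normal(4 * n)
        res = two_way_anova(y, fa, fb)
        assert res["sex"].p_value < 1e-6
        assert res["interaction"].p_value > 0.01

    def test_empty_cell_rejected(self):
        y = np.arange(6, dtype=float)
        fa = np.array(["m", "m", "m", "m", "f", "f"])
        fb = np.array(["x", "x", "y", "y", "x", "x"])
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(y, fa, fb)


class TestChiSquare:
    def test_identical_rows(self):
        res = chi_square_counts([[10, 5, 5], [10, 5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_published_table_p_in_interval(self):
        """The sex x response table [[29,9,10],[19,11,6]] gives p ~ 0.45."""
        res = chi_square_counts([[29, 9, 10], [19, 11, 6]])
        assert 0.4 < res.p_value < 0.5
        assert res.extra["df"] == 2

    def test_2x2_closed_form(self):
        """Pearson chi-square on a 2x2 equals n(ad-bc)^2 / (row/col products)."""
        a, b, c, d = 12, 5, 7, 9
        res = chi_square_counts([[a, b], [c, d]])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_counts([[0, 5], [0, 7]])


class TestNormalityGate:
    def test_gate_switches_tests(self, rng):
        normal = rng.standard_normal(20)
        skewed = rng.exponential(1.0, 20) ** 3
        res_t = unpaired_comparison(normal, normal + 0.1)
        assert res_t.test_name == "unpaired_t"
        res_mw = unpaired_comparison(skewed, skewed * 1.1)
        assert res_mw.test_name == "mann_whitney"

    def test_paired_gate(self, rng):
        x = rng.standard_normal(15)
        res = paired_comparison(x, x + rng.standard_normal(15) * 0.2)
        assert res.test_name in ("paired_t", "wilcoxon_signed_rank")
        assert "auto_selected" in res.extra
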