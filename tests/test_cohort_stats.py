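"""Statistics tests: frozen oracle values, Monte-Carlo calibration, and
property-based equivalences (summary vs raw ANOVA, Mann-Whitney vs
trapezoidal AUC, orientation symmetry)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cortiqct import reference_tables as ref
from cortiqct.cohort_stats import (GroupSummary, anova_from_summary,
                                   anova_oneway, binormal_auc,
                                   delong_auc_variance, delong_test,
                                   levene_test, roc_points, roc_youden)


def trapezoid_auc(scores, labels, orientation="lower"):
    """Independent oracle: trapezoidal integration of the empirical ROC
    built by exhaustive threshold enumeration."""
    thr, sens, spec = roc_points(scores, labels, orientation)
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    fpr = np.concatenate([[0.0], fpr[order], [1.0]])
    tpr = np.concatenate([[0.0], sens[order], [1.0]])
    return float(np.trapezoid(tpr, fpr))


class TestLevene:
    def test_shifted_groups_statistic_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = levene_test([g, g + 10.0])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_constant_groups_convention(self):
        assert levene_test([[1.0, 1.0], [2.0, 2.0]]) == (0.0, 1.0)

    def test_matches_scipy_on_random_data(self, rng):
        groups = [rng.normal(0, s, 40) for s in (1.0, 2.0, 3.0)]
        stat, p = levene_test(groups)
        ref_stat, ref_p = sps.levene(*groups, center="mean")
        assert stat == pytest.approx(float(ref_stat))
        assert p == pytest.approx(float(ref_p))

    def test_power_against_ninefold_variance(self):
        # Monte-Carlo power oracle: N(0,1) vs N(0,9), n=200 -> p < 0.01
        # almost surely; >= 95% over seeded replicates
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            _, p = levene_test([r.normal(0, 1, 200), r.normal(0, 3, 200)])
            hits += p < 0.01
        assert hits >= 0.95 * n_rep

    def test_null_p_uniform(self):
        # homoscedastic data -> p approximately U[0,1] (KS check)
        ps = []
        for seed in range(300):
            r = np.random.default_rng(10_000 + seed)
            _, p = levene_test([r.normal(0, 1, 50), r.normal(2, 1, 50)])
            ps.append(p)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_input_validation(self):
        with pytest.raises(ValueError):
            levene_test([[1.0, 2.0]])
        with pytest.raises(ValueError):
            levene_test([[1.0], [2.0, 3.0]])


class TestAnova:
    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0]
        res = anova_oneway([g, g, g])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1.0, 30) for m in (0.0, 0.5, 1.0)]
        res = anova_oneway(groups)
        ref_res = sps.f_oneway(*groups)
        assert res.f_stat == pytest.approx(float(ref_res.statistic), rel=1e-12)
        assert res.p_value == pytest.approx(float(ref_res.pvalue), rel=1e-9)

    def test_lsd_only_when_significant(self, rng):
        sig = anova_oneway([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        assert sig.p_value < 0.05 and sig.lsd_pairs
        null = anova_oneway([[1.0, 2.0, 3.0], [1.1, 2.1, 2.9]])
        assert null.p_value > 0.05 and not null.lsd_pairs

    def test_lsd_matches_pooled_t(self, rng):
        groups = [rng.normal(m, 1.0, 25) for m in (0.0, 1.0, 2.0)]
        res = anova_oneway(groups, labels=["a", "b", "c"])
        k, n = 3, 75
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
        for a, b, diff, p in res.lsd_pairs:
            i, j = "abc".index(a), "abc".index(b)
            t = (groups[i].mean() - groups[j].mean()) / math.sqrt(msw * 2 / 25)
            assert p == pytest.approx(2 * sps.t.sf(abs(t), n - k), rel=1e-10)

    def test_zero_within_variance_flagged(self):
        res = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert math.isinf(res.f_stat) or res.f_stat == 0
        assert "degenerate_zero_within_variance" in res.flags

    def test_df_invariants(self, rng):
        groups = [rng.normal(0, 1, n) for n in (10, 20, 30)]
        res = anova_oneway(groups)
        assert res.df_between == 2
        assert res.df_within == 57


class TestAnovaFromSummary:
    # frozen oracle values recomputed from the bundled summary tables
    REPLAY = [
        (ref.BMD_GROUPS_ALL, "average_thickness", 16.282),
        (ref.BMD_GROUPS_ALL, "average_area", 16.508),
        (ref.BMD_GROUPS_ALL, "total_volume", 17.482),
        (ref.AGE_GROUPS_ALL, "average_thickness", 9.141),
        (ref.AGE_GROUPS_FEMALE, "average_thickness", 8.953),
        (ref.AGE_GROUPS_FEMALE, "total_volume", 5.299),
    ]

    @pytest.mark.parametrize("table,param,expected", REPLAY)
    def test_frozen_replay_values(self, table, param, expected):
        rows = [GroupSummary(*r) for r in ref.group_summaries(table, param)]
        res = anova_from_summary(rows)
        assert res.f_stat == pytest.approx(expected, abs=5e-3)
        # and within 2% of the published statistic (rounded summaries)
        assert res.f_stat == pytest.approx(table["f"][param], rel=0.02)

    def test_identical_summaries_f_zero(self):
        s = GroupSummary("a", 10, 5.0, 1.0)
        res = anova_from_summary([s, GroupSummary("b", 10, 5.0, 1.0)])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_sd_differing_means_flagged(self):
        res = anova_from_summary([GroupSummary("a", 5, 1.0, 0.0),
                                  GroupSummary("b", 5, 2.0, 0.0)])
        assert math.isinf(res.f_stat)
        assert "degenerate_zero_within_variance" in res.flags

    def test_equivalence_with_raw_form(self, rng):
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.normal(), rng.uniform(0.5, 3.0),
                                 rng.integers(3, 40)) for _ in range(k)]
            raw = anova_oneway(groups)
            summ = anova_from_summary([
                GroupSummary(f"g{i}", g.size, float(g.mean()),
                             float(g.std(ddof=1)))
                for i, g in enumerate(groups)])
            assert summ.f_stat == pytest.approx(raw.f_stat, rel=1e-10)

    @given(st.lists(st.lists(st.floats(-50, 50), min_size=3, max_size=20),
                    min_size=2, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_equivalence_property(self, raw_groups):
        groups = [np.asarray(g) for g in raw_groups]
        if any(g.std(ddof=1) == 0 for g in groups):
            return
        raw = anova_oneway(groups)
        summ = anova_from_summary([
            GroupSummary(f"g{i}", g.size, float(g.mean()), float(g.std(ddof=1)))
            for i, g in enumerate(groups)])
        if math.isfinite(raw.f_stat):
            assert summ.f_stat == pytest.approx(raw.f_stat, rel=1e-8, abs=1e-10)


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([1.0, 2.0, 3.0, 4.0], [True, True, False, False])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0
        assert res.specificity == 100.0

    def test_null_auc_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        res = roc_youden(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_toy_cutoff_between_classes(self):
        # diseased {1,2}, healthy {3,4}, lower-is-disease: AUC 1, the
        # Youden-optimal observed cutoff is 2 (call disease when <= 2)
        res = roc_youden([1.0, 2.0, 3.0, 4.0], [True, True, False, False])
        assert 2.0 <= res.cutoff < 3.0

    def test_exhaustive_threshold_enumeration_oracle(self, rng):
        # brute force over all thresholds reproduces the reported operating point
        scores = rng.normal(0, 1, 60) + np.where(rng.random(60) < 0.5, 0.0, 1.5)
        labels = scores < np.median(scores)  # arbitrary correlated labels
        res = roc_youden(scores, labels, orientation="lower")
        best = (-1.0, None)
        for c in np.unique(scores):
            sens = (scores[labels] <= c).mean()
            spec = (scores[~labels] > c).mean()
            if sens + spec - 1.0 > best[0] + 1e-12:
                best = (sens + spec - 1.0, c)
        assert res.youden == pytest.approx(best[0])

    def test_mann_whitney_equals_trapezoid(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=80), 1)  # induce ties
            labels = rng.random(80) < 0.4
            if labels.all() or not labels.any():
                continue
            res = roc_youden(scores, labels)
            assert res.auc == pytest.approx(
                trapezoid_auc(scores, labels), abs=1e-12)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_orientation_reversal_property(self, data):
        n = data.draw(st.integers(6, 30))
        scores = np.array(data.draw(st.lists(
            st.floats(-10, 10), min_size=n, max_size=n)))
        labels = np.array(data.draw(st.lists(st.booleans(),
                                             min_size=n, max_size=n)))
        if labels.all() or not labels.any():
            return
        lo = roc_youden(scores, labels, "lower")
        hi = roc_youden(scores, labels, "higher")
        assert lo.auc == pytest.approx(1.0 - hi.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1.0, 2.0], [True, True])

    def test_ci_brackets_auc(self, rng):
        scores = rng.normal(size=100) + rng.integers(0, 2, 100)
        labels = rng.random(100) < 0.5
        res = roc_youden(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high


class TestDeLong:
    def test_self_comparison(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        res = delong_test(scores, scores, labels)
        assert res.z_stat == 0.0
        assert res.p_value == 1.0
        assert "degenerate_variance" in res.flags

    def test_variance_nonnegative(self, rng):
        for _ in range(20):
            a = rng.normal(size=40)
            b = a + rng.normal(0, 0.5, 40)
            labels = rng.random(40) < 0.5
            if labels.all() or not labels.any():
                continue
            res = delong_test(a, b, labels)
            assert res.var_diff >= 0.0

    def test_z_sign_consistent_with_auc_ordering(self, rng):
        labels = np.repeat([True, False], 50)
        a = np.where(labels, -2.0, 2.0) + rng.normal(0, 0.5, 100)  # strong
        b = rng.normal(0, 1, 100)                                  # useless
        res = delong_test(a, b, labels, orientation="lower")
        assert res.auc_a > res.auc_b
        assert res.z_stat > 0

    def test_type_i_error_calibration(self):
        # two independent, equally informative markers; nominal 5% level
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            labels = np.repeat([True, False], 100)
            a = np.where(labels, 1.0, 0.0) + r.normal(0, 1, 200)
            b = np.where(labels, 1.0, 0.0) + r.normal(0, 1, 200)
            res = delong_test(a, b, labels, orientation="higher")
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_single_auc_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(1.0, 1.0, 40),
                                 rng.normal(0.0, 1.0, 60)])
        labels = np.repeat([True, False], [40, 60])
        analytic = delong_auc_variance(scores, labels, orientation="higher")
        aucs = []
        for _ in range(2000):
            i_d = rng.integers(0, 40, 40)
            i_n = 40 + rng.integers(0, 60, 60)
            s = np.concatenate([scores[i_d], scores[i_n]])
            res = roc_youden(s, labels, orientation="higher")
            aucs.append(res.auc)
        assert analytic == pytest.approx(np.var(aucs), rel=0.15)

    def test_unpaired_markers_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1.0, 2.0], [1.0, 2.0, 3.0], [True, False])


class TestBinormalAuc:
    def test_equal_distributions_half(self):
        s = GroupSummary("d", 10, 1.0, 1.0)
        assert binormal_auc(s, [GroupSummary("n", 10, 1.0, 1.0)]) == pytest.approx(0.5)

    def test_closed_form_phi_one(self):
        # mean gap = sqrt(s1^2 + s2^2) -> AUC = Phi(1)
        d = GroupSummary("d", 10, 0.0, 1.0)
        n = GroupSummary("n", 10, math.sqrt(2.0), 1.0)
        assert binormal_auc(d, [n]) == pytest.approx(sps.norm.cdf(1.0), abs=1e-12)

    def test_reference_thickness_mixture(self):
        rows = [GroupSummary(*r) for r in
                ref.group_summaries(ref.BMD_GROUPS_ALL, "average_thickness")]
        auc = binormal_auc(rows[2], rows[:2])
        assert auc == pytest.approx(0.749, abs=0.002)
        assert auc == pytest.approx(ref.ROC_ALL["average_thickness"]["auc"], abs=0.02)

    def test_monte_carlo_agreement(self):
        # simulation oracle for the closed form
        rng = np.random.default_rng(5)
        d = GroupSummary("d", 52, 1.19, 0.63)
        mix = [GroupSummary("a", 59, 1.85, 0.70), GroupSummary("b", 58, 1.75, 0.61)]
        closed = binormal_auc(d, mix)
        dis = rng.normal(d.mean, d.sd, 100_000)
        non = np.concatenate([rng.normal(c.mean, c.sd, 50_000 * c.n // 59)
                              for c in mix])
        mc = (non[None, :5_000] > dis[:5_000, None]).mean()
        assert closed == pytest.approx(mc, abs=0.01)

    def test_degenerate_step_function(self):
        d = GroupSummary("d", 5, 1.0, 0.0)
        assert binormal_auc(d, [GroupSummary("n", 5, 2.0, 0.0)]) == 1.0
        assert binormal_auc(d, [GroupSummary("n", 5, 0.0, 0.0)]) == 0.0
        assert binormal_auc(d, [GroupSummary("n", 5, 1.0, 0.0)]) == 0.5


class TestGroupSummaryValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            GroupSummary("x", 0, 1.0, 1.0)
        with pytest.raises(ValueError):
            GroupSummary("x", 5, 1.0, -0.1)
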