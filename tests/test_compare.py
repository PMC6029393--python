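import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar

from methpanel import (
    compare_paired_tests,
    concordance,
    confusion_counts,
    exact_binomial_p,
    fisher_z_ci,
    group_summaries,
    paired_marker_difference,
    pearson_with_ci,
    wilcoxon_rank_sum,
)


class TestPairedMarkerDifference:
    def test_identical_vectors(self):
        d = paired_marker_difference([1, 2, 3], [1, 2, 3])
        assert d.mean_difference == 0.0
        assert d.p_value == 1.0
        assert d.degenerate

    def test_known_t_statistic(self):
        # differences {1, 2, 3}: t = 2*sqrt(3) on 2 df, two-sided p ~ 0.0742
        d = paired_marker_difference([2, 4, 6], [1, 2, 3])
        assert d.mean_difference == pytest.approx(2.0)
        assert d.p_value == pytest.approx(0.07417990022744855, rel=1e-9)
        assert d.ci_low <= d.mean_difference <= d.ci_high

    def test_constant_shift(self):
        rng = np.random.default_rng(0)
        fv = rng.uniform(0, 10, 20)
        d = paired_marker_difference(fv + 1.5, fv)
        assert d.mean_difference == pytest.approx(1.5)
        assert d.degenerate  # zero variance of the differences
        assert d.p_value == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_marker_difference([1.0], [2.0])

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(5, 2, 30), rng.normal(4.5, 2, 30)
        d = paired_marker_difference(a, b)
        res = stats.ttest_rel(a, b)
        assert d.p_value == pytest.approx(res.pvalue)


class TestExactBinomial:
    @pytest.mark.parametrize(
        "b,c,expected",
        [
            (0, 0, 1.0),
            (2, 2, 1.0),
            (0, 3, 0.25),  # 2 * (1/2)^3
            (1, 0, 1.0),  # 2 * (1/2)^1, capped
        ],
    )
    def test_examples(self, b, c, expected):
        assert exact_binomial_p(b, c) == pytest.approx(expected)

    @given(st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=150)
    def test_symmetry_and_balance(self, b, c):
        p = exact_binomial_p(b, c)
        assert p == exact_binomial_p(c, b)
        assert 0 < p <= 1
        if b == c:
            assert p == 1.0

    @given(st.integers(0, 10), st.integers(0, 10))
    @settings(max_examples=100)
    def test_matches_statsmodels_exact_mcnemar(self, b, c):
        if b + c == 0:
            return
        table = [[0, b], [c, 0]]
        assert exact_binomial_p(b, c) == pytest.approx(
            float(mcnemar(table, exact=True).pvalue)
        )


def _calls(values, ids=None):
    ids = ids or [f"p{i}" for i in range(len(values))]
    return pd.Series(values, index=ids, dtype=bool)


class TestComparePairedTests:
    def test_identical_tests(self):
        calls = _calls([1, 1, 0, 0, 1, 0])
        labels = _calls([1, 1, 1, 0, 0, 0])
        res = compare_paired_tests(calls, calls.copy(), labels)
        assert res.diff_sensitivity == 0.0
        assert res.diff_specificity == 0.0
        assert res.p_sensitivity == 1.0 and res.p_specificity == 1.0
        assert res.concordance == 1.0

    def test_one_discordant_case_of_28(self):
        """One extra detection among 28 cases: difference 1/28, p = 1."""
        labels = _calls([1] * 28 + [0] * 32)
        a = _calls([1] * 27 + [0] + [0] * 32)  # 27/28
        b = _calls([1] * 26 + [0, 0] + [0] * 32)  # 26/28
        res = compare_paired_tests(a, b, labels)
        assert res.diff_sensitivity == pytest.approx(1 / 28)
        assert res.p_sensitivity == 1.0
        assert res.diff_specificity == 0.0

    def test_three_discordants_one_way(self):
        labels = _calls([1] * 8 + [0] * 4)
        a = _calls([1] * 8 + [0] * 4)
        b = _calls([1] * 5 + [0] * 3 + [0] * 4)
        res = compare_paired_tests(a, b, labels)
        assert res.p_sensitivity == pytest.approx(0.25)
        assert res.diff_sensitivity == pytest.approx(3 / 8)
        lo, hi = res.sens_ci
        assert lo <= res.diff_sensitivity <= hi

    def test_cross_module_consistency_with_diagnostics(self, profiles, labels):
        """diff_sensitivity equals the difference of sensitivities computed
        independently via confusion counts on the paired subset."""
        by_type = {
            st_: grp.droplevel("sample_type") for st_, grp in profiles.groupby(level="sample_type")
        }
        paired = sorted(set(by_type["DRE"].index) & set(by_type["FV"].index))
        a = by_type["FV"]["test_positive"].loc[paired]
        b = by_type["DRE"]["test_positive"].loc[paired]
        y = labels.loc[paired]
        res = compare_paired_tests(a, b, y)
        ca, cb = confusion_counts(a, y), confusion_counts(b, y)
        assert res.diff_sensitivity == pytest.approx(
            ca.tp / ca.n_cases - cb.tp / cb.n_cases
        )
        assert res.diff_specificity == pytest.approx(
            ca.tn / ca.n_controls - cb.tn / cb.n_controls
        )

    def test_patient_mismatch_rejected(self):
        a = _calls([1, 0], ["x", "y"])
        b = _calls([1, 0], ["x", "z"])
        labels = _calls([1, 0], ["x", "y"])
        with pytest.raises(ValueError, match="symmetric"):
            compare_paired_tests(a, b, labels)


class TestConcordance:
    def test_identical_and_complementary(self):
        a = _calls([1, 0, 1, 0])
        assert concordance(a, a.copy())["pairwise"] == 1.0
        assert concordance(a, ~a)["pairwise"] == 0.0

    def test_49_of_60(self):
        a = _calls([True] * 60)
        b = _calls([True] * 49 + [False] * 11)
        assert concordance(a, b)["pairwise"] == pytest.approx(49 / 60)

    def test_three_way(self):
        a = _calls([1, 1, 0, 0])
        b = _calls([1, 0, 0, 0])
        y = _calls([1, 1, 0, 1])
        out = concordance(a, b, y)
        assert out["pairwise"] == pytest.approx(3 / 4)
        assert out["three_way"] == pytest.approx(2 / 4)


def _exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided p of the Mann-Whitney U over all
    case/control assignments of the pooled sample (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        y = rng.normal(2, 1, 60)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_exact_branch_matches_enumeration(self, data):
        n1 = data.draw(st.integers(2, 5))
        n2 = data.draw(st.integers(2, 5))
        values = data.draw(
            st.lists(
                st.integers(0, 1000), min_size=n1 + n2, max_size=n1 + n2, unique=True
            )
        )
        x = np.array(values[:n1], float)
        y = np.array(values[n1:], float)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_exact_rank_sum_p(x, y))


class TestPearson:
    def test_fisher_z_closed_form(self):
        lo, hi = fisher_z_ci(0.649, 35)
        assert lo == pytest.approx(0.4028891054991325, abs=1e-12)
        assert hi == pytest.approx(0.8075845704294736, abs=1e-12)

    def test_pearson_matches_fisher_ci(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        r, lo, hi, p = pearson_with_ci(x, y)
        lo2, hi2 = fisher_z_ci(r, 40)
        assert (lo, hi) == (lo2, hi2)
        assert lo < r < hi
        res = stats.pearsonr(x, y)
        assert r == pytest.approx(float(res.statistic))
        assert p == pytest.approx(float(res.pvalue))

    def test_perfect_correlation_degenerate(self):
        x = np.arange(10.0)
        r, lo, hi, p = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert (lo, hi) == (1.0, 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_fisher_z_coverage_near_nominal(self):
        """~95% of Fisher-z CIs cover the true correlation on bivariate-normal
        draws at n = 35 (seeded, tolerance +/- 2%)."""
        rng = np.random.default_rng(12)
        rho, n, sims = 0.5, 35, 2000
        cov = [[1, rho], [rho, 1]]
        hits = 0
        for _ in range(sims):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            r = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
            lo, hi = fisher_z_ci(r, n)
            hits += lo <= rho <= hi
        assert abs(hits / sims - 0.95) < 0.02


class TestGroupSummaries:
    def test_medians_and_quantile_convention(self, profiles, labels, cohort):
        groups = cohort.capra_groups
        out = group_summaries(profiles, groups)
        dre = out[(out.sample_type == "DRE") & (out.statistic == "n_positive")]
        scores = profiles.xs("DRE", level="sample_type")
        g = groups.loc[scores.index]
        for code in (0, 1, 2):
            v = scores.loc[g == code, "n_positive"].to_numpy(float)
            row = dre[dre.group == code].iloc[0]
            assert row["median"] == np.percentile(v, 50)
            assert row["q1"] == np.percentile(v, 25)  # type-7 linear interpolation
            assert row["n"] == len(v)
            assert row["min"] <= row["q1"] <= row["median"] <= row["q3"] <= row["max"]

    def test_single_member_group(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", "DRE"), ("b", "DRE")], names=["patient_id", "sample_type"]
        )
        profiles = pd.DataFrame(
            {"n_positive": [7, 2], "avg_methylation": [3.0, 0.5]}, index=idx
        )
        groups = pd.Series([2, 0], index=["a", "b"])
        out = group_summaries(profiles, groups)
        row = out[(out.group == 2) & (out.statistic == "n_positive")].iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 7
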