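"""Vote aggregation, exact binomial CI, paired t, ANOVA + Tukey, sample size."""

import numpy as np
import pytest
from scipy.stats import binom

from spinefuse import (
    VoteRecord,
    aggregate_votes,
    anova_tukey,
    clopper_pearson,
    noninferiority_test,
    paired_t_one_sided,
    sample_size_paired,
)
from spinefuse.errors import (
    DegenerateTestError,
    InvalidParameterError,
    InvalidRecordError,
)
from spinefuse.stats import ARIR, EQUIV, HRIR


def make_records(n_arir, n_equiv, n_hrir):
    """Unanimous records producing the given aggregated counts."""
    recs = []
    for i in range(n_arir):
        recs.append(VoteRecord(f"a{i}", (ARIR, ARIR, ARIR)))
    for i in range(n_equiv):
        recs.append(VoteRecord(f"e{i}", (EQUIV, EQUIV, EQUIV)))
    for i in range(n_hrir):
        recs.append(VoteRecord(f"h{i}", (HRIR, HRIR, HRIR)))
    return recs


class TestAggregateVotes:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ((ARIR, ARIR, HRIR), ARIR),
            ((ARIR, HRIR, EQUIV), EQUIV),  # three-way split
            ((HRIR, HRIR, HRIR), HRIR),
            ((EQUIV, EQUIV, ARIR), EQUIV),
        ],
    )
    def test_majority_rule(self, votes, expected):
        assert aggregate_votes(VoteRecord("c", votes)) == expected

    def test_order_invariance(self):
        import itertools

        for perm in itertools.permutations((ARIR, ARIR, HRIR)):
            assert aggregate_votes(VoteRecord("c", perm)) == ARIR

    def test_wrong_vote_count_rejected(self):
        with pytest.raises(InvalidRecordError):
            VoteRecord("c", (ARIR, ARIR))
        with pytest.raises(InvalidRecordError):
            VoteRecord("c", ("YES", ARIR, HRIR))


def cp_bisection_oracle(successes, n, confidence):
    """Invert the binomial tail sums directly by bisection."""
    alpha = 1.0 - confidence

    def solve(f, lo=0.0, hi=1.0):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    low = 0.0 if successes == 0 else solve(
        lambda p: binom.sf(successes - 1, n, p) - alpha / 2
    )
    high = 1.0 if successes == n else solve(
        lambda p: -(binom.cdf(successes, n, p) - alpha / 2)
    )
    return low, high


class TestClopperPearson:
    def test_reproduces_published_interval_for_21_of_28(self):
        low, high = clopper_pearson(21, 28, 0.95)
        assert round(low, 2) == 0.55
        assert round(high, 2) == 0.89

    def test_boundary_cases_exact(self):
        assert clopper_pearson(28, 28, 0.95)[1] == 1.0
        assert clopper_pearson(0, 28, 0.95)[0] == 0.0

    @pytest.mark.parametrize("k", [0, 1, 7, 14, 21, 27, 28])
    def test_matches_tail_inversion_oracle(self, k):
        got = clopper_pearson(k, 28, 0.95)
        want = cp_bisection_oracle(k, 28, 0.95)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_monotone_in_successes(self):
        lows, highs = zip(*(clopper_pearson(k, 28) for k in range(29)))
        assert list(lows) == sorted(lows)
        assert list(highs) == sorted(highs)

    def test_coverage_at_study_operating_point(self):
        """Exact interval covers the true p >= 95% of the time (5000 sims)."""
        rng = np.random.default_rng(10)
        p_true, n = 0.75, 28
        hits = 0
        intervals = {k: clopper_pearson(k, n, 0.95) for k in range(n + 1)}
        for k in rng.binomial(n, p_true, size=5000):
            low, high = intervals[int(k)]
            hits += low <= p_true <= high
        assert hits / 5000 >= 0.945  # exact method is conservative

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            clopper_pearson(5, 4)
        with pytest.raises(InvalidParameterError):
            clopper_pearson(-1, 4)


class TestNonInferiority:
    def test_study_counts_demonstrate_noninferiority(self):
        res = noninferiority_test(make_records(17, 4, 7), margin=0.45)
        assert (res.n_arir, res.n_equiv, res.n_hrir) == (17, 4, 7)
        assert res.proportion == pytest.approx(0.75)
        assert round(res.ci_low, 2) == 0.55
        assert round(res.ci_high, 2) == 0.89
        assert res.non_inferior

    def test_margin_equal_to_lower_bound_fails_strictly(self):
        res = noninferiority_test(make_records(17, 4, 7), margin=0.45)
        again = noninferiority_test(make_records(17, 4, 7), margin=res.ci_low)
        assert not again.non_inferior

    def test_all_human_preferred_fails(self):
        res = noninferiority_test(make_records(0, 0, 28), margin=0.45)
        assert res.proportion == 0.0
        assert not res.non_inferior

    def test_counts_sum_and_bounds_ordered(self):
        res = noninferiority_test(make_records(10, 5, 3))
        assert res.n == 18
        assert 0.0 <= res.ci_low <= res.proportion <= res.ci_high <= 1.0


class TestPairedT:
    def test_constant_positive_shift_significant(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 10)
        x = y + 0.5
        t, df, p = paired_t_one_sided(x, y, "greater")
        assert df == 9
        assert p < 0.05

    def test_matches_closed_form_on_fixed_data(self):
        x = np.array([0.25, 0.31, 0.18, 0.40, 0.22])
        y = np.array([0.20, 0.28, 0.20, 0.33, 0.19])
        d = x - y
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, df, p = paired_t_one_sided(x, y, "greater")
        assert t == pytest.approx(t_manual, abs=1e-12)
        from scipy.stats import t as tdist

        assert p == pytest.approx(tdist.sf(t_manual, len(d) - 1), abs=1e-12)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(DegenerateTestError):
            paired_t_one_sided([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestAnovaTukey:
    def test_identical_groups_no_effect_and_no_posthoc(self):
        g = [1.0, 1.0, 1.0, 1.0]
        res = anova_tukey([g, g, g])
        assert res.f_statistic == 0.0
        assert res.p_overall == 1.0
        assert not res.tukey_run

    def test_separated_group_pattern(self):
        rng = np.random.default_rng(12)
        g1 = rng.normal(0, 0.1, 8)
        g2 = rng.normal(0, 0.1, 8)
        g3 = rng.normal(10, 0.1, 8)
        res = anova_tukey([g1, g2, g3], group_names=["baseline", "arir", "hrir"])
        assert res.p_overall < 0.001
        assert res.tukey_run
        pair = {(p["group_a"], p["group_b"]): p["p_adj"] for p in res.pairwise}
        assert pair[("baseline", "arir")] > 0.05       # 1 vs 2 indistinguishable
        assert pair[("baseline", "hrir")] < 0.001      # 3 separated from both
        assert pair[("arir", "hrir")] < 0.001

    def test_matches_statsmodels_tukey_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [
            [5.1, 4.9, 5.3, 5.0, 5.2],
            [5.6, 5.8, 5.5, 5.9, 5.7],
            [4.2, 4.0, 4.3, 4.1, 4.4],
        ]
        res = anova_tukey(groups)
        data = np.concatenate(groups)
        labels = np.repeat(["g0", "g1", "g2"], 5)
        sm = pairwise_tukeyhsd(data, labels, alpha=0.05)
        sm_p = {
            (a, b): p
            for (a, b), p in zip(
                [("group0", "group1"), ("group0", "group2"), ("group1", "group2")],
                sm.pvalues,
            )
        }
        ours = {(p["group_a"], p["group_b"]): p["p_adj"] for p in res.pairwise}
        for key in ours:
            assert ours[key] == pytest.approx(sm_p[key], abs=1e-6)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            anova_tukey([[1.0, 2.0], [3.0, 4.0]])


class TestSampleSize:
    def test_unit_case_closed_form(self):
        # ((1.6449 + 0.8416) * 1 / 1)^2 = 6.18 -> 7
        res = sample_size_paired(sd=1.0, mean_diff=1.0, margin=0.0)
        assert res["n"] == 7

    def test_doubling_sd_quadruples_raw_n(self):
        a = sample_size_paired(sd=1.0, mean_diff=0.5)
        b = sample_size_paired(sd=2.0, mean_diff=0.5)
        assert b["n_raw"] == pytest.approx(4 * a["n_raw"], rel=1e-12)

    def test_audit_fields_present_for_study_inputs(self):
        res = sample_size_paired(sd=0.11, mean_diff=0.03, margin=0.05)
        assert res["effect"] == pytest.approx(0.08)
        assert res["n"] >= 2
        assert set(res) >= {"n", "n_raw", "effect", "z_alpha", "z_power"}

    def test_nonpositive_effect_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_size_paired(sd=1.0, mean_diff=-0.1, margin=0.05)
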