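"""Ratios, Welch tests, threshold derivation, composite classification and
the rank-sum distribution-shift test, each checked against an independent
oracle where one exists."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metaboflow.differential import (
    BOTH_ND,
    CON_ONLY,
    DOWN,
    FINITE,
    PRO_ONLY,
    SAME,
    UP,
    RatioValue,
    Thresholds,
    classify,
    derive_thresholds,
    distribution_shift_test,
    pro_con_ratio,
    welch_test,
)


def welch_oracle(a, b):
    """Direct Welch-Satterthwaite formula + t CDF, independent of the
    implementation's scipy.ttest_ind path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


def rank_sum_oracle(con, pro, alternative):
    """Brute-force enumeration of all rank splits of the pooled sample."""
    con, pro = list(con), list(pro)
    pooled = sorted(con + pro)
    n_con = len(con)

    def split_u(idx):
        con_v = [pooled[i] for i in idx]
        pro_v = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(
            sum(1.0 if c > p else 0.5 if c == p else 0.0 for p in pro_v)
            for c in con_v
        )

    observed = sum(
        sum(1.0 if c > p else 0.5 if c == p else 0.0 for p in pro)
        for c in con
    )
    us = [split_u(set(idx))
          for idx in itertools.combinations(range(len(pooled)), n_con)]
    us = np.array(us)
    if alternative == "con_less":
        return float((us <= observed + 1e-9).mean())
    lo = (us <= observed + 1e-9).mean()
    hi = (us >= observed - 1e-9).mean()
    return float(min(1.0, 2 * min(lo, hi)))


class TestProConRatio:
    def test_equal_means_give_unity(self):
        assert pro_con_ratio([2, 3, 4], [4, 3, 2]).value == pytest.approx(1.0)

    def test_pro_only_when_control_all_nd(self):
        ratio = pro_con_ratio([4, 4, 4], [np.nan] * 3)
        assert ratio.state == PRO_ONLY and ratio.value is None

    def test_con_only_symmetric(self):
        assert pro_con_ratio([np.nan] * 3, [1, 2, 3]).state == CON_ONLY

    def test_both_nd(self):
        assert pro_con_ratio([np.nan] * 3, [np.nan] * 3).state == BOTH_ND

    def test_hand_computation(self):
        assert pro_con_ratio([2, 4], [1, 2]).value == pytest.approx(2.0)

    def test_nd_excluded_from_means(self):
        assert pro_con_ratio([2, 4, np.nan], [1, 2, np.nan]).value == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pro_con_ratio([-1, 2], [1, 2])


class TestWelch:
    def test_identical_samples_p_one(self):
        assert welch_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2, 3], [2, 3, 4]),
            ([1.0, 1.1, 0.9], [2.0, 2.4, 1.8]),
            ([5, 5, 5, 6], [5, 7, 9]),
            ([0.2, 0.25, 0.22], [0.2, 0.21, 0.24]),
        ],
    )
    def test_matches_direct_formula_oracle(self, a, b):
        assert welch_test(a, b) == pytest.approx(welch_oracle(a, b), abs=1e-9)

    def test_insufficient_replicates_absent_not_one(self):
        assert welch_test([1.0], [1, 2, 3]) is None
        assert welch_test([1, 2, np.nan, np.nan], [1, np.nan, 2, 3]) is not None

    def test_zero_variance_conventions(self):
        assert welch_test([0, 0, 0], [0, 0, 0]) == 1.0
        assert welch_test([1, 1, 1], [2, 2, 2]) == 0.0

    @given(st.floats(min_value=0.01, max_value=1000), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance_and_group_swap(self, c, seed):
        rng = np.random.default_rng(seed)
        a = rng.lognormal(0, 0.3, 3)
        b = rng.lognormal(0.5, 0.3, 3)
        p = welch_test(a, b)
        assert welch_test(c * a, c * b) == pytest.approx(p, rel=1e-9)
        assert welch_test(b, a) == pytest.approx(p, rel=1e-12)
        r1 = pro_con_ratio(a, b).value
        r2 = pro_con_ratio(b, a).value
        assert r1 * r2 == pytest.approx(1.0, rel=1e-12)


def _results_frame(rows):
    return pd.DataFrame(
        rows, columns=["ratio_state", "ratio", "p"]
    )


class TestDeriveThresholds:
    def test_extremes_map_to_printed_thresholds(self):
        """Max significant-up ratio 1.202 -> 1.20; min significant-down
        0.830 -> 0.8 (asymmetric floor rounding)."""
        frame = _results_frame(
            [
                (FINITE, 1.202, 0.01),
                (FINITE, 1.15, 0.02),
                (FINITE, 0.830, 0.03),
                (FINITE, 0.9, 0.04),
                (FINITE, 3.0, 0.5),  # not significant: must not move upper
            ]
        )
        thr = derive_thresholds(frame)
        assert thr.upper == pytest.approx(1.20)
        assert thr.lower == pytest.approx(0.8)

    def test_fallback_defaults_when_no_significant_side(self):
        frame = _results_frame([(FINITE, 1.4, 0.5), (FINITE, 0.7, 0.9)])
        thr = derive_thresholds(frame)
        assert (thr.upper, thr.lower) == (1.20, 0.8)

    def test_one_sided_fallback(self):
        frame = _results_frame([(FINITE, 1.87, 0.01)])
        thr = derive_thresholds(frame)
        assert thr.upper == pytest.approx(1.87)
        assert thr.lower == 0.8

    def test_no_derivation_metabolite_falls_below_derived_lower(self):
        """Floor rounding means the minimum significant ratio itself never
        sits strictly below the derived lower bound."""
        frame = _results_frame([(FINITE, 0.91, 0.01), (FINITE, 0.87, 0.04)])
        thr = derive_thresholds(frame)
        assert thr.lower <= 0.87


class TestClassify:
    thr = Thresholds()

    @pytest.mark.parametrize(
        "ratio,p,expected",
        [
            (1.64, 0.01, UP),        # significant and above upper
            (1.55, 0.08, UP),        # 1.5-fold with loose significance
            (1.0, 0.9, SAME),
            (0.70, 0.03, DOWN),
            (1.3, 0.2, SAME),        # above upper but not significant
            (0.60, 0.08, DOWN),      # loose mirror clause
        ],
    )
    def test_rule_examples(self, ratio, p, expected):
        assert classify(RatioValue(FINITE, ratio), p, self.thr) == expected

    def test_degenerate_states(self):
        assert classify(RatioValue(PRO_ONLY), None, self.thr) == UP
        assert classify(RatioValue(CON_ONLY), None, self.thr) == DOWN
        assert classify(RatioValue(BOTH_ND), None, self.thr) == "UNDETECTED"

    def test_absent_p_blocks_p_dependent_clauses(self):
        assert classify(RatioValue(FINITE, 3.0), None, self.thr) == SAME

    @given(
        st.floats(min_value=0.05, max_value=20),
        st.floats(min_value=0.0, max_value=0.3),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_ratio(self, ratio, bump, p):
        """Increasing the ratio at fixed p never demotes the class."""
        order = {DOWN: 0, SAME: 1, UP: 2}
        lo = classify(RatioValue(FINITE, ratio), p, self.thr)
        hi = classify(RatioValue(FINITE, ratio * (1 + bump)), p, self.thr)
        assert order[hi] >= order[lo]


class TestDistributionShift:
    def test_identical_vectors_two_sided(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert distribution_shift_test(x, x) == pytest.approx(1.0)

    def test_exact_enumeration_small_case(self):
        assert distribution_shift_test([1, 2], [3, 4], "con_less") == pytest.approx(
            1 / 6
        )

    def test_wrong_direction_sanity(self):
        p = distribution_shift_test([5, 6, 7], [1, 2, 3], "con_less")
        assert p >= 0.9

    @pytest.mark.parametrize("n_con,n_pro,seed", [(2, 3, 0), (4, 4, 1), (5, 5, 2),
                                                  (3, 5, 3)])
    @pytest.mark.parametrize("alternative", ["two_sided", "con_less"])
    def test_exact_branch_matches_brute_force(self, n_con, n_pro, seed, alternative):
        rng = np.random.default_rng(seed)
        con = rng.normal(0, 1, n_con).round(2)
        pro = rng.normal(0.5, 1, n_pro).round(2)
        if np.unique(np.concatenate([con, pro])).size < n_con + n_pro:
            pro = pro + 1e-4  # force tie-free pooled sample
        got = distribution_shift_test(con, pro, alternative)
        want = rank_sum_oracle(con, pro, alternative)
        assert got == pytest.approx(want, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            distribution_shift_test([], [1.0])
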