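"""Contingency analysis, rank tests, odds ratios, and cohort arithmetic."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from abostroke.assoc import (
    SUBTYPES,
    TABLE1_COUNTS,
    build_contingency,
    chi_square_test,
    cohort_filter,
    compare_groups,
    contingency_from_counts,
    odds_ratio,
    round_half_up,
    wilcoxon_rank_sum,
)
from abostroke.bloodtype import BloodType, BloodTypeCall
from abostroke.simulate import SimConfig, draw_truth, gen_cohort_labels


def _direct_chi2(counts):
    counts = np.asarray(counts, dtype=float)
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    return ((counts - expected) ** 2 / expected).sum()


class TestChiSquare:
    def test_identical_rows_are_independent(self):
        chi2, df, p = chi_square_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_statistic_equals_direct_evaluation(self):
        counts = TABLE1_COUNTS.to_numpy()
        chi2, df, p = chi_square_test(counts)
        assert chi2 == pytest.approx(_direct_chi2(counts))
        assert df == 4

    def test_perfect_association(self):
        _, _, p = chi_square_test([[20, 0], [0, 20]])
        assert p < 1e-8

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError):
            chi_square_test([[5, 0], [5, 0]])


class TestContingency:
    def test_published_subtype_table(self):
        tab = contingency_from_counts(
            TABLE1_COUNTS.to_numpy(), ["O", "non_O"], list(SUBTYPES)
        )
        assert list(tab.row_percents[0]) == [25.12, 6.85, 28.59, 0.74, 38.70]
        assert list(tab.row_percents[1]) == [30.19, 7.07, 26.33, 0.82, 35.59]
        assert tab.p_value < 0.0001
        assert tab.df == 4

    def test_build_from_calls_excludes_missing(self):
        calls = [
            BloodTypeCall("a", BloodType.O, None, 1.0),
            BloodTypeCall("b", BloodType.NON_O, None, 1.0),
            BloodTypeCall("c", BloodType.MISSING, None, 1.0),
            BloodTypeCall("d", BloodType.NON_O, None, 1.0),
        ]
        labels = {"a": "LAA", "b": "LAA", "d": "SAO"}
        tab = build_contingency(calls, labels, col_labels=("LAA", "SAO"))
        assert tab.counts.sum() == 3

    def test_unlabelled_sample_is_error(self):
        calls = [BloodTypeCall("a", BloodType.O, None, 1.0)]
        with pytest.raises(ValueError, match="no category label"):
            build_contingency(calls, {}, col_labels=("LAA", "SAO"))


class TestOddsRatio:
    def test_no_association(self):
        or_, lo, hi = odds_ratio([[10, 10], [10, 10]])
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_arithmetic_oracle(self):
        # LAA vs non-LAA by blood type, cells from the published table sums
        a, b, c, d = 2030, 4693, 708, 2111
        or_, _, _ = odds_ratio([[a, b], [c, d]])
        assert or_ == pytest.approx(a * d / (b * c))

    def test_haldane_anscombe_correction(self):
        or_, _, _ = odds_ratio([[5, 0], [5, 5]])
        assert or_ == pytest.approx((5.5 * 5.5) / (0.5 * 5.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio([[1, -1], [1, 1]])


def _enumerated_two_sided_p(x, y):
    """Independent oracle: full enumeration of the rank-sum distribution."""
    xy = np.concatenate([x, y])
    ranks = stats.rankdata(xy)
    obs = ranks[: len(x)].sum()
    ws = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(xy)), len(x))]
    )
    return min(1.0, 2 * min(np.mean(ws <= obs), np.mean(ws >= obs)))


class TestWilcoxon:
    def test_separated_groups_exact_tail(self):
        """x={1,2,3} vs y={4,5,6}: 1 of C(6,3)=20 assignments per tail."""
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(2 / 20)

    def test_identical_constant_groups(self):
        _, p = wilcoxon_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=6), rng.normal(size=7)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_sample_p_matches_enumeration(self, seed):
        """Exact p (ties included) agrees with brute-force enumeration, n<=8."""
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 9, size=2)
        x = rng.integers(0, 5, size=nx).astype(float)
        y = rng.integers(0, 5, size=ny).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_enumerated_two_sided_p(x, y), abs=1e-12)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCohortFilter:
    def test_published_exclusion_arithmetic(self):
        assert cohort_filter(10241, 11, 688, 2174) == (9542, 7368)

    def test_no_exclusions(self):
        assert cohort_filter(100, 0, 0, 0) == (100, 100)

    def test_over_exclusion_is_error(self):
        with pytest.raises(ValueError):
            cohort_filter(10, 5, 6, 0)


def test_round_half_up_at_the_boundary():
    assert round_half_up(0.745) == 0.75  # bankers' rounding would give 0.74
    assert round_half_up(25.115) == 25.12


def test_compare_groups_detects_planted_ldl_shift():
    """The simulated non-O LDL-C excess shows up; the null biomarker does not
    systematically."""
    cfg = SimConfig(n_samples=4000, ldl_nonO_log_shift=0.1, seed=13)
    truth = draw_truth(cfg)
    bts = truth.set_index("sample_id")["true_blood_type"]
    sheet = gen_cohort_labels(bts, cfg)
    calls = [
        BloodTypeCall(s, BloodType.O if b == "O" else BloodType.NON_O, None, 1.0)
        for s, b in bts.items()
    ]
    out = compare_groups(sheet, calls, continuous=["ldl_c", "crp"], categorical=["subtype"])
    p = out.set_index("variable")["p_value"]
    assert p["ldl_c"] < 0.01
    assert out.set_index("variable").loc["subtype", "test"] == "chi_square"
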