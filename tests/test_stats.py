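"""Contingency-table statistics: chi-square, Cramer's V, cell tests."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazenum.stats import (ContingencyTable, StatsError, cell_tests,
                           chi_square_kx2, condition_reports, cramers_v,
                           format_report, interpret_v)
from gazenum.stimuli import Condition
from gazenum.study import DICE_FIVE_TABLE

# frozen independent oracle values for the dice-five worked table
# (pure-Python expected-count arithmetic, computed before this module)
DICE5_CHI2 = 3.005978243817127
DICE5_P = 0.2224641927230395
DICE5_V = 0.11824252262739053
DICE5_CELL3_CHI2 = 2.990441996350025
DICE5_CELL3_P_RAW = 0.08375730415290897
DICE5_CELL3_P_ADJ = 0.25127191245872693


def _table(counts, condition=Condition.DICE_CANONICAL):
    counts = np.asarray(counts)
    return ContingencyTable(counts=counts,
                            row_labels=tuple(f"t{i+1}"
                                             for i in range(counts.shape[0])),
                            col_labels=("dhh", "hearing"),
                            condition=condition)


class TestOmnibus:
    def test_proportional_margins_give_zero(self):
        res = chi_square_kx2(_table([[10, 20], [10, 20], [10, 20]]))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.v == pytest.approx(0.0, abs=1e-9)

    def test_perfect_2x2_association(self):
        res = chi_square_kx2(_table([[10, 0], [0, 10]]))
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1
        assert res.v == pytest.approx(1.0)

    def test_dice_five_matches_frozen_oracle(self):
        res = chi_square_kx2(_table(DICE_FIVE_TABLE))
        assert res.chi2 == pytest.approx(DICE5_CHI2, abs=1e-9)
        assert res.p == pytest.approx(DICE5_P, abs=1e-9)
        assert res.v == pytest.approx(DICE5_V, abs=1e-9)
        assert res.df == 2 and res.n == 215
        assert res.low_expected  # type-3 row has expected counts < 5

    def test_row_and_column_permutation_invariance(self):
        base = np.array([[33, 82], [24, 62], [1, 13]])
        ref = chi_square_kx2(_table(base)).chi2
        assert chi_square_kx2(_table(base[[2, 0, 1]])).chi2 \
            == pytest.approx(ref)
        assert chi_square_kx2(_table(base[:, ::-1])).chi2 \
            == pytest.approx(ref)

    def test_zero_row_dropped_with_record(self):
        res = chi_square_kx2(_table([[5, 9], [0, 0], [7, 3]]))
        assert res.dropped_rows == (1,)
        assert res.df == 1

    def test_empty_table_rejected(self):
        with pytest.raises(StatsError):
            _table([[0, 0], [0, 0]])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(counts=st.lists(
        st.tuples(st.integers(1, 60), st.integers(1, 60)),
        min_size=2, max_size=5))
    def test_matches_bruteforce_pearson(self, counts):
        """Statistic equals independent nested-loop expected-count sums."""
        tab = np.array(counts)
        res = chi_square_kx2(_table(tab))
        n = tab.sum()
        acc = 0.0
        for i in range(tab.shape[0]):
            for j in range(2):
                e = tab[i].sum() * tab[:, j].sum() / n
                acc += (tab[i, j] - e) ** 2 / e
        assert res.chi2 == pytest.approx(acc, rel=1e-12)
        assert res.v == pytest.approx(min(1.0, np.sqrt(acc / n)), rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a=st.integers(1, 50), b=st.integers(1, 50),
           c=st.integers(1, 50), d=st.integers(1, 50))
    def test_2x2_equals_closed_form(self, a, b, c, d):
        """n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on 2x2 inputs."""
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        res = chi_square_kx2(_table([[a, b], [c, d]]))
        assert res.chi2 == pytest.approx(closed, rel=1e-12)


class TestCramersV:
    def test_zero_iff_zero_chi2(self):
        assert cramers_v(0.0, 100, 3, 2) == 0.0

    def test_maximal_2x2(self):
        assert cramers_v(50.0, 50, 2, 2) == 1.0

    def test_requires_positive_n(self):
        with pytest.raises(StatsError):
            cramers_v(1.0, 0, 3, 2)

    def test_dice_five_v_from_oracle_chi2(self):
        assert cramers_v(DICE5_CHI2, 215, 3, 2) \
            == pytest.approx(DICE5_V, abs=1e-12)


class TestInterpretV:
    @pytest.mark.parametrize("v,df,label", [
        (0.21, 2, "medium"),
        (0.06, 2, "none"),   # below the df=2 small threshold of 0.07
        (0.50, 1, "large"),
        (0.07, 2, "small"),
        (0.35, 2, "large"),
        (0.10, 1, "small"),
        (0.29, 1, "small"),
        (0.09, 1, "none"),
    ])
    def test_cohen_benchmarks(self, v, df, label):
        assert interpret_v(v, df) == label

    def test_unsupported_df(self):
        with pytest.raises(StatsError, match="df=4"):
            interpret_v(0.3, 4)


class TestCellTests:
    def test_null_table_gives_unit_adjusted_p(self):
        res = cell_tests(_table([[10, 20], [5, 10], [15, 30]]))
        for c in res:
            assert c.chi2 == pytest.approx(0.0, abs=1e-12)
            assert c.p_adj == 1.0

    def test_dice_five_type3_cell_matches_oracle(self):
        res = cell_tests(_table(DICE_FIVE_TABLE))
        c3 = res[2]
        assert c3.chi2 == pytest.approx(DICE5_CELL3_CHI2, abs=1e-9)
        assert c3.p_raw == pytest.approx(DICE5_CELL3_P_RAW, abs=1e-9)
        assert c3.p_adj == pytest.approx(DICE5_CELL3_P_ADJ, abs=1e-9)
        assert c3.direction == "hearing"  # hearing over-uses counting here

    def test_bonferroni_monotone(self):
        for c in cell_tests(_table([[12, 30], [9, 14], [4, 21]])):
            assert c.p_adj >= c.p_raw
            assert c.p_adj <= 1.0

    def test_zero_margin_flagged_untestable(self):
        res = cell_tests(_table([[0, 0], [5, 10], [15, 30]]))
        assert not res[0].testable
        assert res[1].testable

    def test_requires_three_rows(self):
        with pytest.raises(StatsError):
            cell_tests(_table([[1, 2], [3, 4]]))


class TestConditionReports:
    @staticmethod
    def _counts(sub, cnt, dice, beyond):
        return {Condition.SUBITIZING_RANDOM: np.array(sub),
                Condition.COUNTING_RANDOM: np.array(cnt),
                Condition.DICE_CANONICAL: np.array(dice),
                Condition.BEYOND_DICE_CANONICAL: np.array(beyond)}

    def test_cell_tests_gated_on_omnibus_significance(self):
        flat = [[30, 60], [30, 60], [30, 60]]
        skew = [[80, 40], [20, 60], [20, 60]]
        reports = condition_reports(
            self._counts(skew, flat, flat, flat), ("dhh", "hearing"))
        assert len(reports[Condition.SUBITIZING_RANDOM].cells) == 3
        for cond in (Condition.COUNTING_RANDOM, Condition.DICE_CANONICAL,
                     Condition.BEYOND_DICE_CANONICAL):
            assert reports[cond].cells == []

    def test_missing_condition_is_error(self):
        counts = self._counts([[1, 2], [3, 4], [5, 6]],
                              [[1, 2], [3, 4], [5, 6]],
                              [[1, 2], [3, 4], [5, 6]],
                              [[1, 2], [3, 4], [5, 6]])
        del counts[Condition.DICE_CANONICAL]
        with pytest.raises(StatsError, match="dice_canonical"):
            condition_reports(counts, ("dhh", "hearing"))

    def test_report_text_names_all_conditions(self):
        flat = [[30, 60], [30, 60], [30, 60]]
        reports = condition_reports(
            self._counts(flat, flat, flat, flat), ("dhh", "hearing"))
        text = format_report(reports)
        for cond in reports:
            assert cond.value in text
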