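"""Pattern classification: examples, enumeration oracle, algebraic properties."""

from __future__ import annotations

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from densitraj.patterns import (
    PatternLabel,
    binarize,
    classify_pattern,
    paired_pattern_table,
    pattern_table,
    percent,
    percent_difference,
    sankey_frame,
    transition_table,
)

from conftest import make_cohort, make_timeline


def oracle_classify(seq) -> str:
    """Independent route: compare the sequence with its sorted versions."""
    s = list(seq)
    if len(set(s)) == 1:
        return "constant"
    if s == sorted(s):
        return "ascending"
    if s == sorted(s, reverse=True):
        return "descending"
    return "bi-directional"


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "seq,label",
        [
            ((2, 2, 2), PatternLabel.CONSTANT),  # c,c,c
            ((1, 2, 3), PatternLabel.ASCENDING),  # b,c,d
            ((1, 0, 1), PatternLabel.BIDIRECTIONAL),  # b,a,b
            ((1, 1, 2), PatternLabel.ASCENDING),  # plateau inside a monotone run
            ((3, 3, 1, 1), PatternLabel.DESCENDING),
        ],
    )
    def test_examples(self, seq, label):
        assert classify_pattern(seq) is label

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern([1, 2])

    @pytest.mark.parametrize("length", [3, 4])
    def test_enumeration_matches_oracle(self, length):
        """Every quaternary sequence of length 3 and 4 agrees with the
        sorted-copy oracle, and the length-3 census is (4, 16, 16, 28)."""
        counts = Counter()
        for seq in itertools.product(range(4), repeat=length):
            label = classify_pattern(seq)
            assert label.value == oracle_classify(seq)
            counts[label.value] += 1
        if length == 3:
            assert counts == {
                "constant": 4,
                "ascending": 16,
                "descending": 16,
                "bi-directional": 28,
            }

    def test_binary_enumeration_census(self):
        counts = Counter(
            classify_pattern(seq).value for seq in itertools.product((0, 1), repeat=3)
        )
        assert counts == {
            "constant": 2,
            "ascending": 2,
            "descending": 2,
            "bi-directional": 2,
        }


seqs = st.lists(st.integers(0, 3), min_size=3, max_size=8)


class TestProperties:
    @settings(max_examples=300, derandomize=True)
    @given(seqs)
    def test_partition(self, seq):
        """Exactly one of the four labels applies to any sequence."""
        assert classify_pattern(seq) in set(PatternLabel)

    @settings(max_examples=300, derandomize=True)
    @given(seqs)
    def test_reversal_antisymmetry(self, seq):
        swap = {
            PatternLabel.ASCENDING: PatternLabel.DESCENDING,
            PatternLabel.DESCENDING: PatternLabel.ASCENDING,
            PatternLabel.CONSTANT: PatternLabel.CONSTANT,
            PatternLabel.BIDIRECTIONAL: PatternLabel.BIDIRECTIONAL,
        }
        assert classify_pattern(seq[::-1]) is swap[classify_pattern(seq)]

    @settings(max_examples=300, derandomize=True)
    @given(seqs)
    def test_binarize_is_monotone_stable(self, seq):
        """The order-preserving binary collapse never reverses a trend:
        a constant sequence stays constant; an ascending one never becomes
        descending or bi-directional (and symmetrically)."""
        four = classify_pattern(seq)
        binary = classify_pattern(binarize(seq))
        if four is PatternLabel.CONSTANT:
            assert binary is PatternLabel.CONSTANT
        elif four is PatternLabel.ASCENDING:
            assert binary in (PatternLabel.CONSTANT, PatternLabel.ASCENDING)
        elif four is PatternLabel.DESCENDING:
            assert binary in (PatternLabel.CONSTANT, PatternLabel.DESCENDING)

    def test_binarize_example(self):
        assert binarize((0, 1, 2, 3)) == (0, 0, 1, 1)


class TestTables:
    def test_all_constant_cohort(self):
        cohort = make_cohort(*(make_timeline(f"W{i}", [2, 2, 2]) for i in range(3)))
        tab = pattern_table(cohort, "reader", "four_category")
        assert tab.loc["constant", "count"] == 3
        assert tab["count"].sum() == 3

    def test_table_matches_naive_recount(self, sim_cohort):
        cohort, _ = sim_cohort
        for rater in ("ai", "reader"):
            tab = pattern_table(cohort, rater, "four_category")
            recount = Counter(
                oracle_classify(t.densities(rater)) for t in cohort
            )
            for pat in tab.index:
                assert tab.loc[pat, "count"] == recount.get(pat, 0)

    def test_paired_table_diagonal_under_perfect_agreement(
        self, perfect_agreement_cohort
    ):
        paired = paired_pattern_table(perfect_agreement_cohort, "four_category")
        off_diag = paired.counts.to_numpy().sum() - paired.counts.to_numpy().trace()
        assert off_diag == 0
        assert paired.n_women == 4

    def test_paired_table_single_disagreement_cell(self):
        cohort = make_cohort(
            make_timeline("W1", [1, 2, 3], ai_seq=[2, 2, 2]),
            make_timeline("W2", [1, 2, 3], ai_seq=[2, 2, 2]),
        )
        paired = paired_pattern_table(cohort, "four_category")
        assert paired.counts.loc["constant", "ascending"] == 2
        assert paired.counts.to_numpy().sum() == 2

    def test_paired_marginals_reconcile(self, sim_cohort):
        cohort, _ = sim_cohort
        for context in ("four_category", "binary"):
            paired = paired_pattern_table(cohort, context)
            ai_tab = pattern_table(cohort, "ai", context)
            rd_tab = pattern_table(cohort, "reader", context)
            assert (paired.counts.sum(axis=1) == ai_tab["count"]).all()
            assert (paired.counts.sum(axis=0).to_numpy() == rd_tab["count"].to_numpy()).all()

    def test_transition_table(self, sim_cohort):
        cohort, _ = sim_cohort
        tab = transition_table(cohort, "reader")
        assert tab.n_women == cohort.n_women
        one = make_cohort(make_timeline("W1", [1, 2, 3]))
        t1 = transition_table(one, "reader")
        assert t1.counts.loc["b", "d"] == 1
        assert t1.counts.to_numpy().sum() == 1
        sk = sankey_frame(t1)
        assert sk["count"].sum() == 1

    def test_empty_cohort_rejected(self):
        from densitraj.cohort import Cohort

        with pytest.raises(ValueError):
            pattern_table(Cohort(()), "ai", "four_category")


class TestPercentConvention:
    def test_round_half_up_to_one_decimal(self):
        assert percent(49575, 61177) == 81.0
        assert percent(34736, 61177) == 56.8

    def test_difference_of_rounded_percentages(self):
        # unrounded difference is 24.25; the printed convention gives 24.2
        assert percent_difference(49575, 34736, 61177) == 24.2
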