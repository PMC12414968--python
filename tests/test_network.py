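"""Clipped-Hebbian storage, thresholded recall and interference accounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gridmem import (
    NetworkParams,
    PatternSet,
    as_pattern,
    cross_pattern_activation,
    empty_matrix,
    exact_recall_all,
    firing_threshold,
    is_exact_recall,
    is_saturated_state,
    matrix_from_patterns,
    pre_threshold_sums,
    recall,
    store,
)


class TestStore:
    def test_outer_product_block(self):
        w = store(empty_matrix(4), (0, 1))
        expected = np.zeros((4, 4))
        expected[np.ix_([0, 1], [0, 1])] = 1
        assert (w == expected).all()

    def test_idempotent(self):
        w1 = store(empty_matrix(4), (0, 1))
        w2 = store(w1.copy(), (0, 1))
        assert (w1 == w2).all()

    def test_disjoint_supports_are_block_diagonal(self):
        w = matrix_from_patterns(4, [(0, 1), (2, 3)])
        assert w.sum() == 8
        assert w[0, 2] == 0 and w[2, 0] == 0

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            store(empty_matrix(4), (0, 4))


class TestRecall:
    def test_recall_of_stored_pattern(self, printed_matrix):
        assert recall(printed_matrix, (0, 1), 2).tolist() == [0, 1]

    def test_recall_of_invalid_cue_misfires(self, printed_matrix):
        assert pre_threshold_sums(printed_matrix, (0, 3)).tolist() == [1, 2, 2, 1]
        assert recall(printed_matrix, (0, 3), 2).tolist() == [1, 2]

    def test_all_ones_matrix_saturates_output(self):
        w = np.ones((5, 5), dtype=np.uint8)
        assert recall(w, (1, 3), 2).tolist() == list(range(5))

    def test_threshold_must_be_positive(self, printed_matrix):
        with pytest.raises(ValueError):
            recall(printed_matrix, (0, 1), 0)


class TestExactRecall:
    def test_stored_pattern_exact(self, printed_matrix):
        assert is_exact_recall(printed_matrix, (0, 1), 2)

    def test_invalid_cue_not_exact(self, printed_matrix):
        assert not is_exact_recall(printed_matrix, (0, 3), 2)

    def test_lone_pattern_self_recalls_at_t_equals_s(self):
        w = matrix_from_patterns(6, [(1, 2, 4)])
        assert is_exact_recall(w, (1, 2, 4), 3)

    def test_vectorised_matches_scalar(self, printed_matrix, printed_patterns):
        assert exact_recall_all(printed_matrix, printed_patterns, 2)
        assert all(
            is_exact_recall(printed_matrix, p, 2) for p in printed_patterns
        )
        assert not exact_recall_all(printed_matrix, [(0, 3)], 2)


class TestCrossPatternActivation:
    def test_saturated_state_value(self, printed_matrix, printed_patterns):
        # each of the 4 patterns drives its 2 non-member outputs at sum 1
        assert cross_pattern_activation(printed_matrix, printed_patterns) == 8

    def test_empty_matrix_gives_zero(self):
        assert cross_pattern_activation(empty_matrix(4), [(0, 1)]) == 0

    def test_single_pattern_has_no_cross_activation(self):
        w = matrix_from_patterns(4, [(0, 1)])
        assert cross_pattern_activation(w, [(0, 1)]) == 0

    def test_monotone_under_storage(self):
        # storing more patterns never reduces the interference total
        pats = [(0, 1), (2, 3), (0, 2), (1, 3)]
        last = 0
        for k in range(1, len(pats) + 1):
            w = matrix_from_patterns(4, pats[:k])
            now = cross_pattern_activation(w, pats[:k])
            assert now >= last
            last = now


class TestSaturatedState:
    def test_ideal_state_detected(self, printed_matrix, printed_patterns):
        assert is_saturated_state(printed_matrix, printed_patterns, 2)

    def test_deleted_entry_breaks_saturation(self, printed_matrix, printed_patterns):
        w = printed_matrix.copy()
        w[0, 2] = 0
        assert not is_saturated_state(w, printed_patterns, 2)

    def test_vacuous_for_empty_set(self):
        assert is_saturated_state(empty_matrix(3), [], 1)


@given(
    st.lists(
        st.sets(st.integers(0, 7), min_size=2, max_size=2).map(tuple),
        min_size=1,
        max_size=6,
    ),
    st.sets(st.integers(0, 7), min_size=2, max_size=2).map(tuple),
)
def test_storing_is_monotone(patterns, extra):
    """Adding a pattern never decreases any entry or pre-threshold sum."""
    w_before = matrix_from_patterns(8, patterns)
    w_after = store(w_before.copy(), extra)
    assert (w_after >= w_before).all()
    cue = patterns[0]
    assert (
        pre_threshold_sums(w_after, cue) >= pre_threshold_sums(w_before, cue)
    ).all()


@given(st.sets(st.integers(0, 9), min_size=1, max_size=5).map(tuple))
def test_member_sums_equal_sparsity(pattern):
    """A pattern stored alone drives each of its members at exactly S."""
    s = len(pattern)
    w = matrix_from_patterns(10, [pattern])
    sums = pre_threshold_sums(w, pattern)
    assert all(sums[i] == s for i in pattern)


@given(
    st.lists(
        st.sets(st.integers(0, 7), min_size=3, max_size=3).map(tuple),
        min_size=1,
        max_size=5,
    )
)
def test_exact_recall_is_threshold_monotone(patterns):
    """Raising T silences outputs: exact recall at T implies member sums >= T
    and the recalled set at T+1 is a subset of the set at T."""
    w = matrix_from_patterns(8, patterns)
    p = patterns[0]
    for t in range(1, 4):
        r_t = set(recall(w, p, t).tolist())
        r_t1 = set(recall(w, p, t + 1).tolist())
        assert r_t1 <= r_t
        if is_exact_recall(w, p, t):
            assert (pre_threshold_sums(w, p)[list(p)] >= t).all()


class TestParamsAndPatterns:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(4, 5)
        with pytest.raises(ValueError):
            NetworkParams(4, 2, 3)
        with pytest.raises(ValueError):
            NetworkParams(4, 2, 0)

    def test_canonical_threshold(self):
        assert NetworkParams(12, 4, 1).threshold == 4
        assert NetworkParams(12, 4, 2).threshold == 3
        # both CLI conventions resolve to the same effective rule
        assert firing_threshold(4, 2, "geq_T") == firing_threshold(4, 2, "strict_gt")
        with pytest.raises(ValueError):
            firing_threshold(4, 1, "bogus")

    def test_divisibility_guard(self):
        NetworkParams(12, 4, 2).require_divisibility()
        with pytest.raises(ValueError):
            NetworkParams(10, 4).require_divisibility()
        with pytest.raises(ValueError):
            NetworkParams(12, 4, 3).require_divisibility()  # D does not divide S
        # boundary sparsities are allowed
        assert NetworkParams(5, 5).require_divisibility().b == 1
        assert NetworkParams(5, 1).require_divisibility().b == 5

    def test_as_pattern_normalises_and_validates(self):
        assert as_pattern([3, 1, 2]) == (1, 2, 3)
        with pytest.raises(ValueError):
            as_pattern([1, 1])
        with pytest.raises(ValueError):
            as_pattern([-1])
        with pytest.raises(ValueError):
            as_pattern([5], n=5)

    def test_pattern_set_enforces_difference(self):
        params = NetworkParams(8, 4, 2)
        PatternSet(params, [(0, 1, 2, 3), (2, 3, 4, 5)]).validate()
        with pytest.raises(ValueError):
            PatternSet(params, [(0, 1, 2, 3), (0, 1, 2, 4)]).validate()
        with pytest.raises(ValueError):
            PatternSet(params, [(0, 1, 2)])
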