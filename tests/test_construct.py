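"""Grid construction of saturated matrices and their structural audit."""

import numpy as np
import pytest

from gridmem import (
    GridSpec,
    NetworkParams,
    basis_patterns,
    build_saturated_matrix,
    count_valid_patterns,
    is_saturated_state,
    matrix_from_patterns,
    validate_saturated,
    enumerate_valid_patterns,
    exact_recall_all,
)


class TestBasisPatterns:
    @pytest.mark.parametrize(
        "n, s, d, expected",
        [
            (4, 2, 1, [(0, 1), (2, 3)]),
            (6, 2, 1, [(0, 1), (2, 3), (4, 5)]),
            (8, 4, 2, [(0, 1, 2, 3), (4, 5, 6, 7)]),
        ],
    )
    def test_block_decomposition(self, n, s, d, expected):
        ps = basis_patterns(GridSpec.canonical(n, s, d))
        assert ps.patterns == expected

    def test_disjoint_and_covering(self):
        ps = basis_patterns(GridSpec.canonical(12, 4))
        cells = [i for p in ps for i in p]
        assert sorted(cells) == list(range(12))

    def test_basis_recalls_exactly_at_canonical_threshold(self):
        for n, s, d in [(6, 2, 1), (9, 3, 1), (8, 4, 2)]:
            spec = GridSpec.canonical(n, s, d)
            w = build_saturated_matrix(spec)
            ps = basis_patterns(spec)
            assert exact_recall_all(w, ps.patterns, spec.params.threshold)


class TestBuild:
    def test_worked_4x4_matrix(self):
        # the [identity, reversed] orientation pair gives the worked example
        spec = GridSpec(NetworkParams(4, 2), perms=((0, 1), (1, 0)))
        w = build_saturated_matrix(spec)
        assert w.tolist() == [
            [1, 1, 1, 0],
            [1, 1, 0, 1],
            [1, 0, 1, 1],
            [0, 1, 1, 1],
        ]

    def test_single_block_is_all_ones(self):
        w = build_saturated_matrix(GridSpec.canonical(2, 2))
        assert (w == 1).all()

    def test_three_block_matrix_counts(self):
        w = build_saturated_matrix(GridSpec.canonical(6, 2))
        # each off-diagonal 2x2 sub-matrix has exactly one zero per row/column
        for a in range(3):
            for b in range(3):
                sub = w[2 * a : 2 * a + 2, 2 * b : 2 * b + 2]
                if a == b:
                    assert (sub == 1).all()
                else:
                    assert (sub.sum(axis=0) == 1).all()
                    assert (sub.sum(axis=1) == 1).all()
        assert count_valid_patterns(w, 2) == 9

    def test_d_expansion_is_kron_of_equivalent(self):
        spec = GridSpec.canonical(8, 4, 2)
        w = build_saturated_matrix(spec)
        w_eq = build_saturated_matrix(GridSpec.canonical(4, 2, 1))
        assert (w == np.kron(w_eq, np.ones((2, 2), dtype=np.uint8))).all()

    def test_bad_perms_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(NetworkParams(4, 2), perms=((0, 1),))
        with pytest.raises(ValueError):
            GridSpec(NetworkParams(4, 2), perms=((0, 0), (0, 1)))
        with pytest.raises(ValueError):
            GridSpec.canonical(10, 4)


class TestValidate:
    @pytest.mark.parametrize(
        "n, s, d", [(4, 2, 1), (6, 2, 1), (9, 3, 1), (8, 4, 2), (12, 4, 1)]
    )
    def test_constructed_matrices_pass(self, n, s, d):
        spec = GridSpec.canonical(n, s, d)
        assert validate_saturated(build_saturated_matrix(spec), spec) == []

    def test_randomly_oriented_matrices_pass(self):
        for seed in range(5):
            spec = GridSpec.with_random_orientations(9, 3, seed=seed)
            assert validate_saturated(build_saturated_matrix(spec), spec) == []

    def test_all_ones_matrix_flagged(self):
        spec = GridSpec.canonical(4, 2)
        violations = validate_saturated(np.ones((4, 4), dtype=np.uint8), spec)
        assert any("zero" in v for v in violations)

    def test_doubled_zero_reported_with_block_coordinates(self):
        spec = GridSpec.canonical(4, 2)
        w = build_saturated_matrix(spec).copy()
        w[0, 3] = 0  # second zero in off-diagonal block (0, 1)
        violations = validate_saturated(w, spec)
        assert any("(0,1)" in v for v in violations)

    def test_transitive_inconsistency_detected(self):
        # three blocks: make the (0,1)/(1,0) zeros a swap while the other
        # pairs stay identity -> zero maps no longer compose
        spec = GridSpec.canonical(6, 2)
        w = build_saturated_matrix(spec).copy()
        sub = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        w[0:2, 2:4] = sub
        w[2:4, 0:2] = sub.T
        violations = validate_saturated(w, spec)
        assert any("transitively" in v for v in violations)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            validate_saturated(np.ones((3, 3)), GridSpec.canonical(4, 2))

    def test_non_binary_entries_flagged(self):
        spec = GridSpec.canonical(4, 2)
        w = build_saturated_matrix(spec).astype(int)
        w[0, 0] = 2
        assert validate_saturated(w, spec)

    def test_non_constant_expansion_block_flagged(self):
        spec = GridSpec.canonical(8, 4, 2)
        w = build_saturated_matrix(spec).copy()
        w[0, 4] ^= 1
        assert any("expansion" in v for v in validate_saturated(w, spec))


class TestSaturationProperties:
    @pytest.mark.parametrize("n, s, d", [(6, 2, 1), (9, 3, 1), (8, 4, 2)])
    def test_fixed_point_and_just_below_threshold(self, n, s, d):
        """Storing every enumerated pattern reproduces the constructed matrix
        and leaves every non-member output exactly one unit below firing."""
        spec = GridSpec.canonical(n, s, d)
        w = build_saturated_matrix(spec)
        patterns = list(enumerate_valid_patterns(w, s))
        assert (matrix_from_patterns(n, patterns) == w).all()
        assert is_saturated_state(w, patterns, spec.params.threshold)

    def test_capacity_is_orientation_invariant(self):
        counts = set()
        for seed in range(4):
            spec = GridSpec.with_random_orientations(9, 3, seed=seed)
            counts.add(count_valid_patterns(build_saturated_matrix(spec), 3))
        assert counts == {27}
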