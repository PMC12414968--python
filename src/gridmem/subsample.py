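"""Enumerate every pattern storable without error in a saturated matrix.

A pattern can be stored without altering the matrix (and hence without
disturbing any previously stored pattern) iff every ordered pair of its
active cells is already connected — the pattern is an S-clique of the
bidirectional connection graph.  The enumerator walks candidate cells in
increasing index order with recursive backtracking, narrowing the
candidate pool to the common neighbours of the cells chosen so far and
pruning any branch whose pool cannot reach size S.  Output order is
lexicographic on the active-index lists, deterministic run to run.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

from .construct import GridSpec
from .network import Pattern, PatternSet

__all__ = [
    "enumerate_valid_patterns",
    "count_valid_patterns",
    "patterns_from_slot_assignments",
]


def enumerate_valid_patterns(
    w: np.ndarray, s: int, limit: int | None = None
) -> Iterator[Pattern]:
    """Lazily yield, in lexicographic order, every storable S-subset.

    A subset qualifies iff ``w[i, j] == 1`` for all ordered pairs of its
    cells (diagonal included), i.e. storing it changes no matrix entry.
    ``limit`` caps the number of patterns yielded.
    """
    w = np.asarray(w)
    n = w.shape[0]
    if s > n:
        raise ValueError(f"sparsity S={s} exceeds N={n}")
    if s < 1:
        raise ValueError("sparsity must be >= 1")
    sym = (w.astype(bool) & w.astype(bool).T)
    diag = np.diagonal(sym).copy()

    count = 0

    def extend(chosen: list, pool: np.ndarray, start: int) -> Iterator[Pattern]:
        nonlocal count
        if len(chosen) == s:
            yield tuple(chosen)
            count += 1
            return
        candidates = np.nonzero(pool)[0]
        candidates = candidates[candidates >= start]
        need = s - len(chosen)
        for pos, i in enumerate(candidates):
            if limit is not None and count >= limit:
                return
            if len(candidates) - pos < need:  # pool exhausted: prune
                return
            yield from extend(chosen + [int(i)], pool & sym[i], int(i) + 1)

    yield from extend([], diag, 0)


def count_valid_patterns(w: np.ndarray, s: int) -> int:
    """Number of storable S-subsets of ``w`` (consumes the enumerator)."""
    return sum(1 for _ in enumerate_valid_patterns(w, s))


def patterns_from_slot_assignments(spec: GridSpec) -> PatternSet:
    """Closed-form cross-check of the enumerator for the canonical grid.

    On the identity-orientation, D = 1 grid, a storable pattern picks, for
    each local slot s, one block to supply the cell with that slot: the
    pattern { b_s * S + s : s = 0..S-1 } for every function b from slots to
    blocks, B ** S patterns in total.  Generated independently of the
    backtracking enumerator and must equal its output as a set.
    """
    if spec.params.d != 1:
        raise ValueError("slot-assignment generation requires D = 1")
    if not spec.is_canonical:
        raise ValueError("slot-assignment generation requires identity orientations")
    p = spec.params
    pats = [
        tuple(sorted(block * p.s + slot for slot, block in enumerate(assign)))
        for assign in itertools.product(range(p.b), repeat=p.s)
    ]
    return PatternSet(p, pats)
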