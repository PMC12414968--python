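"""Binary feedforward storage and thresholded recall.

The network is a single-layer, fully connected feedforward net with ``N``
input units, ``N`` output units and binary weights (a Willshaw-style
associative memory).  A pattern is a set of ``S`` active unit indices; the
cue and the desired output are identical (auto-association through a
feedforward matrix).  Storage is clipped-Hebbian: storing a pattern sets
``W[i, j] = 1`` for every ordered pair of its active cells, and the matrix
for a whole set is the element-wise OR of the per-pattern blocks.  Recall
multiplies the cue into ``W`` and fires every output whose pre-threshold
sum reaches the firing threshold ``T``.

Conventions
-----------
* Indices are 0-based; patterns are kept as strictly increasing tuples.
* Firing is ``sum >= T`` with canonical ``T = S - D + 1`` where ``D`` is the
  minimum number of active cells by which any two stored patterns must
  differ.  The equivalent strict-inequality convention (``sum > S - D``) is
  accepted at the CLI level and maps to the same effective rule.
* ``D`` counts differing *active* cells; the bitwise Hamming distance of two
  equal-sparsity patterns is ``2 D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Pattern",
    "NetworkParams",
    "PatternSet",
    "as_pattern",
    "patterns_to_array",
    "active_difference",
    "firing_threshold",
    "empty_matrix",
    "store",
    "matrix_from_patterns",
    "pre_threshold_sums",
    "recall",
    "is_exact_recall",
    "exact_recall_all",
    "cross_pattern_activation",
    "is_saturated_state",
    "THRESHOLD_CONVENTIONS",
]

#: A pattern: strictly increasing tuple of 0-based active unit indices.
Pattern = tuple

#: Accepted firing-threshold conventions.  ``geq_T`` fires iff the summed
#: input is >= T with T = S - D + 1; ``strict_gt`` is the strict-inequality
#: reading (fire iff sum > T with T = S - D), which is the same effective rule.
THRESHOLD_CONVENTIONS = ("geq_T", "strict_gt")


def as_pattern(active: Iterable[int], n: int | None = None) -> Pattern:
    """Normalise ``active`` to a sorted tuple of distinct valid indices."""
    p = tuple(sorted(int(i) for i in active))
    if len(set(p)) != len(p):
        raise ValueError(f"pattern has repeated indices: {p}")
    if p and p[0] < 0:
        raise ValueError(f"pattern has negative index: {p}")
    if n is not None and p and p[-1] >= n:
        raise ValueError(f"pattern index {p[-1]} out of range for N={n}")
    return p


def active_difference(p: Iterable[int], q: Iterable[int]) -> int:
    """Number of active cells of ``p`` not active in ``q`` (the D metric)."""
    return len(set(p) - set(q))


def firing_threshold(s: int, d: int = 1, convention: str = "geq_T") -> int:
    """Effective >=-threshold for sparsity ``s`` and differentiability ``d``.

    Both conventions resolve to the same rule: fire iff sum >= S - D + 1.
    """
    if convention not in THRESHOLD_CONVENTIONS:
        raise ValueError(f"unknown threshold convention {convention!r}")
    return s - d + 1


@dataclass(frozen=True)
class NetworkParams:
    """Parameter bundle (N, S, D) with the canonical threshold.

    Parameters
    ----------
    n : int
        Number of input units (= number of output units).
    s : int
        Pattern sparsity: active units per pattern (absolute count).
    d : int, default 1
        Minimum number of differing active cells between any two stored
        patterns.
    """

    n: int
    s: int
    d: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.s <= self.n:
            raise ValueError(f"require 1 <= S <= N, got S={self.s}, N={self.n}")
        if not 1 <= self.d <= self.s:
            raise ValueError(f"require 1 <= D <= S, got D={self.d}, S={self.s}")

    @property
    def threshold(self) -> int:
        """Canonical firing threshold T = S - D + 1 (fire iff sum >= T)."""
        return self.s - self.d + 1

    def require_divisibility(self) -> "NetworkParams":
        """Assert the grid-construction invariants: S | N, D | S, D | N."""
        if self.n % self.s:
            raise ValueError(f"S={self.s} must divide N={self.n}")
        if self.s % self.d:
            raise ValueError(f"D={self.d} must divide S={self.s}")
        if self.n % self.d:
            raise ValueError(f"D={self.d} must divide N={self.n}")
        return self

    # Equivalent-network view (used for D > 1): N_eq = N/D, S_eq = S/D.
    @property
    def n_eq(self) -> int:
        self.require_divisibility()
        return self.n // self.d

    @property
    def s_eq(self) -> int:
        self.require_divisibility()
        return self.s // self.d

    @property
    def b(self) -> int:
        """Number of orthogonal basis patterns, B = N/S."""
        self.require_divisibility()
        return self.n // self.s


@dataclass
class PatternSet:
    """An ordered collection of patterns under shared network parameters."""

    params: NetworkParams
    patterns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patterns = [as_pattern(p, self.params.n) for p in self.patterns]
        for p in self.patterns:
            if len(p) != self.params.s:
                raise ValueError(
                    f"pattern {p} has {len(p)} active cells, expected S={self.params.s}"
                )

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def as_array(self) -> np.ndarray:
        """Boolean membership array of shape (P, N)."""
        return patterns_to_array(self.patterns, self.params.n)

    def validate(self) -> None:
        """Check pairwise distinctness and the >= D active-cell difference."""
        a = self.as_array()
        if len(a) < 2:
            return
        overlap = a.astype(np.int64) @ a.T.astype(np.int64)
        diff = self.params.s - overlap
        np.fill_diagonal(diff, self.params.s)
        if int(diff.min()) < self.params.d:
            i, j = np.unravel_index(int(diff.argmin()), diff.shape)
            raise ValueError(
                f"patterns {self.patterns[i]} and {self.patterns[j]} differ in "
                f"{int(diff[i, j])} active cells < D={self.params.d}"
            )


def patterns_to_array(patterns: Sequence[Iterable[int]], n: int) -> np.ndarray:
    """Stack patterns as a boolean membership matrix of shape (P, n)."""
    a = np.zeros((len(patterns), n), dtype=bool)
    for row, p in enumerate(patterns):
        a[row, list(p)] = True
    return a


def empty_matrix(n: int) -> np.ndarray:
    """All-zeros N x N binary connectivity matrix."""
    if n < 1:
        raise ValueError("N must be positive")
    return np.zeros((n, n), dtype=np.uint8)


def store(w: np.ndarray, pattern: Iterable[int]) -> np.ndarray:
    """Store a pattern in-place: set W[i, j] = 1 for all i, j active.

    Clipped-Hebbian storage; idempotent.  Returns ``w``.
    """
    p = as_pattern(pattern, w.shape[0])
    idx = np.fromiter(p, dtype=np.intp)
    w[np.ix_(idx, idx)] = 1
    return w


def matrix_from_patterns(n: int, patterns: Iterable[Iterable[int]]) -> np.ndarray:
    """Superimpose all per-pattern blocks into a fresh binary matrix."""
    w = empty_matrix(n)
    for p in patterns:
        store(w, p)
    return w


def pre_threshold_sums(w: np.ndarray, pattern: Iterable[int]) -> np.ndarray:
    """Raw weighted input to every output unit for cue ``pattern``."""
    p = as_pattern(pattern, w.shape[0])
    idx = np.fromiter(p, dtype=np.intp)
    return w[idx, :].sum(axis=0, dtype=np.int64)


def recall(w: np.ndarray, pattern: Iterable[int], t: int) -> np.ndarray:
    """Output units firing for cue ``pattern`` at threshold ``t`` (sum >= t)."""
    if t < 1:
        raise ValueError("threshold must be >= 1")
    return np.nonzero(pre_threshold_sums(w, pattern) >= t)[0]


def is_exact_recall(w: np.ndarray, pattern: Iterable[int], t: int) -> bool:
    """True iff the recalled output set equals the cue's active set."""
    p = as_pattern(pattern, w.shape[0])
    return recall(w, p, t).tolist() == list(p)


def exact_recall_all(
    w: np.ndarray, patterns: Sequence[Iterable[int]], t: int
) -> bool:
    """Vectorised check that every pattern recalls exactly at threshold ``t``."""
    if len(patterns) == 0:
        return True
    a = patterns_to_array(patterns, w.shape[0])
    sums = a.astype(np.int64) @ w.astype(np.int64)
    return bool(((sums >= t) == a).all())


def cross_pattern_activation(
    w: np.ndarray, patterns: Sequence[Iterable[int]]
) -> int:
    """Cross-pattern activation (CPA): interference accounting.

    Sums, over every stored pattern and every output unit *not* in that
    pattern, the pre-threshold input that cue drives into the non-member
    output.  Member outputs are pinned at S and carry no interference
    information, so they are excluded.
    """
    if len(patterns) == 0:
        return 0
    a = patterns_to_array(patterns, w.shape[0])
    sums = a.astype(np.int64) @ w.astype(np.int64)
    return int(sums[~a].sum())


def is_saturated_state(
    w: np.ndarray, patterns: Sequence[Iterable[int]], t: int
) -> bool:
    """True iff the stored set sits in the ideal capacity-achieving state.

    Every pattern recalls exactly, and every non-member output sum equals
    exactly ``t - 1`` — one unit below firing, so no further pattern could be
    stored without tipping some output over threshold.  Vacuously true for an
    empty set.
    """
    if len(patterns) == 0:
        return True
    a = patterns_to_array(patterns, w.shape[0])
    sums = a.astype(np.int64) @ w.astype(np.int64)
    if not ((sums >= t) == a).all():
        return False
    return bool((sums[~a] == t - 1).all())
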