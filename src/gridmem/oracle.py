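"""Brute-force ground truth for tiny networks.

Independent of the grid construction and the backtracking enumerator: the
exhaustive search walks all C(N, S) candidate patterns and finds the true
maximum number that can be stored simultaneously with exact recall of every
one of them and pairwise active-cell difference >= D.  Validity of a stored
family is downward-closed (clipped storage only adds connections, so a
spurious supra-threshold output never goes away), which makes depth-first
search with best-so-far pruning exact.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np

from .network import (
    NetworkParams,
    PatternSet,
    exact_recall_all,
    matrix_from_patterns,
    store,
)

__all__ = [
    "valid_patterns_bruteforce",
    "max_capacity_exhaustive",
    "verify_maximal",
]


def valid_patterns_bruteforce(w: np.ndarray, s: int) -> list:
    """All S-subsets whose ordered cell pairs are fully connected in ``w``.

    Naive all-subsets checker; the independent oracle for the backtracking
    enumerator at small N.
    """
    w = np.asarray(w)
    n = w.shape[0]
    out = []
    for cand in itertools.combinations(range(n), s):
        if all(w[i, j] for i in cand for j in cand):
            out.append(cand)
    return out


def _pairwise_ok(stored: Sequence[tuple], cand: tuple, d: int) -> bool:
    cset = set(cand)
    for p in stored:
        if len(set(p) - cset) < d:
            return False
    return True


def max_capacity_exhaustive(
    params: NetworkParams,
    max_candidates: int = 100,
    symmetric_pruning: str = "auto",
) -> tuple[int, PatternSet]:
    """Exact maximum mutually-recallable family size, with one witness.

    Depth-first search over all C(N, S) candidate patterns in lexicographic
    order, keeping the incumbent best and pruning branches that cannot beat
    it.  When D = 1 and ``symmetric_pruning`` is not "off", the search fixes
    the lexicographically smallest pattern {0..S-1} as a member: unit
    relabelling maps any maximum family onto one containing it, so the
    restriction is lossless (validated against the unpruned search in the
    test-suite).

    Refuses (``ValueError``) when C(N, S) exceeds ``max_candidates``; use the
    enumerator plus ``verify_maximal`` beyond that scale.
    """
    if symmetric_pruning not in ("auto", "on", "off"):
        raise ValueError("symmetric_pruning must be auto, on or off")
    n, s, d = params.n, params.s, params.d
    n_cand = math.comb(n, s)
    if n_cand > max_candidates:
        raise ValueError(
            f"C({n},{s}) = {n_cand} exceeds the exhaustive-search bound "
            f"{max_candidates}; use the enumerator with verify_maximal instead"
        )
    cands = list(itertools.combinations(range(n), s))
    t = params.threshold

    best_count = 0
    best_set: list = []

    def dfs(start: int, stored: list, w: np.ndarray) -> None:
        nonlocal best_count, best_set
        if len(stored) > best_count:
            best_count = len(stored)
            best_set = list(stored)
        for idx in range(start, n_cand):
            if len(stored) + (n_cand - idx) <= best_count:
                break  # cannot beat the incumbent
            cand = cands[idx]
            if not _pairwise_ok(stored, cand, d):
                continue
            w2 = store(w.copy(), cand)
            if not exact_recall_all(w2, stored + [cand], t):
                continue
            dfs(idx + 1, stored + [cand], w2)

    use_fix = symmetric_pruning == "on" or (symmetric_pruning == "auto" and d == 1)
    if use_fix:
        first = cands[0]
        w0 = matrix_from_patterns(n, [first])
        dfs(1, [first], w0)
    else:
        dfs(0, [], matrix_from_patterns(n, []))
    return best_count, PatternSet(params, best_set)


def verify_maximal(
    w: np.ndarray, patterns: Sequence[tuple], params: NetworkParams
) -> bool:
    """True iff no further S-subset is addable to the stored family.

    A candidate outside the family is addable when it meets the pairwise
    D-difference constraint and, after tentative clipped storage, every
    stored pattern (itself included) still recalls exactly.  Candidates that
    contain a zero pair of ``w`` are certified un-addable without the store
    check only when ``w`` is exactly the superposition of the stored family
    (then storing them would create new connections into a saturated state);
    here the full tentative-store check is applied for generality.
    """
    n, s, d, t = params.n, params.s, params.d, params.threshold
    stored = set(tuple(p) for p in patterns)
    stored_list = [tuple(p) for p in patterns]
    for cand in itertools.combinations(range(n), s):
        if cand in stored:
            continue
        if not _pairwise_ok(stored_list, cand, d):
            continue
        w2 = store(np.array(w, copy=True), cand)
        if exact_recall_all(w2, stored_list + [cand], t):
            return False
    return True
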