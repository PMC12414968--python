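"""Random sequential storage and the CPA-guided variant.

The stochastic baseline draws uniform random S-subsets and stores each
candidate that (a) is new, (b) differs from every stored pattern in at
least D active cells, and (c) leaves every stored pattern — itself
included — exactly recallable after clipped storage.  It keeps drawing
until no candidate remains addable (verified by an exhaustive scan when
C(N, S) is small) or a rejection budget is exhausted.  Because clipped
storage is not reversible entry-wise, acceptance is decided on a tentative
copy of the matrix and committed only on success.

The CPA-guided variant scores each admissible candidate by the
cross-pattern activation of the resulting state and stores the one with
the smallest score, breaking ties toward the lexicographically smallest
pattern.  CPA rewards candidates that add the least interference, but it
cannot undo early unlucky picks: both strategies can stall strictly below
the closed-form capacity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .capacity import CapacityResult
from .network import NetworkParams, PatternSet, as_pattern

__all__ = ["FillResult", "random_fill", "cpa_guided_fill"]

#: Exhaustive termination scans are used when C(N, S) is at most this.
EXHAUSTIVE_LIMIT = 20_000
#: Consecutive random rejections before an exhaustive termination scan.
SCAN_TRIGGER = 100
#: CPA candidate pools are exhaustive when C(N, S) is at most this.
CPA_EXHAUSTIVE_LIMIT = 2_000


@dataclass
class FillResult:
    """Stored set, capacity bookkeeping and run metadata for a fill run."""

    pattern_set: PatternSet
    capacity: CapacityResult
    metadata: dict = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.capacity.fraction


class _FillState:
    """Incrementally maintained store: membership array + clipped matrix.

    Keeps the P x N boolean membership array alongside W so that the
    admissibility test (pairwise D-difference + exact recall of everything
    after tentative storage) is a single matrix product per candidate.
    """

    def __init__(self, params: NetworkParams):
        self.params = params
        self.t = params.threshold
        self.w = np.zeros((params.n, params.n), dtype=np.int64)
        self.arr = np.zeros((0, params.n), dtype=np.int64)
        self.patterns: list = []

    def admissible(self, cand: tuple):
        """Tentative store; returns (w_after, arr_after) or None."""
        p = self.params
        vec = np.zeros(p.n, dtype=np.int64)
        vec[list(cand)] = 1
        if len(self.patterns):
            overlap = self.arr @ vec
            if int(overlap.max()) > p.s - p.d:  # too close to a stored pattern
                return None
        w2 = self.w | np.outer(vec, vec)
        arr2 = np.concatenate([self.arr, vec[None, :]])
        sums = arr2 @ w2
        if not (((sums >= self.t) == arr2.astype(bool)).all()):
            return None
        return w2, arr2

    def commit(self, cand: tuple, state) -> None:
        self.w, self.arr = state
        self.patterns.append(cand)

    def cpa(self, state) -> int:
        w2, arr2 = state
        sums = arr2 @ w2
        return int(sums[~arr2.astype(bool)].sum())

    def result(self, metadata: dict) -> FillResult:
        ps = PatternSet(self.params, self.patterns)
        cap = CapacityResult.for_params(self.params, len(self.patterns))
        return FillResult(ps, cap, metadata)


def _scan_any_addable(state: _FillState) -> bool:
    """Exhaustive lexicographic scan: is any candidate still addable?"""
    seen = set(state.patterns)
    p = state.params
    for cand in itertools.combinations(range(p.n), p.s):
        if cand in seen:
            continue
        if state.admissible(cand) is not None:
            return True
    return False


def random_fill(
    params: NetworkParams,
    seed: int,
    attempt_budget: int = 10_000,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> FillResult:
    """Fill the network by uniform random pattern draws until saturation.

    Terminates when an exhaustive scan certifies that nothing more fits
    (small C(N, S)) or after ``attempt_budget`` consecutive rejections.
    Fully reproducible: the same seed yields the same stored set.
    """
    if attempt_budget < 1:
        raise ValueError("attempt_budget must be >= 1")
    params.require_divisibility()
    rng = np.random.default_rng(seed)
    n_cand = math.comb(params.n, params.s)
    exhaustive = n_cand <= exhaustive_limit

    state = _FillState(params)
    rejections = 0
    # Inconclusive scans double the trigger: pure runtime tuning — accepted
    # patterns depend only on the RNG draw sequence, never on scan timing.
    trigger = SCAN_TRIGGER
    while True:
        cand = as_pattern(rng.choice(params.n, size=params.s, replace=False))
        trial = None if cand in state.patterns else state.admissible(cand)
        if trial is not None:
            state.commit(cand, trial)
            rejections = 0
            trigger = SCAN_TRIGGER
            continue
        rejections += 1
        if exhaustive:
            if rejections >= trigger:
                if not _scan_any_addable(state):
                    break
                rejections = 0
                trigger *= 2
        elif rejections >= attempt_budget:
            break

    return state.result(
        {
            "strategy": "random",
            "seed": seed,
            "attempt_budget": attempt_budget,
            "termination": "exhaustive_scan" if exhaustive else "rejection_budget",
            "candidates_total": n_cand,
        }
    )


def cpa_guided_fill(
    params: NetworkParams,
    seed: int,
    candidate_pool_size: int | None = None,
    attempt_budget: int = 10_000,
) -> FillResult:
    """Greedy fill choosing, each step, the admissible candidate of least CPA.

    ``candidate_pool_size=None`` scans every candidate when C(N, S) is small
    (<= CPA_EXHAUSTIVE_LIMIT) and otherwise samples 50 random candidates per
    step.  Ties in CPA break toward the lexicographically smallest pattern.
    """
    params.require_divisibility()
    rng = np.random.default_rng(seed)
    n_cand = math.comb(params.n, params.s)
    exhaustive = candidate_pool_size is None and n_cand <= CPA_EXHAUSTIVE_LIMIT
    pool_size = candidate_pool_size or 50

    state = _FillState(params)
    rejections = 0
    while True:
        if exhaustive:
            pool = itertools.combinations(range(params.n), params.s)
        else:
            pool = (
                as_pattern(rng.choice(params.n, size=params.s, replace=False))
                for _ in range(pool_size)
            )
        best = None  # (cpa, pattern, trial state)
        for cand in pool:
            cand = tuple(cand)
            if cand in state.patterns:
                continue
            trial = state.admissible(cand)
            if trial is None:
                continue
            score = state.cpa(trial)
            if best is None or (score, cand) < (best[0], best[1]):
                best = (score, cand, trial)
        if best is None:
            if exhaustive:
                break  # full scan found nothing addable
            rejections += pool_size
            if rejections >= attempt_budget:
                break
            continue
        state.commit(best[1], best[2])
        rejections = 0

    return state.result(
        {
            "strategy": "cpa",
            "seed": seed,
            "candidate_pool": "exhaustive" if exhaustive else pool_size,
            "attempt_budget": attempt_budget,
            "candidates_total": n_cand,
        }
    )
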