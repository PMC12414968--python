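"""Cost of reorganizing a suboptimal stored set into an optimal one.

Given a (typically randomly grown) stored set R and an optimal set O, each
R-pattern is matched one-to-one to a distinct O-pattern minimising total
bitwise Hamming distance (for equal-sparsity patterns, distance is twice
the active-cell set difference).  Reorganization then mixes two moves:
converting a pattern to its matched partner by flipping bits (cost = the
pair's Hamming distance) or deleting it outright (cost = S bits).  Sorting
pairs by conversion cost, the work curve gives, for every k, the total
bits spent converting the k cheapest pairs and deleting the rest; its
minimum is the least work to reach the optimal configuration.  Adding
optimal patterns absent from R is free — only flips and deletions are
priced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["bitwise_hamming", "match_patterns", "WorkCurve", "work_curve"]


def bitwise_hamming(p: Sequence[int], q: Sequence[int]) -> int:
    """Bitwise Hamming distance of two patterns (symmetric set difference)."""
    return len(set(p) ^ set(q))


def _cost_matrix(r_patterns, o_patterns) -> np.ndarray:
    return np.array(
        [[bitwise_hamming(r, o) for o in o_patterns] for r in r_patterns],
        dtype=np.int64,
    )


def match_patterns(
    r_patterns: Sequence, o_patterns: Sequence, method: str = "optimal"
) -> np.ndarray:
    """Assign each R-pattern to a distinct O-pattern.

    ``optimal`` solves the linear assignment problem exactly (minimum total
    bitwise Hamming distance); ``greedy`` walks R in order and grabs the
    nearest unused O-pattern (smaller index on ties), for comparison only.
    Returns the O-index assigned to each R-pattern, in R order.
    """
    if len(r_patterns) > len(o_patterns):
        raise ValueError(
            f"cannot match {len(r_patterns)} patterns into {len(o_patterns)}"
        )
    if len(r_patterns) == 0:
        return np.empty(0, dtype=np.intp)
    cost = _cost_matrix(r_patterns, o_patterns)
    if method == "optimal":
        rows, cols = linear_sum_assignment(cost)
        out = np.empty(len(r_patterns), dtype=np.intp)
        out[rows] = cols
        return out
    if method == "greedy":
        used: set = set()
        out = np.empty(len(r_patterns), dtype=np.intp)
        for i in range(len(r_patterns)):
            order = np.argsort(cost[i], kind="stable")
            pick = next(int(j) for j in order if int(j) not in used)
            used.add(pick)
            out[i] = pick
        return out
    raise ValueError(f"unknown matching method {method!r}")


@dataclass
class WorkCurve:
    """Reorganization work as a function of how many patterns are converted.

    Entry k converts the k cheapest matched pairs by bit flips and deletes
    the remaining |R| - k patterns at S bits each.
    """

    s: int
    pair_costs: np.ndarray  # conversion cost per R-pattern, sorted ascending
    order: np.ndarray  # R indices sorted by conversion cost
    assignment: np.ndarray  # O index matched to each R pattern (R order)
    r_patterns: list
    o_patterns: list

    @property
    def n_patterns(self) -> int:
        return len(self.pair_costs)

    def to_frame(self) -> pd.DataFrame:
        """Full curve: one row per k = 0..|R|, plus cumulative flip count."""
        ks = np.arange(self.n_patterns + 1)
        flips = np.concatenate([[0], np.cumsum(self.pair_costs)])
        removals = self.s * (self.n_patterns - ks)
        return pd.DataFrame(
            {
                "k": ks,
                "flips_bits": flips,
                "removal_bits": removals,
                "total_bits": flips + removals,
            }
        )

    @property
    def totals(self) -> np.ndarray:
        return self.to_frame()["total_bits"].to_numpy()

    @property
    def argmin_k(self) -> int:
        """Smallest k achieving the minimum total work."""
        return int(self.totals.argmin())

    @property
    def min_work_bits(self) -> int:
        return int(self.totals.min())

    def reorganized_set(self, k: int | None = None) -> list:
        """O-patterns obtained by converting the k cheapest pairs.

        With the unmatched (and deletion-freed) optimal patterns added —
        additions are not priced — the reorganized store is the full optimal
        set; this returns only the converted targets.
        """
        if k is None:
            k = self.argmin_k
        return [self.o_patterns[int(self.assignment[i])] for i in self.order[:k]]


def work_curve(
    r_patterns: Sequence, o_patterns: Sequence, s: int | None = None,
    method: str = "optimal",
) -> WorkCurve:
    """Compute the flip-vs-delete work curve for R against optimal set O."""
    r_patterns = [tuple(p) for p in r_patterns]
    o_patterns = [tuple(p) for p in o_patterns]
    if s is None:
        if not r_patterns and not o_patterns:
            raise ValueError("cannot infer S from empty pattern sets")
        s = len((r_patterns or o_patterns)[0])
    assignment = match_patterns(r_patterns, o_patterns, method=method)
    costs = np.array(
        [
            bitwise_hamming(r_patterns[i], o_patterns[int(assignment[i])])
            for i in range(len(r_patterns))
        ],
        dtype=np.int64,
    )
    order = np.argsort(costs, kind="stable")
    return WorkCurve(
        s=int(s),
        pair_costs=costs[order],
        order=order,
        assignment=assignment,
        r_patterns=r_patterns,
        o_patterns=o_patterns,
    )
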