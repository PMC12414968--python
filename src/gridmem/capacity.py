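"""Closed-form storage capacity and the equivalent-network transform.

At maximum threshold (D = 1) the number of patterns storable without any
recall error in the grid-constructed saturated matrix is exactly

    C = (N / S) ** S,

one block choice per local slot.  For D > 1 the network is mapped to an
equivalent network of size N_eq = N/D with sparsity S_eq = S/D (each
equivalent cell stands for a group of D original cells that always act
together), preserving the saturation condition, so the general capacity is
(N/S) ** (S/D).

A literal evaluation of the double-sum capacity expression
sum_{i=0}^{N/S-1} sum_{j=0}^{S} C(S, j) * i**j is also provided.  By the
binomial theorem it collapses to sum_{k=1}^{N/S} k**S, which strictly
exceeds (N/S)**S whenever N/S > 1; the closed form is the value certified
by the exhaustive oracle and is authoritative throughout the package.  The
double sum is retained purely as a documented reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .network import NetworkParams

__all__ = [
    "CapacityResult",
    "capacity_closed_form",
    "capacity_summation_as_printed",
    "capacity_general",
    "equivalent_params",
    "optimal_sparsity",
    "OptimalSparsity",
]


def _require_divides(num: int, den: int, what: str) -> None:
    if num % den:
        raise ValueError(f"{what}: {den} does not divide {num}")


def capacity_closed_form(n: int, s: int) -> int:
    """Maximum storable pattern count at D = 1: (N/S)**S, exact integers."""
    if not 1 <= s <= n:
        raise ValueError(f"require 1 <= S <= N, got S={s}, N={n}")
    _require_divides(n, s, "capacity_closed_form")
    return (n // s) ** s


def capacity_summation_as_printed(n: int, s: int) -> int:
    """Literal evaluation of the double-sum capacity expression.

    Computes sum_{i=0}^{N/S - 1} sum_{j=0}^{S} C(S, j) * i**j exactly.  Not
    the authoritative capacity: it equals sum_{k=1}^{N/S} k**S and exceeds
    the oracle-certified closed form for N/S > 1.  Kept for documentation
    and as an executable record of the discrepancy.
    """
    if not 1 <= s <= n:
        raise ValueError(f"require 1 <= S <= N, got S={s}, N={n}")
    _require_divides(n, s, "capacity_summation_as_printed")
    total = 0
    for i in range(n // s):
        for j in range(s + 1):
            total += math.comb(s, j) * i**j
    return total


def equivalent_params(n: int, s: int, d: int) -> tuple[int, int]:
    """Equivalent network (N_eq, S_eq) = (N/D, S/D) for differentiability D."""
    NetworkParams(n, s, d).require_divisibility()
    return n // d, s // d


def capacity_general(n: int, s: int, d: int = 1) -> int:
    """Capacity under a minimum active-cell difference D: (N/S)**(S/D)."""
    n_eq, s_eq = equivalent_params(n, s, d)
    return capacity_closed_form(n_eq, s_eq)


@dataclass
class CapacityResult:
    """Theoretical capacity next to an achieved pattern count."""

    params: NetworkParams
    c_closed: int
    c_achieved: int | None = None

    @property
    def b(self) -> int:
        return self.params.b

    @property
    def fraction(self) -> float | None:
        """Achieved capacity as a percentage of the closed form."""
        if self.c_achieved is None:
            return None
        return 100.0 * self.c_achieved / self.c_closed

    @classmethod
    def for_params(cls, params: NetworkParams, c_achieved: int | None = None):
        return cls(params, capacity_general(params.n, params.s, params.d), c_achieved)


@dataclass
class OptimalSparsity:
    """Argmax sparsity with the full (S, capacity) table."""

    s_opt: int
    table: pd.DataFrame
    tie_break: str = "smallest S"


def optimal_sparsity(
    n: int, d: int = 1, s_values: Sequence[int] | None = None
) -> OptimalSparsity:
    """Sparsity maximising capacity at fixed N and D.

    ``s_values`` defaults to every divisor of N compatible with D (D | S).
    Ties are broken toward the smallest S (the sparser code).
    """
    if s_values is None:
        s_values = [s for s in range(1, n + 1) if n % s == 0 and s % d == 0 and d <= s]
    s_values = sorted(set(int(s) for s in s_values))
    if not s_values:
        raise ValueError("no admissible sparsity values")
    rows = []
    for s in s_values:
        rows.append(
            {"n": n, "s": s, "d": d, "b": n // s, "capacity": capacity_general(n, s, d)}
        )
    table = pd.DataFrame(rows)
    best = int(table["capacity"].max())
    s_opt = int(table.loc[table["capacity"] == best, "s"].min())
    return OptimalSparsity(s_opt=s_opt, table=table)
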