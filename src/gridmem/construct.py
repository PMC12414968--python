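"""Deterministic construction of a fully saturated connectivity matrix.

The grid construction partitions the (equivalent) network's units into
B = N/S contiguous blocks of S_eq cells.  The B basis patterns — one block
each — saturate the diagonal sub-matrices.  Each block carries a
permutation of the local slots {0..S_eq-1} that assigns every cell a *class*
label; two cells in different blocks are left unconnected exactly when
their classes coincide, so every off-diagonal sub-matrix has exactly one
empty cell per row and per column.  The classes partition all cells into
S_eq groups of B cells, and the patterns that add no connection are
precisely the selections of one cell per class: B ** S_eq of them, the
closed-form capacity.

For D > 1 the matrix is built on the equivalent network (N_eq = N/D,
S_eq = S/D) and every equivalent cell is expanded to a D x D all-ones
sub-block, so stored patterns take whole D-cell groups and automatically
differ by at least D active cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import NetworkParams, PatternSet

__all__ = ["GridSpec", "basis_patterns", "build_saturated_matrix", "validate_saturated"]


def _identity_perm(s_eq: int) -> tuple:
    return tuple(range(s_eq))


@dataclass(frozen=True)
class GridSpec:
    """Grid layout of a saturated matrix: block decomposition + orientations.

    ``perms[a]`` is the permutation of local slots giving the class label of
    every cell in block ``a``; the default is the identity for every block.
    Any choice of per-block permutations yields a matrix with the same valid
    pattern count (capacity is orientation-invariant).
    """

    params: NetworkParams
    perms: tuple = None  # tuple of B permutations of range(S_eq)

    def __post_init__(self) -> None:
        self.params.require_divisibility()
        b, s_eq = self.params.b, self.params.s_eq
        perms = self.perms
        if perms is None:
            perms = tuple(_identity_perm(s_eq) for _ in range(b))
        perms = tuple(tuple(int(x) for x in p) for p in perms)
        if len(perms) != b:
            raise ValueError(f"need {b} block permutations, got {len(perms)}")
        for p in perms:
            if sorted(p) != list(range(s_eq)):
                raise ValueError(f"{p} is not a permutation of range({s_eq})")
        object.__setattr__(self, "perms", perms)

    @classmethod
    def canonical(cls, n: int, s: int, d: int = 1) -> "GridSpec":
        """Identity-orientation spec for (N, S, D)."""
        return cls(NetworkParams(n, s, d))

    @classmethod
    def with_random_orientations(cls, n: int, s: int, d: int = 1, seed: int = 0):
        """Spec whose block orientations are drawn from ``seed``."""
        params = NetworkParams(n, s, d).require_divisibility()
        rng = np.random.default_rng(seed)
        perms = tuple(
            tuple(int(x) for x in rng.permutation(params.s_eq))
            for _ in range(params.b)
        )
        return cls(params, perms)

    # cell-index decomposition on the equivalent network
    def block_of(self, i: int) -> int:
        return i // self.params.s_eq

    def local_of(self, i: int) -> int:
        return i % self.params.s_eq

    def class_of(self, i: int) -> int:
        """Class label of equivalent cell i: perms[block(i)][local(i)]."""
        return self.perms[self.block_of(i)][self.local_of(i)]

    @property
    def is_canonical(self) -> bool:
        return all(p == _identity_perm(self.params.s_eq) for p in self.perms)


def basis_patterns(spec: GridSpec) -> PatternSet:
    """The B = N/S pairwise-disjoint block patterns covering all N units."""
    p = spec.params
    pats = [tuple(range(a * p.s, (a + 1) * p.s)) for a in range(p.b)]
    return PatternSet(p, pats)


def build_saturated_matrix(spec: GridSpec) -> np.ndarray:
    """Build the saturated N x N matrix for ``spec``.

    On the equivalent network, W[i, j] = 1 iff block(i) == block(j) or
    class(i) != class(j); for D > 1 every equivalent entry expands to a
    D x D all-ones (or all-zeros) sub-block.
    """
    p = spec.params
    n_eq, s_eq = p.n_eq, p.s_eq
    blocks = np.repeat(np.arange(p.b), s_eq)
    classes = np.concatenate([np.asarray(perm) for perm in spec.perms])
    w_eq = (
        (blocks[:, None] == blocks[None, :]) | (classes[:, None] != classes[None, :])
    ).astype(np.uint8)
    if p.d == 1:
        return w_eq
    return np.kron(w_eq, np.ones((p.d, p.d), dtype=np.uint8))


def validate_saturated(w: np.ndarray, spec: GridSpec) -> list:
    """Structural audit of a candidate saturated matrix.

    Returns an empty list iff (a) diagonal sub-matrices are all-ones, (b)
    every off-diagonal sub-matrix has exactly one zero per row and per
    column, and (c) the zero placements are transitively consistent across
    blocks (the zero maps compose: sigma_ac = sigma_bc o sigma_ab), i.e.
    they derive from some family of per-block orientations.  For D > 1 the
    D x D expansion blocks must additionally be constant.

    Violations are reported as human-readable strings with block
    coordinates; a dimension mismatch raises ``ValueError``.
    """
    p = spec.params
    w = np.asarray(w)
    if w.shape != (p.n, p.n):
        raise ValueError(f"matrix shape {w.shape} does not match N={p.n}")
    violations: list = []
    if not np.isin(w, (0, 1)).all():
        violations.append("matrix entries are not all binary")
        return violations

    n_eq, s_eq, b, d = p.n_eq, p.s_eq, p.b, p.d
    if d > 1:
        grouped = w.reshape(n_eq, d, n_eq, d)
        if (grouped.min(axis=(1, 3)) != grouped.max(axis=(1, 3))).any():
            violations.append("D x D expansion sub-blocks are not constant")
            return violations
        w_eq = grouped[:, 0, :, 0]
    else:
        w_eq = w

    # zero maps sigma[a, b]: row r of block-pair (a, b) -> column of its zero
    sigma = {}
    bijective = True
    for a in range(b):
        for c in range(b):
            sub = w_eq[a * s_eq : (a + 1) * s_eq, c * s_eq : (c + 1) * s_eq]
            if a == c:
                if not (sub == 1).all():
                    violations.append(f"diagonal sub-matrix {a} is not all-ones")
                continue
            zr, zc = np.nonzero(sub == 0)
            row_counts = np.bincount(zr, minlength=s_eq)
            col_counts = np.bincount(zc, minlength=s_eq)
            if (row_counts != 1).any() or (col_counts != 1).any():
                violations.append(
                    f"off-diagonal sub-matrix ({a},{c}) lacks exactly one zero "
                    f"per row/column (row zeros {row_counts.tolist()}, "
                    f"column zeros {col_counts.tolist()})"
                )
                bijective = False
                continue
            m = np.empty(s_eq, dtype=np.intp)
            m[zr] = zc
            sigma[(a, c)] = m

    if bijective and not violations and b >= 2:
        ident = np.arange(s_eq)
        for a in range(b):
            for c in range(b):
                if a == c:
                    continue
                if (sigma[(c, a)][sigma[(a, c)]] != ident).any():
                    violations.append(
                        f"zero maps of block pair ({a},{c}) are not mutually inverse"
                    )
        for a in range(b):
            for c in range(b):
                for e in range(b):
                    if len({a, c, e}) < 3:
                        continue
                    if (sigma[(c, e)][sigma[(a, c)]] != sigma[(a, e)]).any():
                        violations.append(
                            f"zero maps are not transitively consistent across "
                            f"blocks ({a},{c},{e})"
                        )
    return violations
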