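# Methods

## Model

The network is a single layer of `N` binary input units fully connected to
`N` binary output units through a binary weight matrix `W`. A pattern is a
set of `S` active unit indices; cue and target are identical. Storage is
clipped-Hebbian (Willshaw): storing pattern `p` sets `W[i, j] = 1` for all
ordered pairs `i, j ∈ p`, and a stored set's matrix is the OR of the
per-pattern blocks — storage is monotone and not reversible entry-wise.
Recall computes, for cue `p`, the sums `a_j = Σ_{i∈p} W[i, j]` and fires
output `j` iff `a_j ≥ T`. A pattern is exactly recalled when the fired set
equals its active set. Member sums always equal `S`, so recall errors are
exclusively spurious activations of non-member outputs; because storage
only adds connections, a spurious activation never disappears as more
patterns are stored (validity of a stored family is downward-closed — the
property the oracle's pruning relies on).

Two representational parameters govern interference: the sparsity `S` and
the differentiability `D`, the minimum number of active cells by which any
two stored patterns must differ (bitwise Hamming distance `2D` for
equal-sparsity vectors).

### Threshold convention

The canonical firing rule is `fire iff sum ≥ T` with `T = S − D + 1`. The
strict-inequality reading (`fire iff sum > S − D`) is the same effective
rule; the CLI accepts either name (`geq_T` / `strict_gt`) and records
the choice in output metadata. At `D = 1` the threshold is maximal
(`T = S`): a single missing connection suppresses a spurious output.

## Capacity

With `S | N` and `D = 1` the maximum number of simultaneously storable,
exactly recallable patterns is `C = (N/S)^S`. For `D > 1` (with `D | S`,
`D | N`) original cells are grouped `D` at a time into equivalent cells; the
equivalent network `(N_eq, S_eq) = (N/D, S/D)` is at maximum threshold, and
`C = (N/S)^(S/D)`. Capacity is computed in exact integer arithmetic (no
floats), so sizes up to `N = 10^7` are handled.

The literal double sum `Σ_{i=0}^{N/S−1} Σ_{j=0}^{S} C(S,j) i^j` collapses,
by the binomial theorem, to `Σ_{k=1}^{N/S} k^S`, which strictly exceeds
`(N/S)^S` whenever `N/S > 1`. The exhaustive oracle certifies `(N/S)^S` as
the true maximum on every small instance tested, so the closed form is
authoritative everywhere in the package; the double sum is kept only as
`capacity_summation_as_printed`, with an executable test documenting the
disagreement (at `N=4, S=2`: 5 vs the certified 4). The enumeration the
double sum was meant to express is not recoverable, so no attempt is made
to "fix" it.

`optimal_sparsity` evaluates the closed form over admissible sparsities
(divisors of `N` compatible with `D` by default) and breaks capacity ties
toward the smaller `S` — sparser codes are preferred, and the tie-break is
recorded in the result. At `N = 12` the capacity peaks at `S = 4 = N/3`
(81 vs 64 at `S = 3` or `6`), the general `S ≈ N/3` optimum.

## Saturated-matrix construction

Units are split into `B = N/S` contiguous blocks of `S_eq` equivalent
cells. Each block `a` carries a permutation `perm_a` of the local slots;
`class(i) = perm_a(local(i))` labels every cell. The matrix is

    W[i, j] = 1  iff  block(i) = block(j)  or  class(i) ≠ class(j),

expanded by `kron(·, ones(D, D))` for `D > 1`. Diagonal sub-matrices are
all-ones (the basis patterns); each off-diagonal sub-matrix has exactly one
zero per row and per column. The classes partition the cells into `S_eq`
groups of `B`, and the subsets storable without adding a connection are
precisely the selections of one cell per class: `B^(S_eq)` patterns, each
pair differing in at least one class slot (≥ `D` original cells), every
non-member output sum sitting at exactly `T − 1`. Identity permutations are
the canonical default; any per-block choice gives the same capacity
(orientation invariance), and `GridSpec.with_random_orientations` draws one
reproducibly from a seed.

The class-coincidence placement is not cosmetic. The plausible alternative
— zeros on the anti-diagonal of each sub-matrix, i.e.
`class(i) + class(j) = S_eq − 1` — satisfies the one-zero-per-row/column
rule yet over-generates: at `N = 9, S = 3` it admits 29 fully connected
3-subsets, of which some fail exact recall once all are stored (its
conflict relation is not transitive). `validate_saturated` therefore checks
three things: all-ones diagonal blocks, one zero per row/column in every
off-diagonal block, and transitive consistency of the zero maps
(`σ_ac = σ_bc ∘ σ_ab` with mutually inverse pairs), which is exactly the
condition under which "adds no connection" coincides with "all patterns
recall exactly".

## Enumeration and the oracle

`enumerate_valid_patterns` yields every `S`-subset whose ordered cell pairs
are all connected — an `S`-clique search on the bidirectional graph —
by recursive backtracking: candidates are visited in increasing index
order, the pool is narrowed to common neighbours of the chosen cells, and a
branch is pruned when the pool cannot reach size `S`. Output is
lexicographic and deterministic; the iterator is lazy, with an optional
yield cap, so counting at `N = 24, S = 4` (1296 patterns) materialises
nothing. Two independent cross-checks are tested against it: a naive
all-subsets checker (`valid_patterns_bruteforce`, used up to `N = 12`) and
the closed-form slot-assignment generator (`patterns_from_slot_assignments`,
canonical grids only).

`max_capacity_exhaustive` is the ground truth: depth-first search over all
`C(N, S)` candidate patterns (refused above a configurable bound, default
100 candidates) maximising the simultaneously recallable family size under
the pairwise `D` constraint, with best-so-far pruning. When `D = 1` the
search fixes the lexicographically smallest pattern as a member — unit
relabelling maps any maximum family onto one containing it — and this
pruned search is validated against the unpruned one in the tests.
`verify_maximal` extends the guarantee beyond exhaustive scale by a single
pass over all candidates, checking none can be added.

## Baselines

`random_fill` draws uniform random `S`-subsets (numpy `default_rng(seed)`,
fully reproducible) and accepts a candidate iff it is new, differs from
every stored pattern in ≥ `D` active cells, and — after tentative storage
on a copy, since clipping cannot be rolled back — every stored pattern
still recalls exactly. Termination: when `C(N, S) ≤ 20,000`, an exhaustive
lexicographic scan certifies that nothing more fits (triggered after 100
consecutive rejections, with the trigger doubling after each inconclusive
scan — a pure runtime choice: accepted patterns depend only on the RNG draw
sequence, never on scan timing); for larger instances, a budget of 10,000
consecutive rejections. `cpa_guided_fill` scores each admissible candidate
by the cross-pattern activation (summed non-member pre-threshold input over
all stored patterns) of the resulting state, stores the minimiser and
breaks ties lexicographically; the pool is every candidate when
`C(N, S) ≤ 2,000`, else 50 fresh random draws per step. The pool sizes and
budgets are not externally prescribed; they are recorded in each run's
metadata. Both baselines routinely stall below `(N/S)^S` — early accepted
patterns correlate and saturate the matrix prematurely, and CPA cannot
repair a suboptimal prefix (frequently all remaining candidates tie).

## Reorganization cost

Given a suboptimal stored set `R` and an optimal set `O` (`|R| ≤ |O|`),
`match_patterns` assigns each `R`-pattern to a distinct `O`-pattern
minimising total bitwise Hamming distance, solved exactly as a linear
assignment problem (scipy's Hungarian solver); a greedy nearest-match mode
exists behind a flag for comparison. `work_curve` sorts the matched pairs
by conversion cost and reports, for every `k`, the bits flipped to convert
the `k` cheapest pairs plus `S` bits for each of the `|R| − k` deletions;
since sorted costs make the increments `d_k − S` non-decreasing, the curve
is convex and its minimum easy to read. The table carries both natural
x-axes — patterns converted (`k`) and cumulative bits flipped. Additions of
optimal patterns missing from `R` are free (only flips and deletions are
priced), and the constant cost of evaluating pattern viability is not
modelled. Converting per the argmin and adding the unmatched optimal
patterns provably lands on the full optimal configuration.

## Problem sizes and what the tests show

All simulations are desk-scale by design: constructive optimality is
verified exhaustively at `S = 4`, `N ∈ {12, 16, 20, 24}` (81–1296
patterns), the oracle runs where `C(N, S) ≤ 100`, and the baseline
comparison uses 50 seeds at `N = 16, S = 4` — small integer multiples of
`S`, the regime where both routes can be checked against ground truth. The
closed-form results are exact at any size; what the small-`N` simulations
cannot show is the asymptotic behaviour of the *random* baseline, whose
shortfall statistics at `N ≫ S` are estimated only through the rejection
budget. The model itself idealises aggressively: binary weights, noiseless
cues, identical input/output patterns, no pattern completion. Passing tests
certify the combinatorial claims, not robustness of recall under
degradation — noise tolerance is deliberately out of scope.

## Numerical and degenerate-input choices

- Capacity arithmetic is pure-integer; percentages are the only floats.
- `S = N` (a single storable pattern) and `S = 1` (capacity `N`, no
  interference at `T = 1`) are supported and used as boundary tests.
- Non-divisible `(N, S, D)` combinations raise in the core API and are
  skipped with a log message in sweeps — flooring would silently change
  the model.
- Pattern files are sorted 0-based index lists, one per line, `#` comments;
  matrix files are `N` followed by `N` rows of 0/1; all tables are CSV with
  run metadata (parameters, seeds, convention, version) in `#` headers.
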