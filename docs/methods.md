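# Methods

## Problem statement

Given a protein of `l` residues (optionally ending in a stop, written `*`),
find a coding sequence `c` (length `L = 3l` nucleotides) and a
pseudoknot-free secondary structure `s` of `c` minimizing

    J(c, s) = mu * E(c, s) + kappa * sum_{codons of c} (-ln w(codon))

where `E` is a loop-decomposition free energy and `w` is Sharp & Li's
relative adaptiveness (codon frequency divided by the maximum frequency in
its synonymous family).  Because CAI is the geometric mean of the `w`
values, `sum ln w = l * ln(CAI)`, so `J` realizes both standard objectives:
`MFE - lambda*l*log(CAI)` with `(mu, kappa) = (1, lambda)`, `lambda in
[0, inf)`, and `lambda*MFE - (1-lambda)*l*log(CAI)` with `(mu, kappa) =
(lambda, 1-lambda)`, `lambda in [0, 1]`.  Natural logarithms are used
throughout; any fixed log base only rescales `kappa`.

## Codon lattice

The search space of synonymous CDSs is a layered DAG: position `i` holds
one state per distinct codon prefix of length `i mod 3 + 1` of residue
`i div 3`'s family (at most 6 states).  Within a codon, edges follow the
prefix trie; across codon boundaries the graph is complete bipartite.
This prefix encoding resolves the first/third-position dependencies of the
six-codon families — e.g. a serine `AG` prefix can only continue with `U`
or `C` — so every path spells a valid CDS and the number of paths equals
the product of family sizes.  Third-position states carry their codon's
`-ln w`; `kappa * (-ln w)` is placed on the edges *entering* these states,
so any path accumulates the codon cost exactly once per codon.

Zero-frequency codons are not dropped: their `w` is floored at
`floor * max_family_frequency` (default `floor = 1e-3`) so the structural
search space always contains every synonymous codon.  Dropping them would
silently remove structures; the floor keeps them available at a steep but
finite codon cost.

## Joint dynamic program

The solver is a span-based Zuker-style DP whose cells are indexed by the
pair of lattice states at the span boundaries; each cell is a small
(≤ 6×6) matrix and recursions combine cells with min-plus matrix products.
Matrices (nearest-neighbor model):

* `C[i,j]` — spans closed by a base pair at `(i, j)`; cases: hairpin,
  stack, bulge/internal (total loop size ≤ 30, the standard enumeration
  cap), and multiloop;
* `M1[i,j]` / `M[i,j]` — multiloop segments with the first branch at `i` /
  at least one branch;
* `F[j]` — the external loop over the prefix `0..j`;
* `P[i,j]` — cheapest unpaired walk between two boundary states (codon
  cost only), used for loop interiors.

For the nussinov model the same machinery reduces to two matrices (`C` and
a free span matrix).  All span values include the codon costs of positions
`(i, j]`, which makes every combination charge each codon exactly once.
With bounded lattice width the exact solver runs in `O(L^3)` time and
`O(L^2)` space; the test suite asserts the cubic *operation-count* trend on
constant-width lattices rather than wall-clock time.

**Traceback** recomputes candidate values against the stored matrices and
descends into the first minimum in a fixed candidate order (unpaired before
paired, split points ascending, states in lexicographic prefix order).
This yields bit-reproducible outputs; among co-optimal solutions the
returned CDS is the one this ordering reaches first, which prefers
lexicographically smaller codon prefixes at each local decision (a cheap
deterministic surrogate for a globally lexicographic rule).  Every returned
design is re-scored from scratch (`score_structure`, `sum ln w`), and exact
mode verifies the re-scored objective equals the DP optimum to `1e-6`.

**Beam search** keeps the `b` lowest-valued entries per right endpoint of
the pairing-type matrices (`C`, and `M1` for the nearest-neighbor model),
ties broken by value then (position, state) index.  Aggregation matrices
(`M`, `F`, and the nussinov span matrix) are not pruned; this keeps every
stored value derivable from retained entries, so the traceback of a pruned
run is always feasible.  Beam results report the re-scored objective of the
traced design, which by construction bounds the exact optimum from above
and coincides with it once `b` exceeds the per-endpoint state count.

## Energy models

`nussinov`: −1 per closed pair, no loop terms — a transparent setting for
exhaustive validation.

`nearest_neighbor`: a deliberately bounded Turner-2004-derived parameter
surface, shipped as a plain-text table
(`src/codonfold/data/nn_params.txt`):

* Watson-Crick/wobble stacking energies (symmetric 21-entry table);
* hairpin/bulge/internal loop initiation for lengths ≤ 30, with
  `dG(n) = dG(30) + 1.75*R*T*ln(n/30)` beyond (T = 310.15 K);
* single-nucleotide bulges keep the flanking stack term; larger bulges and
  internal loops do not;
* affine multiloop energy `a + b*(branches incl. closing) + c*unpaired`
  with `a = 9.3`, `b = -0.9`, `c = 0.0` kcal/mol;
* a terminal AU/GU penalty (0.5 kcal/mol) charged for every AU/UA/GU/UG
  pair incident to a non-stack loop (i.e. once per helix end);
* minimum hairpin loop: 3 unpaired nucleotides.

Not modeled: dangling ends, terminal mismatches, tetraloop/special-hairpin
bonuses, internal-loop asymmetry, coaxial stacking.  Consequently absolute
MFE values differ from ViennaRNA/full Turner 2004, and published
benchmark counts obtained under full parameter parity (e.g. distinct-front
sizes for specific UniProt proteins) are not expected to reproduce under
this model; all correctness claims are made against the package's own
energy function via the exhaustive oracles.  The scorer
(`score_structure`) and both DPs share one term surface, so "reported
energy equals re-scored energy" is exact by construction and is asserted
everywhere.

Energies are double-precision; comparisons use absolute tolerance `1e-9`
(`1e-6` for the DP-vs-rescore consistency check, which accumulates float
summation differences across formulations).

## Pareto-front enumeration

The front is enumerated with the normalized scalarization `lambda*MFE -
(1-lambda)*S` (`S = l*log(CAI)`) by slope bisection:

1. solve the near-lexicographic endpoints `lambda = eps` and `1 - eps`
   (`eps = 1e-6`); pure 0/1 endpoints ignore one objective entirely and may
   return dominated representatives, the epsilon forces lexicographic
   optima;
2. for adjacent points `a` (stable) and `b` (adapted), solve at
   `lambda* = (Sa - Sb) / ((Ma - Mb) + (Sa - Sb))`, the weight at which
   both tie; recurse on both sub-intervals only if the new point improves
   the tied objective by more than `1e-9`; recursion depth is capped at 64
   (exceeding it signals tolerance pathology and raises);
3. every solver invocation counts toward `N`; distinct CDSs count toward
   `n`; a final dominance filter (sorted by descending CAI, strictly
   decreasing MFE kept) guards residual epsilon artifacts, and ties in both
   coordinates collapse to the lexicographically smallest CDS.

Only *supported* (convex-hull) Pareto points are reachable by weighted
sums; unsupported points are intentionally not enumerated.  MFE% and CAI%
annotations rescale each measure linearly over the front's observed range
(100% = most stable MFE / highest CAI; single-point fronts map to 100% by
convention).

## Oracles and what the tests show

Two exhaustive references validate the chain bottom-up: structure-space
enumeration (≤ 14 nt) validates the fixed-sequence folder; the folder then
scans all CDSs (≤ 6 aa, ≤ 8 aa for bare enumeration) to validate the joint
DP and the per-lambda optimality of front points.  Test problem sizes —
50 proteins of 2–5 aa for design exactness, 100 sequences ≤ 12 nt for
folding, fronts for proteins of 4–10 aa with the CDS-product capped at 400
for oracle-checked instances — were chosen so the whole suite exercises
every recursion case while remaining a desk-scale computation.  Random
proteins are uniform over the 20 amino acids (with that product cap), which
over-represents large synonymous families relative to natural sequences;
this is the stressful direction for the lattice DP.  Passing these tests
demonstrates exact agreement with the model as specified, not biological
accuracy of the turner-lite parameter surface.

## Known limitations

* Nearest-neighbor parity with ViennaRNA is out of scope (see above).
* Beam mode guarantees feasibility and upper-bounds the optimum but has no
  approximation ratio; beam quality is asserted only via the dominance and
  saturation contracts.
* The weighted-sum front misses unsupported Pareto points by design.
* `N` counts solver calls that returned a solution; alternative conventions
  (e.g. counting emitted distinct solutions) would change `N` but not the
  front itself.
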