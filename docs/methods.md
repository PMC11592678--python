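# Methods

## Scope and model

The package scores edges of undirected simple graphs (no self-loops, no
parallel edges, unweighted, static) and evaluates any scorer by edge
percolation. Directed, weighted and temporal graphs are out of scope. Node
labels are opaque strings and are never coerced to numbers; every edge is
addressed by a canonical key, the pair ordered lexicographically on the
string form of its labels, which fixes every ordering and tie-break in the
package deterministically.

## Index conventions

Several of the indices are defined in the literature only up to conventions
that matter numerically. The choices made here, and why:

**Second-order walk sets (SN).** `NN_{i/j}` is the set of endpoints `w ≠ i`
of length-2 walks `i → u → w` whose *intermediate* node `u` is not `j`; the
endpoint `w` may be `j` itself or a first-order neighbour of `i`. This is
the unique variant consistent with the published worked-example scores
(SN = 0.5 for both triangle edges of the first example network); excluding
`j` as an endpoint, or using distance-≤2 balls, give 0.75 and 4/9 instead.

**Empty-union Jaccard.** FN and SN are defined as 0 when the union of the
two sets is empty (isolated edges, triangle-free neighbourhoods). This
matches the second worked example, where every edge scores 0.

**Edge-betweenness normalization.** EB sums, over *unordered* node pairs,
the fraction of the pair's geodesics through the edge, then divides by
`N(N-1)/2`. This pair-normalized form is pinned by the worked-example
bridge values (42/78 = 0.54 and 22/78 = 0.28 on the triangle-free
network). On disconnected graphs, unreachable pairs contribute 0 while `N`
stays the full node count. The implementation is single-pass dependency
accumulation over per-source BFS path-count tables (`O(NM)`); it is
cross-checked in the tests against both `networkx` and an exact-rational
brute-force enumeration of all geodesics.

**Score direction.** Higher score = more important for every method,
including SN. The score tables of the source material rank descending by
score and the percolation protocol removes "most important first"; the
occasional prose claim that a *smaller* second-order overlap marks a more
important edge is inconsistent with those tables and is not followed.

**Mixing weights.** EN = `2·SN + 3·FN` and GLHC = `3·EB + 1·SN + 1.5·FN`.
The constants are empirical in origin; both are exposed as keyword
parameters (`w_sn`, `w_fn`, `w_eb`) with these defaults.

**Bridgeness cliques.** `S_i`, `S_j`, `S_e` come from exact maximal-clique
enumeration (Bron–Kerbosch with pivoting via `networkx.find_cliques`).
Worst case exponential; at the sparse desk scales targeted here it is
negligible.

**EI.** The published definition of the motif composite reuses the same
symbols for "actual" and "maximum" counts, so a concrete reading had to be
fixed: actual counts are exhaustive enumerations of triangles through the
edge, chordless 4-cycles through it, one-chord 4-cycles split by whether
the edge is the chord or a cycle edge, and K4s; maxima are the degree
bounds `min(k_i,k_j) − 1` (triangles) and `(k_i−1)(k_j−1)` (each
quadrilateral class). `L` and `L'` are mean geodesic distances over
connected pairs before/after contracting the edge (endpoints merged,
self-loop discarded, parallel edges collapsed; a single-node graph has
`L' = 0`), computed with `scipy.sparse.csgraph` BFS. A second, independent
brute-force implementation of the same reading backs the tests. EI is a
baseline only; conclusions should not lean on it.

**Rounding.** Scores are computed and stored at full precision. A
presentation helper rounds half-away-from-zero to 2 decimals to match how
printed score tables are formatted; rounded values never feed back into
ranking or monotonicity.

## Percolation protocol

Ranking is *static*: edges are scored once on the intact graph, ordered by
descending score with canonical-key tie-break (an optional seeded-shuffle
tie policy exists for sensitivity analysis, and is never used in
validation), and removed one at a time. After each removal the largest
connected component fraction `ξ_l` is recorded; `R` is the mean of
`ξ_1..ξ_E` and the degradation curve prepends the intact point `(0, ξ_0)`.
The curve is computed backwards with a union-find (add edges in reverse
order), which makes a full curve near-linear in `E` and is verified in the
tests against direct remove-and-recount simulation. The x-axis of the
curve is the fraction of *edges* removed.

Monotonicity groups edges by score equality at an absolute tolerance of
1e-9 on the full-precision values: the statistic describes the ranking the
method actually forms, and grouping on rounded presentation values would
manufacture ties.

## Synthetic networks

The three generator families are the classical ensembles, via `networkx`
with explicit seeds (same seed + same parameters ⇒ identical graph):

* ER `G(n, p)` — every pair an edge independently with probability `p`;
* BA — growth from `m` isolated seed nodes with preferential attachment,
  `E = m(n−m)` exactly (the convention that reproduces the edge count
  `3 × 19 997 = 59 991` quoted for a mean-degree-6, 20 000-node network);
* WS — ring lattice with `k` even neighbours, each lattice edge rewired
  with probability `p`, `E = nk/2` exactly.

These emulate degree heterogeneity (BA), clustering and short paths (WS)
and homogeneous randomness (ER); they do *not* emulate community
structure, degree–degree correlations of real data, or spatial embedding,
so percolation results on them show the framework's correctness, not how
any index performs on a real connectome or interactome.

Topology summaries report the average *local* clustering coefficient
(nodes of degree < 2 contribute 0) — `transitivity` is exposed separately —
and Pearson degree assortativity over edge endpoints, reported as
undefined (`None`) on regular graphs where the degree variance is zero.

Validation runs use `n ≤ 500` (indices at `n ≤ 200` for the motif-heavy
EI) so a full multi-method, multi-seed evaluation completes at desk scale;
the generators themselves take arbitrary `n`.

## Numerical and degenerate-input choices

* Disconnected inputs are accepted everywhere; percolation inevitably
  creates them.
* `evaluate_method` reports `M = None` on single-edge graphs, where the
  monotonicity denominator `E(E−1)` vanishes.
* Betweenness requires `N ≥ 2`; summaries require `N ≥ 2, E ≥ 1`.
* Edge-list loading collapses duplicate and reversed-duplicate lines by
  default (`dedupe=False` turns collapsing into an error) and always
  rejects self-loops.

## Known limitations

* The GLHC mixing weights balance a pair-normalized global term of
  magnitude `O(diameter/N)` against local Jaccard terms of magnitude
  `O(1)`. At the 13-node illustration scale the two signals are
  commensurate and the hybrid strictly improves on both parents; as `N`
  grows the local terms increasingly dominate the composite, and on
  500-node synthetic families the hybrid's robustness tracks the local
  indices rather than betweenness (it remains no worse than SN, but pure
  betweenness can dismantle e.g. rewired ring lattices faster). Users
  targeting larger graphs should consider rescaling `w_eb` accordingly.
* Exact clique enumeration (BN) and per-edge contraction (EI) do not scale
  past a few thousand edges.
* One published score table prints two cells for automorphically
  equivalent edges with different values; no label-invariant
  implementation can reproduce both, and this package reproduces the
  internally consistent value (see the acceptance tests' comments).
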