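# Methods

## Model

`btseek` divides an undirected simple graph into non-overlapping modules
of two kinds.  A *cohesive* module keeps most of its members' edge
endpoints inside the group; a *sparse* module has few or no internal
edges but attaches densely, as a block, to at least one other module (a
*bridge*).  Both patterns are instances of one model: the partition is
an image of the adjacency matrix in which every block — diagonal or
off-diagonal — is idealized as completely full or completely empty.

With n nodes, m edges and global density ρ = 2m/n(n−1), the mismatch of
a partition against its best block image is

    E = Σ_{r≤s} min( (1−ρ)·l_rs , ρ·(L_rs − l_rs) )

where l_rs is the edge count of block (r, s) and L_rs its capacity
(n_r·n_s off the diagonal, n_k(n_k−1)/2 on it).  An edge inside a block
read as empty costs 1−ρ; a hole inside a block read as full costs ρ.
The density weighting keeps the two error types comparable at realistic
densities; an unweighted min(l, L−l) would degenerate to the constant m
whenever all blocks are under half full.  E ≥ 0, with equality exactly
for perfect block images, and E ≤ (1−ρ)·m (the all-empty image).

### A degeneracy worth knowing

E is subadditive over blocks: min(Σa, Σb) ≥ Σ min(a, b), so *refining a
partition never increases E*, and the all-singleton partition always
achieves E = 0 (every 1×1 or empty block is trivially perfect).  E alone
therefore cannot choose the number of modules.  Resolution control comes
from the search (below): groups classified cohesive or sparse are frozen
and groups below `min_split_size` are never split, so the candidate set
never approaches the singleton degeneracy.  Two corollaries are tested
explicitly: the optional greedy merge pass can never strictly decrease E
(it is provably inert and kept only for interface compatibility), and
within one growth path the E-argmin is the deepest recorded state up to
ties, with ties resolved toward the earliest (coarsest) state.

## Classification thresholds

A module k with n_k nodes, l_k internal edges and summed degree d_k is
classified by a triple (a1, a2, a3):

| symbol | statistic | meaning | default |
|---|---|---|---|
| a1 | f_in(k) = 2·l_k / d_k | lower limit of a cohesive module's internal stub fraction (dimensionless, [0,1]) | 0.7 |
| a2 | ā_int(k) = 2·l_k / n_k | upper limit of a sparse module's mean internal degree (edges/node) | 1.5 |
| a3 | b(r,s) = l_rs / min(n_r, n_s) | lower limit of bridge density (edges per node on the smaller side) | 1 |

Cohesive iff f_in ≥ a1; otherwise sparse iff ā_int ≤ a2 **and** some
bridge with b ≥ a3 exists; otherwise *ambiguous* — an explicit third
label, because ambiguity is what licenses further splitting.  Singleton
modules have all densities defined as 0, so they can only be sparse (if
bridged) or ambiguous.  Six preset triples are provided — (0.7, 1.5, 1)
(classical, the recommended first choice), (0.5, 1.3, 1), (0.5, 1.7, 1),
(0.85, 1.3, 1), (0.8, 1.4, 1), (0.5, 1.5, 1) — and all three values
remain fully configurable so alternative threshold semantics can be
swapped in behind the same interface.  The plain internal link density
d_in = 2·l_k/n_k(n_k−1) is also reported for every module.  Note that
a1 bounds a fraction while a2 bounds a per-node degree: a value like
1.5 is only meaningful for the latter.

For bipartite-style networks (two node classes, e.g. actors × events)
the recommended protocol fixes a1 and a2 at their classical values and
sweeps a3 over a range (default [0.5, 1.5] in steps of 0.05); the
E-vs-a3 profile is exposed as a table (`a3_profile`) and the lowest-E
division wins, as with multiple preset triples.

## Search

The search grows a binary tree of group splits:

1. **Root rule.** The root group (all nodes) is split unconditionally
   if it has at least `min_split_size` nodes.  (The whole network as one
   module always has f_in = 1, so a purely label-driven rule could never
   start; the root rule replaces that degenerate first decision.)
2. **Growth rule.** Recompute the full-partition statistics after every
   split; any leaf labeled *ambiguous* with ≥ `min_split_size` nodes and
   depth < `max_depth` is split next (first such leaf in creation
   order).  Cohesive and sparse leaves are frozen.  The depth cap
   (default ⌈log₂ n⌉ + 5) guarantees termination.
3. **Split operator.** For each of `n_restarts` (default 8) seeded
   random balanced starts, two hill climbs run on the group's adjacency
   sub-matrix with the Kernighan–Lin move set — single-node moves and
   cross-side pair swaps, i.e. simultaneous row/column transpositions of
   the matrix: a *cohesive-mode* climb minimizing the cut and a
   *sparse-mode* climb maximizing it.  Each converged bisection is then
   refined by a hill climb directly on the *local* block-image error of
   the three blocks the bisection induces (same move set, global ρ).
   Over all restarts and both modes the bisection with the lowest local
   error wins; ties break toward the lexicographically smallest first
   half.  The cut climbs matter as structured initializers: used alone
   they mislead the division (a maximum cut prefers slicing a cohesive
   module in half to peeling it off), while the local-error refinement
   alone from random starts converges to the same optima more slowly.
4. **Selection.** Every leaf-set state reached during growth is recorded
   as a candidate partition (a flag restricts recording to the final
   state instead).  One tree is grown per threshold triple (or per a3 of
   a sweep); every candidate of every tree is scored with the global E,
   and the minimum wins.  The winning partition is classified under its
   own triple and returned with its labels, bridges, thresholds and E.
   The number of modules is an output of this minimization, never an
   input.

Determinism: all randomness flows from one seed through a spawning seed
sequence (per triple → per split → per restart).  Identical seeds give
bit-identical results; restart seeds are spawned per restart index, so
the restart set for k restarts is a prefix of that for k+1 and the
chosen split's local error is monotone in the restart count.

## Benchmark generator

The default specification plants three modules of 16, 32 and 24 nodes
with per-node degrees fixed at 16, 8 and 16.  Block totals follow from
integer per-node quotas: every module-1 node sends 12 edges to module 2
and 4 to module 3 (block totals 192 and 64); every module-2 node sends
6 to module 1 and 2 to module 3 (64); module 3 absorbs the rest
internally (128 internal edges, mean internal degree 10.67).  Totals:
72 nodes, 448 edges; modules 1 and 2 are exactly sparse (zero internal
edges) and module 3 moderately cohesive (f_in = 2/3).

Realization: per block, per-node stub quotas (integer part to everyone,
remainder +1s to uniformly chosen nodes) are realized by a Gale–Ryser
greedy construction (off-diagonal blocks) or Havel–Hakimi (diagonal),
then randomized by seeded degree-preserving double-edge swaps (4 swaps
attempted per edge).  Block edge counts and all node degrees are exact
for *every* seed; only the wiring within blocks varies.  "Average
degree" in the design is strengthened to exact per-node degree — the
quota arithmetic supports it exactly and it makes every count-level
observable deterministic.

What the generator does *not* emulate: degree heterogeneity inside
modules, overlapping membership, weights, and the size/degree power
laws of real interaction networks.  Tests passing on this benchmark
show that the search recovers planted block structure at moderate
density contrast; they do not certify behaviour on heavy-tailed or
very large real networks.

## Scores

* **E** — as above; computed exactly from the block statistics.
* **NMI** — 2·I(P;Q)/(H(P)+H(Q)) from the node-count confusion matrix
  (arithmetic normalization).  Conventions for degenerate inputs: both
  partitions trivial (single module) → 1; exactly one trivial → 0.
  Backed by scikit-learn's implementation, which matches these
  conventions; an independent hand computation is the test oracle.
* **Q (modularity)** — Σ_k [l_k/m − (d_k/2m)²].  Cross-checked against
  networkx in tests.  The planted benchmark truth scores Q = −0.0612:
  sparse structure sits below the degree-model expectation, which is
  the quantitative reason cohesive-only detectors cannot find it.

The comparison protocol mirrors the cohesive-only baseline: a CNM-style
greedy modularity agglomeration (merge the connected pair with maximal
ΔQ = l_rs/m − d_r·d_s/2m², smallest-label tie-break, stop at the first
non-positive gain) and a 2×3 overlap table of its small/large modules
(strictly below / at least `size_cutoff` nodes, default 10) against the
sparse/cohesive/ambiguous labeling.

## Numerical choices and edge cases

* Strict-improvement hill climbs with a 1e-9 move threshold; E
  comparisons use 1e-12 for tie detection.
* Density ρ is defined as 0 for n < 2; zero-edge blocks contribute 0 to
  E by construction.
* Pearson-correlation networks threshold the *signed* coefficient
  (strictly greater-than); zero-variance genes join no edges.
* Top-k preference networks use the union rule: one-sided nomination
  suffices for an edge, so n·k directed choices yield between ⌈nk/2⌉
  and nk edges.
* Partition module ids are canonicalized to 1..K by first appearance in
  sorted node-label order, making file output independent of set
  iteration order across processes.
* Edge lists: duplicate records and self-loops are dropped and counted;
  weight columns are ignored with a warning; Pajek arcs are symmetrized;
  isolated nodes are kept unless dropping is requested.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated
inputs: the 72-node benchmark (20 seeds for the recovery medians),
structured fixtures of 6–10 nodes with exhaustive oracles (all 2^B
block images; all set partitions up to Bell(8) = 4140; all bipartitions
of 8-node groups), and random graphs of ≤ 30 nodes for property tests.
These sizes keep every oracle exact and the whole suite under a minute;
the search itself handles networks of a few thousand nodes in seconds
per tree.

## Known limitations

* The search is heuristic: no global E optimality is guaranteed or
  claimed (and on the benchmark the E-optimal *bisection* provably
  mixes planted modules, so even a perfect bisection optimizer would
  not recover the planted division exactly; median NMI ≈ 0.6 over seeds
  is the method's operating point there).
* Weighted, directed and overlapping structures are out of scope;
  weights in input files are ignored with a warning.
* Bipartite node classes are carried as annotation only; the a3 sweep
  is the intended treatment, not a two-mode model.
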