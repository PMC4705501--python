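# Methods

## The model

A protein–protein interaction (PPI) network is a simple undirected graph
whose nodes are proteins and whose edges are physical interactions.
Functional modules are groups of proteins that are densely interconnected
internally and sparsely connected to the rest of the network.  This package
detects disjoint functional modules by maximizing the *density modularity*
of the partition,

    D = Σ_i [ l_i² / (n_i² L)  −  d_i⁴ / (n_i² L³) ] ,

where, for module *i*, `l_i` is the number of intra-module edges, `n_i` the
number of nodes, `d_i` the sum of node degrees, and `L` the total number of
edges in the network.  The first term rewards internal edge density
normalized by module size; the second penalizes modules by aggregate
degree.  Density modularity was proposed as an alternative to the
Newman–Girvan modularity Q, whose global normalization suffers a resolution
limit that hides small modules.

**A property worth knowing.** On large networks the degree term, scaled by
1/L³, is negligible and D is governed by the density term.  On very small
graphs (L of order 10) the degree penalty dominates and the trivial
all-singletons partition can outscore any meaningful grouping; D is
therefore treated strictly as a *relative* criterion among the candidate
partitions the optimizer actually visits (see "Snapshot protocol" below),
never as a quantity with an interpretable absolute scale.  The claim
sometimes attached to this score, that it ranges over [0, 1], does not hold
for the formula as written and is not enforced.

## Closely associated degree and the node-move rule

Move decisions use the increment in (the dominant part of) D obtained by
merging a node, viewed as a singleton, into a module with statistics
(l₂, n₂), through e connecting edges:

    R(l₂, n₂, e) = (l₂ + e)² / (1 + n₂)²  −  l₂² / n₂² .

- **Internal score R_in**: the node against its host module, whose
  statistics *exclude* the node itself (otherwise the node's edges would be
  double-counted).  A node that is already a singleton module scores 0.
- **External score R_out**: the maximum of R over every other module
  containing at least one neighbor of the node, together with the arg-max
  module.  If no such module exists the node cannot move.

A node relocates exactly when R_in < R_out (strict).  On a tie the node
stays, which avoids oscillation.  Ties among external candidates resolve
to the smallest module id, for reproducibility.

The 1/L factor and the d⁴ degree bracket are omitted from these *decision*
scores: the factor is constant and the bracket is negligible for a
single-node move on networks of realistic size.  Full D is used only to
score and rank whole partitions.

Two functional forms of R_in are provided.  The default (`consistent`)
form above uses the same expression as R_out, so the comparison is
like-for-like; an accepted move then strictly increases the surrogate
objective Φ = Σ_i l_i²/n_i², which guarantees sweep termination because Φ
takes finitely many values on a finite graph.  The alternative
(`eq5_as_printed`, CLI flag `--eq5-as-printed`) reproduces a published
simplification of the internal score, (e² + 2 l₂ e)/(1 + n₂)², which drops
the −l₂²/n₂² term and is retained for fidelity experiments; move
acceptance is not provably monotone under it, which is why stabilization
carries a `max_sweeps` safety cap (default 1000).

## The algorithm

1. **Initialize** every protein as its own module.
2. **Sweep**: visit all nodes in a seeded random order; apply the move rule
   to each node, recomputing scores live so each decision reflects every
   earlier accepted move.
3. **Stabilize**: repeat sweeps until one pass accepts no move, then record
   the density modularity D of the partition as a snapshot.
4. **Merge**: score every pair of modules joined by at least one edge with
   the proportional merge gain
   (l₁+l₂+e₁₂)²/(n₁+n₂)² − l₁²/n₁² − l₂²/n₂², apply the best merge
   (maximum increment or minimum reduction), and return to step 2 so nodes
   can escape a bad merge — this is what removes the "module barrier" of
   purely agglomerative or divisive methods.
5. When no edge-connected pair remains, return the recorded snapshot with
   the largest D.
6. **Filter**: report modules with at least `min_module_size` proteins
   (default 3, matching the reference-complex convention), labelled
   `m1, m2, …` in decreasing size order.

Pairs of modules with no connecting edge are never merge candidates:
merging disconnected groups has no biological reading, its proportional
gain (−2 l₁ l₂ cross terms) is never maximal on connected structures, and
skipping them reduces the pair scan to the inter-module edge list.

**Snapshot protocol.** D is recorded only at stabilized states, not
mid-sweep and not at the trivial initial state; the merge loop runs to
exhaustion and max-D snapshot selection performs the model selection.
Selection compares unfiltered partitions; the size filter is applied to
the winner only.

**Randomness and restarts.** The only stochastic ingredient is the
per-sweep node visiting order.  The multi-restart protocol (default 20
restarts, matching the published experimental setup) repeats the full run
with seeds `seed, seed+1, …` and keeps the restart with the greatest best
D, so one integer reproduces the entire experiment bit-for-bit.

## Partition state

Per-module statistics (l, n, d), member sets and inter-module edge counts
e_{ij} are maintained incrementally under single-node moves and pairwise
merges, making each move decision O(degree).  A from-scratch audit
(`Partition.check_consistency`) recomputes every cache and is exercised by
property tests over random move/merge sequences.  All decision scores are
ratios of small integers evaluated in double precision and compared with
strict inequalities — no epsilon — so genuine ties behave as ties.
Networks with L = 0 are rejected rather than scored.

## Evaluation statistics

Predictions are compared to reference complexes through the matching
matrix T, with t(i,j) the protein overlap of reference module i and
predicted module j:

- sensitivity  Sn = Σ_i max_j t(i,j) / Σ_i n(i),
- positive predictive value  PPV = Σ_j max_i t(i,j) / Σ_ij t(i,j)
  (defined as 0 for an all-zero T),
- accuracy  Acc = √(Sn · PPV).

Acc is the geometric mean, the standard in complex-prediction evaluation;
the published benchmark rows this package reproduces (Sn 0.508 / PPV 0.660
→ Acc 0.579; Sn 0.534 / PPV 0.670 → Acc 0.598) are consistent only with
the square root, so a stray description of Acc as a "harmonic mean" in the
surrounding literature is treated as a misnomer.  Reference complexes may
overlap; a protein in two references counts in both rows.  Proteins in
predicted modules that appear in no reference contribute nothing to any
t(i,j), per the literal PPV definition.

A predicted module P "matches" a reference R when the neighborhood
affinity ω(P,R) = |P∩R|²/(|P||R|) reaches a threshold, default 0.2 — the
convention of this literature; the matched count is the number of
predicted modules matching at least one reference.

**Enrichment.** The significance of a module of C proteins, k of which
share a function annotated to F of the N genome proteins, is the
hypergeometric tail  p = 1 − Σ_{i<k} C(F,i)C(N−F,C−i)/C(N,C).  It is
evaluated as the algebraically identical upper-tail sum in exact integer
arithmetic (`math.comb` with a single final rounding to double): the
literal complement cancels catastrophically for the p ≈ 1e−30…1e−60
values typical of well-enriched modules, and even a log-gamma formulation
carries only ~1e−11 relative accuracy at genome scale.  Each module is
annotated with its minimum-p term (ties to the lexicographically smaller
term), the cluster frequency k/C, and a significance flag at p < 0.01.
Raw p-values are reported with no multiple-testing correction, matching
the reporting convention of the benchmark literature this package mirrors;
users needing corrected values can apply one to the returned table.

## Synthetic benchmark generator

`adm.synthetic.generate` draws planted-partition networks: every
within-module protein pair receives an edge with probability `p_in`
(default 0.9) and every cross-module pair with probability `p_out`
(default 0.05), the well-separated regime the recovery guarantees are
stated for.  Node identifiers are assigned through a seeded permutation so
that an ID encodes nothing about membership, and isolated proteins from
sparse draws are kept (they become filtered singletons, as in real
preprocessing).  The model is deliberately plain Bernoulli rather than a
degree-corrected stochastic block model: the method's formulas are
unweighted and its decision scores drop the degree terms, so degree
correction would add no test power — it also means the generator does not
emulate the heavy-tailed degree distributions, hub proteins or assay
biases of real interactome data, and recovery on these benchmarks bounds
algorithmic correctness, not performance on real screens.

## Problem sizes used in the test and acceptance suites

Arithmetic identities are checked exhaustively on graphs of up to 7–10
nodes (against enumeration of all set partitions where needed) and the
hypergeometric tail against full enumeration for genomes up to N = 12 plus
a survival-function identity at N = 6000.  Structure recovery is measured
on 4-module × 8-node planted networks over 50 generator seeds with the
full 20-restart protocol, a scale at which the whole suite runs in
seconds on one core while still exercising every code path of the
optimizer.

## Known limitations

- Output modules are disjoint; overlapping complexes are represented only
  through the reference side of the matching matrix.
- Edge weights and interaction confidences are ignored by design; any
  thresholding must happen upstream.
- GO semantic-similarity scoring and ancestor-term propagation are out of
  scope; annotation tables are taken as given.
- On very small graphs the max-D selection among snapshots inherits the
  degree-penalty artifact described above; the optimizer's trajectory never
  contains the trivial partitions the artifact favors, but D values across
  differently-sized networks are not comparable.
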