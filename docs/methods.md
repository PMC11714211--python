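# Methods

This note documents the models implemented in `netscreen`, the parameter
conventions, the numerical choices, what the synthetic fixtures emulate,
and the limitations a user should know about.

## Graph substrate

The interactome is an undirected, unweighted graph over gene symbols.
Self-loops are dropped and duplicate edges collapsed at load time (counts
reported).  Protein–protein interactions are treated as symmetric even
though propagation formulas are often typeset with out-degrees; on an
undirected graph the column-normalized adjacency used by both walks is the
natural specialization.  All array-level computation runs on a cached CSR
adjacency in sorted node order, so results never depend on input order.

Hop distances use unweighted Dijkstra with multi-source minimization
(`scipy.sparse.csgraph`).  Unreachable distances are `inf`; a target set
with any member unable to reach the other set raises an error instead of
silently dropping terms — proximity is defined within one connected
interactome, and a disconnected input is a data problem the user should
see.

## Degree-matched permutation nulls

Network statistics on heavy-tailed graphs are confounded by hubs, so null
gene sets preserve the degree profile of the observed set.  Bins are built
by ascending degree, merging adjacent degrees until each bin holds at
least `min_bin_size` nodes (default 100; a trailing undersized bin is
absorbed into its predecessor).  Each template gene contributes one draw
from its bin, without replacement within a permutation and independently
across permutations.  A bin too small to supply the required distinct
draws raises an error suggesting coarser binning rather than quietly
sampling with replacement.

Empirical P values are plain counting fractions with no pseudocount
(`#{...}/n_perm`), so P = 0 is reportable and means "below the resolution
of n_perm permutations"; the smallest attainable nonzero value is
1/n_perm.

## Module identification

Personalized propagation is the fixed point of
p = d·W·p + (1−d)·v with damping d = 0.85 (the standard PageRank default),
W the column-stochastic adjacency, and v the personalization vector — all
restart mass on the seed gene(s).  The uniform-teleport variant is
recovered by a uniform v.  Convergence: L1 change < 1e-10 (default),
max 1000 iterations, with a warning flag on non-convergence.  The fixed
point is unique for d < 1, so initialization is irrelevant.  The module is
the top-k genes by score (k = 200 by default, matching the convention of
taking a fixed-size high-influence neighborhood); boundary ties break
lexicographically so module membership is deterministic.  The seed gene
itself is excluded from membership by default — the module is the seed's
*associated* genes — and retained in the score map; a flag reverses this.

Module evaluation: Mann–Whitney AUC of the score ranking against a
benchmark gene set (ties averaged), and the LCC localization test — the
observed largest connected component of the induced subgraph against
degree-matched random sets of the same size, with
P = #{LCC_random ≥ LCC_obs}/n_perm.  Uniform (non-degree-preserving)
sampling is available as a configuration alternative; degree-matched is
the default because hub-rich sets connect easily by chance.

## Closest proximity

The closest measure averages, over both sets symmetrically, each member's
hop distance to the nearest member of the other set.  It is zero iff the
restricted sets are equal.  The permutation null redraws degree-matched
counterparts of *both* sets by default, following the screen's definition;
a targets-only mode holds the module fixed.  These two nulls answer
slightly different questions: the both-sets null scores the pair against
generic degree-matched pairs, while the targets-only null conditions on
the actual module.  Empirically (see the calibration tests) the
targets-only Z is standard normal under random target sets, whereas the
both-sets Z is overdispersed (sd ≈ 1.9 on the test fixture) because
distances to one concentrated module vary more across random target sets
than distances between two scattered random sets.  This is a property of
the null design, not an implementation artifact; the screening default
follows the both-sets definition, and calibration claims are made under
the targets-only mode.

The empirical P counts null distances strictly below the observed one,
`#{d_random < d}/n_perm` — small P means the observed distance undercuts
nearly all null draws, i.e. the proximal tail.  Because hop distances are
discrete, ties between null draws and the observed value are common; a
`less_equal` option counts the closed tail instead.  The candidate rule is
Z_NP < −3 **and** P < 0.05, both strict.

## Functional similarity

Wang's term similarity scores each term by its ancestor DAG: S(t) = 1 at
the term, and each ancestor gets the maximum over its in-DAG children of
the child's S-value times the edge weight (is_a 0.8, part_of 0.6 — Wang's
published constants, configurable).  Two terms are compared by the summed
S-values of their shared ancestors (self included) over the sum of all
S-values.  The score is symmetric, in [0, 1], and 1 at identity; within a
namespace it is always positive (the root is shared); cross-namespace
comparison is refused.

Gene-pair similarity is the best-match average (BMA) of the term-pair
matrix: mean of row maxima and column maxima, averaged.  Set-vs-set
similarity applies BMA a second time over the gene-pair matrix, mirroring
gene-cluster semantics of the standard GO-similarity tooling.  A gene with
no annotation in a namespace is *missing*, not zero — zero-imputation
would conflate absent curation with dissimilarity — and FS is the mean
over the namespaces available on both sides.

The FS null redraws random gene lists size-matched to the drug's annotated
target count, uniformly from the annotated universe, holding the module
fixed.  Annotation coverage, not network degree, is the confounder for a
semantic statistic, which is why uniform-annotated is the default; a
degree-matched alternative is provided.  Candidate rule: FS > 0.6 and
P < 0.05.

## RWR diffusion correlation

The walk p_{t+1} = (1−γ)W p_t + γ p_0 restarts with probability γ = 0.75
(the convention of diffusion-based repurposing packages) to a p_0 uniform
over the seed nodes.  A convergence threshold below double-precision
resolution cannot be met by an L1 test, so the iteration additionally
stops when the vector stagnates bit-for-bit — the numerical fixed point —
with defaults tol = 1e-12, max_iter = 10⁴; for γ = 0.75 convergence takes
roughly 20 iterations.  Isolated nodes receive a self-loop column so W
stays stochastic.  The module-side vector is seeded by the whole module by
default (a seed-gene-only mode exists); the drug-side vector by the drug's
targets.  Pearson correlation is computed over all nodes (an exclusion
mask is available for sensitivity analyses).  The null reruns the
diffusion from degree-matched random target sets with the module vector
fixed — it is the screen's reference, so only the drug side is randomized.
Candidate rule: Z_RWR > 3 and P < 0.05.

## Tissue specificity

Z_{i,t} = (E(i,t) − E(i))/δ_i on a genes × tissues matrix of per-tissue
mean expression.  δ_i is the sample standard deviation (n−1) by default;
the population form (under which a gene's Z values sum to zero across
tissues) is available via `ddof=0`.  The statistic is location/scale
invariant per gene, so the log/linear choice of the input matrix does not
change the calls; the choice is recorded as metadata.  Zero-variance genes
get NaN, never 0 or ±inf.  The specificity call is strict: Z > 2.5 by
default.

## Screening orchestration

Per-drug permutation seeds are derived by SHA-256 from
(master seed, drug id, method), so reports are reproducible bit-for-bit
and the null of one drug is unaffected by adding or removing others.
Targets absent from the interactome are dropped with a logged count; a
drug with no mapped target, or no annotated overlap for FS, is recorded
with a skip reason and never aborts the screen.  The final rule is the
three-way AND; all pairwise intersections are exposed in the report
because promoting two-method candidates is a judgment call, not an
algorithm.

## Synthetic study system

The fixture generator stands in for the real inputs with planted truth:

* **Interactome** — Barabási–Albert preferential attachment (n = 1000,
  m = 3 by default; Erdős–Rényi available for calibration suites).  A
  planted module of 25 genes has internal edges added until its induced
  density reaches 55× the background density — the enrichment order that
  genome-scale disease modules show (a ~200-gene module with a few
  thousand internal edges over a ~18k-node, ~485k-edge interactome sits
  near 55×).  Because a propagation-derived module is the seed's immediate
  network vicinity, the seed gene is chosen as the most module-internal
  planted member and wired to 90% of the others.
* **Drug library** — 3 planted drugs with all 4 targets inside the module,
  47 decoys with none; off-module targets are degree-matched to module
  members, so decoys are degree-fair negatives.  Truth label: overlap ≥ 0.5.
* **Ontology** — three namespace trees (depth 4, branching 3, 20% part_of
  edges); planted-module genes draw their annotations from one designated
  subtree, background genes from the whole namespace.
* **Expression** — log-normal background (σ = 0.25) over 300 genes × 30
  tissues with an 8-fold boost for 20 planted genes in the designated
  tissue, the regime of a strongly tissue-restricted transcript.

What passing on fixtures does *not* show: real interactomes carry study
bias and false edges, real annotation is sparse and uneven across genes,
real drugs have off-target promiscuity and unmapped targets, and real
effect sizes are far smaller than planted ones.  The fixtures validate
the statistics' correctness and calibration, not field performance.

## Problem sizes used in validation

The validation suite runs oracle comparisons on graphs up to 200 nodes
(exact linear solves and Floyd–Warshall), null calibration with 500
replicate screens on a 2000-node fixture at 200 permutations, and the
end-to-end planted-recovery screen on the 1000-node system at 200
permutations — sizes at which permutation distributions are well resolved
while a full run of the suite stays in the minutes range on a single CPU.
Production screens on genome-scale interactomes use the same code paths;
only `n_perm = 1000` and the input sizes change.

## Known limitations

* Edge confidence weights, directed/signed interactions, and alternative
  proximity kernels (shortest, centre, separation) are out of scope.
* Information-content-based GO similarities (Resnik/Lin) are not
  implemented; Wang/BMA only.
* The FS screen's cost grows with the gene-pair similarity matrix; results
  are cached per (namespace, gene pair) within a session.
* The affinity filter on drug libraries is a single threshold (default 10,
  in µM units by convention); no unit conversion is attempted.
* P = 0 from n permutations should be read as P < 1/n, not as literal zero.
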