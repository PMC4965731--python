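# Methods

## Scope and data model

`nettop` operates on simple undirected graphs over string vertex
identifiers. Readers (edge list, SIF, GraphML) drop self-loops with a
logged count and collapse parallel edges keeping the maximum weight; every
topological measure assumes a simple graph, and the collapse rule is
conservative for co-expression-style edge strengths. Vertex order is
first-seen order, fixed once per input, and indexes every matrix and table
the package builds. Signature labels are exact string matches after
whitespace trimming — no identifier-alias resolution is attempted, so
callers must bring the network and the gene list into one namespace.

## The thirteen measures

Geodesics always count edges (unit lengths), even on weighted networks;
weights enter only the random-walk transition matrix and the
structural-hole tie proportions. Conventions, chosen so every measure is
well-defined on disconnected input:

- **Degree, coreness, clustering coefficient.** Coreness is the largest k
  surviving k-core peeling (bucket peeling, O(V+E)). Clustering of a
  vertex with degree < 2 is 0.
- **Betweenness** is the sum over *ordered* pairs (s, t) of
  σ_st(v)/σ_st, so each unordered pair counts twice; a `normalized` flag
  halves it (default off). Computed by Brandes dependency accumulation and
  tested against exhaustive geodesic enumeration.
- **Closeness** is the harmonic form Σ 1/σ_vt with unreachable terms
  contributing 0 (not 1/Σσ), which keeps disconnected networks meaningful
  without extracting the largest component.
- **Proximity prestige** is (I_v/(|V|−1)) / (Σσ_vt/I_v) with I_v the
  number of vertices that can reach v; 0 when I_v = 0.
- **Barycenter score** is the reciprocal of the total geodesic distance to
  the rest of the vertex's component (0 for isolated vertices). The measure
  is only loosely characterized in the literature we follow; the
  reciprocal-total-distance reading was adopted as the definition here.
- **Eigenvector centrality** is the Perron vector of A at unit Euclidean
  norm, computed by power iteration on A + I (same leading eigenvector,
  immune to the ±λ oscillation on bipartite graphs); convergence is judged
  by the residual ‖Ax − λx‖∞ ≤ tol (default 1e-9, max 10000 iterations,
  error on failure). Requires at least one edge.
- **Katz index** evaluates ((I − αAᵀ)⁻¹ − I)·1 by a direct sparse solve.
  α defaults to 0.5/λ_max (configurable fraction); α ≥ 1/λ_max is rejected
  because the underlying walk series diverges.
- **Subgraph centrality** is diag(e^A) via the symmetric
  eigendecomposition Σ_j u_j(v)² e^{λ_j}.
- **Within-module z-score** standardizes the within-module degree with the
  *population* standard deviation; z = 0 when a module's within-degrees are
  constant. Modules come from deterministic fast-greedy modularity
  maximization (python-igraph) by default, or connected components; the
  module definition is genuinely open in this problem and the choice is
  configurable.
- **k-step Markov** is P⁰·Tᵏ with T the row-normalized (weighted)
  adjacency, degree-0 vertices absorbing so total probability is conserved,
  P⁰ uniform over the start set (default: all vertices), k = 6 by default.
- **Structural holes** is Burt's aggregate constraint
  C_i = Σ_{j∈N(i)} (p_ij + Σ_{q≠i,j} p_iq p_qj)² with proportional tie
  strengths p_ij = w_ij/Σ_q w_iq; the raw constraint is reported, not
  1 − C_i, so *low* values mean brokerage. Isolated vertices score 0.

`compute_all` shares one BFS sweep across the four shortest-path measures
and one eigendecomposition between subgraph centrality and the Katz α
bound; results are identical to the standalone functions and deterministic
given the network and configuration.

## Labeling and SMOTE

A vertex is positive iff its identifier is in the signature set; zero
matches is an error (classification is impossible), full matches only a
warning. SMOTE brings the minority class up to *exact* balance with the
majority: each synthetic row is x + u·(x_nn − x) with one uniform
u ~ U[0,1) per row (so the point stays on the parent segment) and x_nn one
of the k = 5 nearest minority neighbors by Euclidean distance on unscaled
features (a standardize-before-kNN flag exists, default off). The per-row
replicate count is the integer floor, topped up by seeded random minority
draws; k is clamped to minority−1 with a warning. Originals are preserved
verbatim and synthetic rows carry a `provenance` marker and a reserved
`syntheticNNNNN` id namespace.

## Classifiers

**Bagged decision trees (DTB).** `n_trees` = 100 (default) Gini trees,
each on an independent bootstrap replica of size N (scikit-learn
`BaggingClassifier`), unlimited depth, minimum leaf size 1. The ensemble
score of a vertex is the fraction of trees voting positive; confusion-based
metrics threshold that score at 0.5.

**RUSBoost.** Two-class SAMME-style boosting: each round keeps all N_min
minority rows and draws N_min majority rows *without replacement* with
probability proportional to the current boosting weights, fits a Gini tree
with the selected rows' normalized weights, computes the weighted error on
the full training set, and combines rounds by weighted vote (score in
[0, 1]). Boosting stops early if a round's weighted error reaches 0.5. On
balanced input no row is removed and the loop reduces to plain boosting.
The boosting variant is a design choice; the procedure we follow names the
undersampling scheme but not the boosting arithmetic. RUSBoost combined
with external SMOTE is refused with an explanatory error — the two sampling
schemes would fight each other.

## Metrics, ROC, cross-validation

ACC, PPV, SN, SP, F, Gm follow the standard confusion-matrix formulas;
any 0/0 ratio is reported as 0 and flagged as degenerate. The ROC curve
sweeps all unique scores; its trapezoid area equals the Mann–Whitney rank
statistic (also exposed separately, and asserted equal to 1e-12 in the
tests). Cross-validation is *stratified* k-fold (default k = 10) so the
rare positive class appears in every fold; backward elimination and SMOTE,
when enabled, see the training partition only, and the held-out fold is
scored untouched — no synthetic row can reach a test fold. Per metric the
summary is M ± 1.96·σ_M with σ_M the standard error of the fold values
(sample sd / √k).

## Importance and backward elimination

- **Gini importance** of a feature is the total node-size-weighted impurity
  decrease over every split of every tree, left unnormalized (no division
  by N or by the tree count): a single pure root split on 2n rows credits
  n. This matches the magnitude regime of reported per-feature Gini scores
  in the hundreds.
- **Accuracy importance** is the mean decrease in per-tree out-of-bag
  accuracy when the feature's column is permuted (10 permutations per tree,
  seeded); ensembles without bootstrap structure fall back to permutation
  on supplied data with a warning. "Accuracy" importance has no canonical
  definition in the source procedure; the permutation reading is our
  choice, and only the combination rule below is contract-tested.
- **Combined score** = √(accuracy × Gini), the geometric mean, which keeps
  either scale from dominating; negative inputs are rejected, and tabular
  output rounds to 2 decimals.
- **Backward elimination** greedily removes the feature whose removal
  maximizes mean cross-validated G-mean and stops when the best removal
  would *strictly reduce* the score; a removal that ties still proceeds,
  because a tie shows the feature carried no information (a zero-variance
  column, which can never change a split, is always eliminated). Candidate
  ties are broken by the lower combined score.

## Synthetic studies

`SyntheticSpec` generates the study conditions the pipeline assumes:
a connected preferential-attachment graph (complete seed on m vertices,
then m distinct degree-proportional targets per arriving vertex; edge count
C(m,2) + (n−m)·m), defaults n = 1000, m = 2, giving the heavy-tailed degree
structure of protein networks. Labels are planted by a latent score
Σ w_f·z_f + ε over standardized features (defaults: unit weights on degree
and structural holes, ε ~ N(0, 0.5)); the top ⌈0.04·n⌉ latent values are
the positives — top-quantile labeling keeps the positive count exact and
the tests non-flaky. Everything downstream is a pure function of the spec,
byte-for-byte reproducible.

What the generator does *not* emulate: co-expression value matrices,
pathway annotation structure, identifier noise, or assortativity patterns
of real interactomes. A further structural consequence worth knowing: in a
BA(m = 2) graph roughly half the vertices have degree exactly 2 and
constraint exactly 0.5, an exact feature atom whose latent value lies just
below the default labeling cutoff. Positives drawn from that atom are
selected purely by the noise term and are therefore undecidable from the
features; with the default weights (which also partially cancel, since
degree and constraint are negatively correlated) this caps the achievable
sensitivity well below 1 and makes per-fold G-means volatile when only ~4
positives land in each test fold. Passing tests on these fixtures show the
pipeline's mechanics (fold honesty, balance, determinism, metric
arithmetic) — they do not certify classification quality on real networks,
and conversely modest synthetic G-means reflect the generator's label
noise, not a defect of the classifiers.

## Numerical and degenerate-input conventions

Floating-point test comparisons are 1e-9 absolute unless a tighter bound
is stated (Katz vs dense solve 1e-10, trapezoid-vs-rank AUC 1e-12).
Feature tables round-trip through TSV at ≥ 12 significant digits. Seeds
are threaded explicitly through every stochastic step (bootstrap, SMOTE,
fold shuffling, permutation importance, generators); identical seeds give
identical artifacts. Degenerate cases — empty files, edgeless graphs for
eigenvector centrality, single-class training data, minority classes of
size < 2 for SMOTE — raise informative errors rather than returning
defaults.

## Known limitations

- Exact-match labeling only; no gene-identifier harmonization.
- No directed-graph semantics and no edge-length-weighted geodesics.
- Betweenness is exact (no sampling), so very large networks are costly.
- The backward-elimination path depends on the CV seed through fold
  assignment; survivors can differ between seeds on weak signals.
- Combined-score ranking inherits the known biases of impurity-based
  importance (preference for high-cardinality features, credit splitting
  among correlated features) — on networks, where most centralities
  correlate with degree, ranks of hub-driven features should be read as a
  group, not individually.
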