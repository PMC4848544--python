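# Methods

## Model

Given m samples with class labels and n features, a candidate feature
subset S is scored by building the **k-feature sample graph**: nodes are
samples, and an undirected edge joins i and j when either is among the
other's K nearest neighbors under Euclidean distance restricted to the
columns of S (binary adjacency, zero diagonal, OR-symmetrization). The
subset score is the Newman–Girvan modularity Q of this graph under the
partition induced by the class labels — communities are the classes, never
detected from the graph. Q is computed in two algebraically equivalent
forms (pairwise double sum with prefactor 1/2e, and per-community
l_c/e − (d_c/2e)²); their agreement to 1e−12 is a standing test invariant.
An edgeless graph has no defined Q and raises an error rather than
returning 0, since a silent 0 would corrupt the argmax in selection.

Selection (`kfsgfs_select`) is pure greedy forward search: the first
feature maximizes single-feature Q, each later step adds the feature
maximizing Q of the union, stopping at |S| = P. No removals or
backtracking. Candidates are scanned in ascending column index and the
argmax keeps the first maximizer, so traces are deterministic. Squared
per-feature difference matrices are accumulated incrementally in selection
order; this is floating-point-identical to recomputing the subset
distances from scratch in the same order (tested).

## Neighborhood conventions

On discretized or low-resolution data many pairs of samples are exactly
equidistant, and K-NN graphs built by different libraries then differ.
Three documented conventions are exposed on `build_ksg`/`score_subset`/
`kfsgfs_select`:

* `ties="expand"` (default): the neighborhood of i is every sample with
  distance ≤ the K-th smallest from i. No arbitrary tie-break is needed,
  the graph is equivariant under sample reordering even with ties, and
  edge sets are monotone in K. Neighborhoods can exceed K where ties occur.
* `ties="strict"`: exactly K neighbors; ties broken by ascending sample
  index (deterministic, but index-dependent on tie-heavy data).
* `count_self=True`: the sample itself occupies one of its K slots, i.e.
  K−1 true neighbors. This reproduces graphs built with KNN searchers that
  return the query point as its own first neighbor.

On the iris worked example the conventions genuinely matter: the published
two-feature Q values for the petal-length-anchored subsets are matched to
within 0.011 under `count_self` strict neighborhoods
(0.6208/0.5734/0.5403 vs 0.6057/0.5719/0.5430), while the published
greedy order {3 4 1 2} is obtained under the default tie-inclusive
neighborhoods (strict asc-index neighborhoods flip the first two picks to
{4 3 1 2} because petal width is tie-heavier than petal length). The
ordering Q₃₄ > Q₃₁ > Q₃₂ holds under every exposed convention. The default
is `ties="expand"` because it reproduces the worked example end-to-end and
needs no arbitrary rule.

K defaults to 2; useful values are small (roughly 2–11). Larger K blurs
local class structure; K ≥ m is invalid.

## Preprocessing

* `standardize`: per-feature zero mean, unit **population** variance
  (divide by m). Population form makes the 2-sample column [0, 2] map
  exactly to [−1, 1]. Zero-variance columns become all-zero with a warning
  (microarray matrices routinely contain constant probes; erroring would
  make such files unloadable).
* `discretize_nine_level`: level 0 for values within μ ± σ/2 (closed
  band), then four σ-wide intervals on each side mapping to ±1..±4,
  half-open away from the center, truncating beyond ±4. σ is the
  population standard deviation of the fitted data. The mapping is
  monotone in the raw value (property-tested). This is the discretizer
  used for all mutual-information estimates on continuous data.

## Conditional mutual information

`conditional_mi` is the maximum-likelihood ("plug-in") estimator on the
empirical contingency table with the 0·log 0 = 0 convention, base 2 by
default with a natural-log option. It is cross-checked in tests against a
brute-force loop over the full joint table and against an independent
library implementation of the unconditional case. Plug-in estimates are
biased upward by roughly (|X|−1)(|C|−1)/(2m ln 2); this matters when
comparing features with different alphabet sizes and is why the synthetic
benchmark judges "uninformative" by rank, not by absolute value. On
nine-level discretized iris the diagnostic ordering
RI(f₄,C;f₃) > RI(f₁,C;f₃) > RI(f₂,C;f₃) is robust to the base; the
absolute values (0.1136/0.0339/0.0128 bits) depend on the estimator and
discretizer, for which no external reference configuration is available.

## ENC / ENIC and the k-means objective

`expected_correct_count` implements the stochastic nearest-neighbor
selection rule of neighborhood components analysis: sample i picks
neighbor j with probability P_ij ∝ exp(−‖x_i−x_j‖²) (squared Euclidean by
default, plain optional), P_ii = 0, rows normalized. P_i sums P_ij over
same-class j; ENC = Σ P_i, ENIC = m − ENC exactly. Rows are max-shifted
before exponentiation so microarray-scale distances do not underflow.
`kmeans_objective` only *evaluates* J = Σ‖x_i − μ_a(i)‖² for a given
assignment — no Lloyd iterations, since J is used purely as a diagnostic
link: subsets with high Q have small within-class distances, hence small
J and large ENC. The package asserts this link empirically: across the
synthetic generator's features, single-feature Q and single-feature ENC
rank-correlate positively (Spearman ρ > 0 on 20 consecutive seeds).

## Synthetic data generator

`generate_synthetic` composes four archetypes, column order XOR pairs →
informative → redundant → noise:

* **XOR pair**: per sample a sign s ∈ {−1, +1}, drawn exactly balanced
  within each class; the partner feature carries s times the class parity,
  so the sign *product* encodes the class. Both features add a fine-scale
  class offset (0.08·class) and Gaussian jitter (`noise_sd`, default
  0.01). The exact within-class sign balance pins each feature's
  discretized marginal MI at the plug-in bias floor; the fine-scale offset
  is far below the nine-level bin width (~1σ of a feature of scale ~1), so
  it stays invisible to discretized MI while making nearest neighbors
  class-pure. This is the canonical structure a subset-level geometric
  criterion should find and a per-feature discretized-MI ranking cannot: a
  fully symmetric XOR with no fine-scale signal would be invisible to
  *every* single-feature criterion — including single-feature Q — making
  step 1 of any greedy forward search a coin flip, which is a real and
  documented limitation of forward search, not of the score.
* **Individually informative**: class-shifted Gaussians, adjacent class
  means 1.5σ apart (a solid but not trivial univariate effect).
* **Redundant**: an informative column plus `noise_sd` jitter.
* **Noise**: standard Gaussians independent of the class.

Defaults: 200 samples/class, 2 classes, 1 XOR pair, 2 informative,
1 redundant, 8 noise. What passing tests on this generator show: the
selector prefers jointly informative structure over marginal rankings
under clean, balanced, isotropic conditions. What they do not show:
robustness to class imbalance (modularity's resolution limit penalizes
small classes), heavy-tailed noise, correlated noise features, or
batch structure — none of which the generator emulates.

## Evaluation harness

`knn1_cross_val`: stratified k-fold (default 10) cross-validation of exact
1-NN (Euclidean, distance ties broken by lowest training index), repeated
over `runs` (default 10) re-randomized fold assignments seeded `seed + r`;
accuracy in percent, grand mean = mean of per-run means. When a class has
fewer members than folds, stratification is impossible and the split falls
back to plain K-fold with a warning (e.g. 32 samples over 3 classes).
Any classifier with the fit/predict contract can replace the built-in
1-NN; an RBF-SVM with C = 100 is the usual external reference
configuration. `paired_one_tailed_t` is the standard paired t-test with
alternative mean(a−b) > 0, df = n−1; zero-variance difference vectors are
rejected as degenerate rather than returning p ∈ {0, 1}.

## Problem sizes and numerical choices

All shipped computations run on desk-scale problems: iris (150×4), the
synthetic benchmark (400×10, 20 seeds), random graphs up to 30 nodes.
Graph construction is brute-force O(m²) per candidate — appropriate at
these sizes; approximate K-NN indexes are out of scope. Distances are
compared as squared Euclidean throughout (monotone in the metric, avoids
sqrt rounding in tie detection). Comparisons in the greedy argmax are
strict `>`, so the lowest-index candidate wins exact ties. CSVs are
written with `%.17g` and parsed with round-trip float precision so
load→write→load is exact.

## Known limitations

* Modularity's resolution limit: with very unbalanced classes the
  class-partition Q can prefer irrelevant features; no correction is
  applied.
* The greedy search cannot discover feature groups whose *every* proper
  subset is score-neutral (see the XOR discussion above).
* Plug-in CMI is biased on small samples and large alphabets; no
  Miller–Madow or shrinkage correction is implemented.
* The printed reference values this package is checked against depend on
  unstated neighbor/tie conventions of their original computation; the
  conventions are therefore explicit, user-visible options here.
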