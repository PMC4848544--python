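# kfsgfs

Feature subset selection for high-dimensional labeled data (e.g. microarray
gene expression) by **community modularity of k-feature sample graphs**.

Most filter-style feature selectors rank features one at a time, so they
miss feature groups that are discriminative *together* but useless alone
(the XOR situation), and mutual-information criteria additionally lose the
fine geometry of continuous data to discretization. `kfsgfs` scores a whole
candidate subset at once: build a K-nearest-neighbor graph over the
*samples* using only the candidate feature columns, partition the nodes by
their class labels, and measure how good that partition is as a community
structure.

## The score

For a binary, OR-symmetrized K-NN graph with adjacency `A`, `e` edges and
node degrees `d_i`, the Newman–Girvan modularity of a partition is

    Q = (1/2e) Σ_ij [ A_ij − d_i d_j / 2e ] δ(c_i, c_j)
      = Σ_c [ l_c / e − (d_c / 2e)² ]

where `l_c` and `d_c` are the within-community edge count and degree sum of
community `c`; both forms are implemented and agree to 1e−12. With the
class labels as the partition, a subset whose sample graph has high Q keeps
same-class samples densely interconnected and classes sparsely connected —
small within-class and large between-class distances *as a group*.

Selection is greedy forward search: start from the single feature with the
highest Q, then repeatedly add the feature `f` maximizing `Q(S ∪ {f})`
until `|S| = P`. Companion diagnostics include a plug-in conditional mutual
information `RI(f_i, C; f_j) = I(f_i; C | f_j)` (what `f_i` adds about the
class once `f_j` is known), a softmax expected-correct-count (ENC, as in
neighborhood components analysis) linking high Q to class-pure
neighborhoods, and a stratified 10×10-fold 1-NN evaluation harness with a
paired one-tailed t-test.

## Worked example: iris

```python
import kfsgfs as kf
from sklearn.datasets import load_iris

X, y = load_iris(return_X_y=True)
ds = kf.standardize(kf.LabeledDataset(values=X, labels=y,
                    feature_names=["f1", "f2", "f3", "f4"]))

trace = kf.kfsgfs_select(ds, P=4, K=2)
print(trace.selected_one_based)                 # [3, 4, 1, 2]
print([round(q, 4) for q in trace.q_values])    # [0.5458, 0.5994, 0.6241, 0.5955]
```

Petal length (feature 3) alone already separates the species best
(Q = 0.5458); adding petal width raises Q to 0.5994, and the two sepal
features add little. The same conclusion comes from the conditional-MI
diagnostic on nine-level discretized data — conditioned on petal length,
petal width still carries the most class information:

```python
dsd, _ = kf.discretize_nine_level(kf.LabeledDataset(values=X, labels=y,
          feature_names=["f1", "f2", "f3", "f4"]))
print({k: round(v, 4) for k, v in kf.ri_table(dsd, conditioning_feature=2).items()})
# {'f1': 0.0339, 'f2': 0.0128, 'f4': 0.1136}   (bits)
```

The same pipeline is available from the shell:

```sh
kfsgfs select --input iris.csv --label species --standardize --K 2 --P 4
# 3 4 1 2
```

Because K-NN graphs on tie-heavy data depend on how distance ties are
resolved, the graph builder exposes the convention explicitly
(`ties="expand"` admits every sample tied with the K-th distance, the
default; `ties="strict"` keeps exactly K with lowest-index tie-break;
`count_self=True` lets the sample itself occupy a neighbor slot, as some
KNN searchers do). See `docs/methods.md`.

## Why a subset score: the XOR benchmark

The synthetic generator (`kf.generate_synthetic`) builds datasets with an
XOR feature pair — the class is encoded in the *sign pattern* of the pair,
so each feature's discretized marginal is class-agnostic — plus pure-noise
features. Per-feature mutual information ranks the XOR features at the
bottom (≈ 0.000 bits vs ≈ 0.014 bits for noise at m = 400), yet the greedy
modularity search selects exactly the XOR pair first in 20/20 seeded runs,
because the pair's 2-D sample graph has near-perfect class communities
(joint MI ≈ 1.0 bit).

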