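# scinsight

Joint non-negative matrix factorization for single-cell gene expression
samples that come from **different biological conditions** — disease
phases, treatment arms, time points. Standard batch-correction tools
assume all between-sample differences are technical; when samples belong
to distinct biological groups, that assumption erases exactly the
signal of interest. `scinsight` instead decomposes every sample into
a part shared by all samples and a part shared only within its
condition, so cells can be clustered on condition-free identity
programs while condition effects are retained as interpretable gene
modules.

It is written for computational biologists integrating multi-sample
scRNA-seq studies: the library is a set of scikit-learn-style
estimators and functions, and a thin `scinsight` command-line tool
drives the same pipeline from a shell.

## Model

For sample ℓ (cells × genes matrix X_ℓ, m_ℓ cells, n genes) in
condition j_ℓ:

    X_ℓ = W_ℓ1 H_{j_ℓ} + W_ℓ2 V + E_ℓ,      all factors ≥ 0

* **V** (K × n): K *common gene modules*, shared by all samples — each
  row is a sparse non-negative combination of genes, read as a
  cell-identity program.
* **H_j** (K_j × n): *condition-specific gene modules* shared by the
  samples of condition j (K_j = 2 by default).
* **W_ℓ2** (m_ℓ × K) and **W_ℓ1** (m_ℓ × K_{j_ℓ}): each cell's
  expression of the common and condition-specific modules.

The factors minimize

    Σ_ℓ (1/m_ℓ)‖X_ℓ − W_ℓ1 H_{j_ℓ} − W_ℓ2 V‖²_F
      + λ₁ Σ_ℓ (1/m_ℓ)‖W_ℓ1 H_{j_ℓ}‖²_F
      + λ₂ Σ_{j<j'} ‖H_j H_{j'}ᵀ‖₁

subject to unit-L2 rows of V and H_j, solved by HALS-style block
coordinate descent. λ₁ limits the scale of the condition-specific part,
λ₂ pushes condition modules of different conditions toward disjoint
gene support. Cells are then clustered across samples with a
mutual-nearest-neighbor graph + Louvain on the row-normalized W_ℓ2, and
module expression is quantile-aligned per cluster for visualization.
K is chosen by consensus-clustering stability over random restarts;
λ₁ = λ₂ by a specificity score of the condition modules. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import scinsight as si

# a synthetic six-sample study: 3 time points x 2 samples, 6 cell types,
# 3000 cells, with known ground truth
study, truth = si.simulate_study(si.SimulationConfig(seed=1))
proc = si.preprocess(study, n_hvgs=1500)

est = si.SCInsight(K=13, K_j=2, lambda1=0.01, lambda2=0.01, random_state=1)
est.fit(proc)

clus = si.MNNLouvainClusterer(n_neighbors=20, random_state=1)
labels = clus.fit_predict(est.model_)

print("clusters:", len(np.unique(labels)))
print("ARI vs truth:", round(si.adjusted_rand_index(labels, truth.type_labels), 4))
sample_of = study.sample_index_of_cells()
score = si.integration_score(
    si.neighbor_sets(clus.aligned_.stacked(), sample_of, k=20))
print("integration score:", round(score, 4))
```

Output:

```
clusters: 6
ARI vs truth: 0.9908
integration score: 0.9276
```

Six clusters in one-to-one correspondence with the six simulated cell
types (ARI ≈ 0.99), and an integration score near 1, meaning each
cell's neighborhood contains the six samples in close to their global
proportions — the per-sample technical effects have been removed while
the condition structure stayed in the H_j modules.

The same pipeline from a shell:

```bash
scinsight simulate --preset original --seed 1 --out sim/
scinsight fit --manifest sim/manifest.csv --hvg 1500 --k 13 --kj 2 \
    --lambda1 0.01 --lambda2 0.01 --seed 1 --out factors/
scinsight cluster --factors factors/ --n-c 20 --seed 1 --out clusters/
scinsight score --metric ari --labels clusters/clusters.tsv \
    --labels2 sim/truth.tsv --column cluster --column2 cell_type --out scores/
```

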