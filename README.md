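# sgcluster

Deep graph clustering of single-cell RNA-seq data with **structural
grouping**: a dual-channel autoencoder / graph-attention autoencoder whose
attention mechanism is steered by a differentiable K-way normalized-cut
loss, trained with decoupled DEC-style self-supervision.

## The problem

Clustering cells into subpopulations from an expression matrix
X ∈ R^(N×M) (N cells, M genes) is the entry point of most scRNA-seq
analyses.  Graph-based deep clustering methods build a cell–cell graph
G = (X, A) and learn embeddings by neighbourhood aggregation, but plain
attention only looks at a node and its immediate neighbours — it is blind
to the *graph cluster* (community) structure — and the feature view of a
cell and its structural view live in different spaces (a "heterogeneous
gap").  This package addresses both:

1. **Differentiable structural grouping.**  The K-way normalized-cut
   objective

       max (1/K) Σ_k  links(C_k, C_k) / degree(C_k)

   is relaxed through the indicator map E_k = D^{1/2} F_k (F_kᵀ D F_k)^{-1/2}
   into a trace maximisation whose optimum (Ky Fan) is the mean of the K
   largest eigenvalues of D^{-1/2} A D^{-1/2}.  Each attention layer's
   pre-activation S is treated as a relaxed partition matrix and penalised
   with

       L_SG = ‖(1/N) SᵀS − I‖_F² − (1/NK) tr(Sᵀ D^{-1/2} A D^{-1/2} S),

   summed over layers — so the attention weights are pushed toward nodes in
   the same graph cluster.

2. **Layer-wise interaction.**  An L-layer autoencoder (feature channel,
   representations Z) and an L-layer graph-attention autoencoder
   (structural channel, representations H) are fused after every shared
   layer, U(r) = Z(r) + H(r), the fused representation feeding the next
   attention layer.  The AE decodes X (MSE); the GATE decodes the adjacency
   as Â = sigmoid(H H ᵀ) (MSE).

3. **Decoupled self-supervision.**  Each channel gets its own Student-t
   soft assignment Q against its own cluster centres and its own sharpened
   target P (squared, frequency-normalised), giving the joint objective

       L = L_res + KL(P_z‖Q_z) + α·L_SG + β·KL(P_h‖Q_h),   α = 3·10⁻⁵, β = 10.

A Splatter-style negative-binomial simulator with mean-dependent logistic
dropout ships with the package, so every component is testable without
downloading data; `calibrate_dropout` dials the realized zero fraction to a
requested sparsity.

## Worked example

```python
import numpy as np
from sgcluster import (SimConfig, simulate, preprocess, PreprocessConfig,
                       StructuralGroupingClustering, ari, nmi)

cfg = SimConfig(n_cells=300, n_genes=500, n_groups=3, seed=7)
counts, truth, realized = simulate(cfg)
print(f"simulated {counts.n_cells} cells x {counts.n_genes} genes, "
      f"{realized:.1%} zero entries")

expr = preprocess(counts, PreprocessConfig(min_genes=50, n_hvg=400))
model = StructuralGroupingClustering(n_clusters=3, knn=12, random_state=0)
labels = model.fit_predict(expr.values)

print(f"cluster sizes: {np.bincount(labels)}")
print(f"ARI = {ari(truth, labels):.3f}, NMI = {nmi(truth, labels):.3f}")
```

prints

```
simulated 300 cells x 500 genes, 12.1% zero entries
cluster sizes: [100 100 100]
ARI = 1.000, NMI = 1.000
```

i.e. the three planted groups are recovered exactly (ARI/NMI of 1 mean the
predicted partition coincides with the simulated ground truth up to label
names).  After `fit`, the estimator exposes `labels_`, the feature and
structural embeddings `embedding_z_` / `embedding_h_`, the cell graph
`graph_`, and a per-epoch `history_` of all loss terms.

The same pipeline is available from the shell:

```bash
sgcluster simulate --cells 1000 --genes 1000 --groups 4 --seed 0 --out sim/
sgcluster run --input sim/counts.mtx --clusters 4 --labels sim/labels.tsv --out fit/
sgcluster evaluate --pred fit/labels.tsv --truth sim/labels.tsv
sgcluster markers --input sim/counts.mtx --labels fit/labels.tsv --preprocess
```

Every output directory carries a `manifest.json` (resolved configuration,
input digests, seed) sufficient to reproduce the run bit-for-bit.

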